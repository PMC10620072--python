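"""Interpretation grammars: ordered rewrite rules from word sequences to symbol sequences.

An interpretation grammar is an ordered list of rewrite rules. Primitive rules
map a single word to a single output symbol ("dax -> RED"). Function rules have
a left-hand-side pattern containing one literal (the function name) and one or
two variables, and a right-hand side that rearranges and repeats the recursively
evaluated arguments. Variables come in two classes: ``u`` variables bind exactly
one primitive word, ``x`` variables bind any non-empty word string. Rules are
tried in listing order (first-match priority) against the whole input string,
which makes evaluation deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "UnparseableError",
    "DepthExceededError",
    "Rule",
    "InterpretationGrammar",
    "Assignment",
    "gold_grammar",
    "random_assignment",
    "WORD_POOL",
    "COLOUR_POOL",
    "CANONICAL_ASSIGNMENT",
    "VARIABLES",
    "U_VARS",
    "X_VARS",
]

#: Variable tokens reserved inside rule patterns; grammar vocabularies must not
#: use these as words or symbols.
U_VARS = ("u1", "u2")
X_VARS = ("x1", "x2")
VARIABLES = U_VARS + X_VARS

#: Candidate word pool for the few-shot task (9 words; 7 are used per task).
WORD_POOL = ("dax", "wif", "lug", "zup", "fep", "blicket", "kiki", "tufa", "gazzer")

#: Output-symbol pool (6 colours; 4 are bound to primitives per task).
COLOUR_POOL = ("RED", "GREEN", "BLUE", "YELLOW", "PURPLE", "PINK")

DEFAULT_MAX_DEPTH = 50


class UnparseableError(ValueError):
    """No rule admits a full segmentation whose sub-strings all evaluate."""


class DepthExceededError(RecursionError):
    """Recursive rewriting exceeded the configured depth bound."""


def is_variable(token: str) -> bool:
    return token in VARIABLES


@dataclass(frozen=True)
class Rule:
    """A single rewrite rule.

    ``lhs`` is the pattern: a tuple of literal words and/or variable tokens.
    ``rhs`` is a tuple of slots; for a primitive rule the single slot is an
    output symbol, for function rules each slot references an LHS variable.
    """

    lhs: tuple[str, ...]
    rhs: tuple[str, ...]

    def __post_init__(self) -> None:
        lhs_vars = [t for t in self.lhs if is_variable(t)]
        if len(lhs_vars) > 2:
            raise ValueError(f"at most 2 variables per pattern, got {lhs_vars}")
        if len(set(lhs_vars)) != len(lhs_vars):
            raise ValueError(f"repeated variable in pattern {self.lhs}")
        if self.is_primitive:
            if len(self.rhs) != 1:
                raise ValueError("primitive rules map one word to one symbol")
        else:
            bad = [s for s in self.rhs if is_variable(s) and s not in lhs_vars]
            if bad:
                raise ValueError(f"RHS references unbound variables {bad}")

    @property
    def is_primitive(self) -> bool:
        return len(self.lhs) == 1 and not is_variable(self.lhs[0])

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(t for t in self.lhs if is_variable(t))

    def serialize(self) -> str:
        lhs = " ".join(self.lhs)
        if self.is_primitive:
            return f"{lhs} -> {self.rhs[0]}"
        rhs = " ".join(f"[{s}]" for s in self.rhs)
        return f"{lhs} -> {rhs}"

    @classmethod
    def parse(cls, line: str) -> "Rule":
        try:
            lhs_text, rhs_text = line.split("->")
        except ValueError as exc:
            raise ValueError(f"rule line needs exactly one '->': {line!r}") from exc
        lhs = tuple(lhs_text.split())
        slots = rhs_text.split()
        rhs = tuple(s[1:-1] if s.startswith("[") and s.endswith("]") else s for s in slots)
        return cls(lhs=lhs, rhs=rhs)


@dataclass
class InterpretationGrammar:
    """Ordered rewrite rules plus the vocabularies they operate over."""

    rules: list[Rule]
    input_vocab: tuple[str, ...] = ()
    output_vocab: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.input_vocab:
            words = []
            for r in self.rules:
                for t in r.lhs:
                    if not is_variable(t) and t not in words:
                        words.append(t)
            self.input_vocab = tuple(words)
        if not self.output_vocab:
            syms = []
            for r in self.rules:
                if r.is_primitive and r.rhs[0] not in syms:
                    syms.append(r.rhs[0])
            self.output_vocab = tuple(syms)
        self._primitives = {
            r.lhs[0]: r.rhs[0] for r in self.rules if r.is_primitive
        }

    @property
    def primitives(self) -> dict[str, str]:
        """Word -> symbol map defined by the primitive rules."""
        return self._primitives

    @property
    def function_rules(self) -> list[Rule]:
        return [r for r in self.rules if not r.is_primitive and any(
            not is_variable(t) for t in r.lhs)]

    def serialize(self) -> str:
        return "\n".join(r.serialize() for r in self.rules)

    @classmethod
    def parse(cls, text: str) -> "InterpretationGrammar":
        rules = [Rule.parse(line) for line in text.splitlines() if line.strip()]
        return cls(rules=rules)

    # -- matching and evaluation ------------------------------------------

    def match(self, rule: Rule, seq: Sequence[str]) -> Optional[dict[str, tuple[str, ...]]]:
        """First whole-string binding of ``rule`` against ``seq``, or None.

        Feasible segmentations are enumerated leftmost-shortest (earlier
        variables take the shortest admissible span first); the first one is
        returned without checking evaluability -- :meth:`evaluate` backtracks
        over the full enumeration when sub-strings fail to evaluate.
        """
        for binding in self._bindings(rule, seq):
            return binding
        return None

    def _bindings(
        self, rule: Rule, seq: Sequence[str]
    ) -> Iterator[dict[str, tuple[str, ...]]]:
        seq = tuple(seq)

        def rec(elems: tuple[str, ...], pos: int, bound: dict) -> Iterator[dict]:
            if not elems:
                if pos == len(seq):
                    yield dict(bound)
                return
            head, rest = elems[0], elems[1:]
            remaining = len(seq) - pos
            if remaining <= 0:
                return
            if not is_variable(head):
                if seq[pos] == head:
                    yield from rec(rest, pos + 1, bound)
            elif head in U_VARS:
                if seq[pos] in self._primitives:
                    bound[head] = (seq[pos],)
                    yield from rec(rest, pos + 1, bound)
                    del bound[head]
            else:  # x variable: any non-empty span, shortest first
                # later elements need at least their minimal footprint
                min_rest = sum(1 for _ in rest)
                for span in range(1, remaining - min_rest + 1):
                    bound[head] = seq[pos : pos + span]
                    yield from rec(rest, pos + span, bound)
                    del bound[head]

        return rec(rule.lhs, 0, {})

    def evaluate(
        self, seq: Sequence[str], max_depth: int = DEFAULT_MAX_DEPTH
    ) -> tuple[str, ...]:
        """Rewrite ``seq`` to its terminal output-symbol sequence.

        Rules are tried in listing order; within a rule, segmentations are
        tried leftmost-shortest, and the first one whose bound sub-strings all
        evaluate recursively is used. Deterministic.
        """
        seq = tuple(seq)
        if not seq:
            raise UnparseableError("empty input")
        memo: dict[tuple[str, ...], Optional[tuple[str, ...]]] = {}
        return self._eval(seq, max_depth, memo)

    def _eval(self, seq, depth, memo):
        if seq in memo:
            out = memo[seq]
            if out is None:
                raise UnparseableError(f"unparseable: {' '.join(seq)}")
            return out
        if depth <= 0:
            raise DepthExceededError(f"depth exceeded on: {' '.join(seq)}")
        for rule in self.rules:
            if rule.is_primitive:
                if len(seq) == 1 and seq[0] == rule.lhs[0]:
                    memo[seq] = rule.rhs
                    return rule.rhs
                continue
            for binding in self._bindings(rule, seq):
                try:
                    parts = {
                        var: self._eval(sub, depth - 1, memo)
                        for var, sub in binding.items()
                    }
                except UnparseableError:
                    continue
                out = []
                for slot in rule.rhs:
                    out.extend(parts[slot])
                out = tuple(out)
                memo[seq] = out
                return out
        memo[seq] = None
        raise UnparseableError(f"unparseable: {' '.join(seq)}")

    def parses(self, seq: Sequence[str], max_depth: int = DEFAULT_MAX_DEPTH) -> bool:
        try:
            self.evaluate(seq, max_depth=max_depth)
            return True
        except (UnparseableError, DepthExceededError):
            return False


# -- the human few-shot task grammar ---------------------------------------

FUNCTION_ROLES = ("f1", "f2", "f3")
PRIMITIVE_ROLES = ("p1", "p2", "p3", "p4")


@dataclass(frozen=True)
class Assignment:
    """Randomizable binding of surface words to task roles and colours.

    ``primitives`` maps the four primitive words (in role order p1..p4) to
    their colours; ``functions`` maps role names f1/f2/f3 to the words that
    carry them. Both maps are injective.
    """

    primitives: tuple[tuple[str, str], ...]  # ((word, colour), ...) in role order
    functions: tuple[tuple[str, str], ...]  # (("f1", word), ...)

    def __post_init__(self) -> None:
        words = [w for w, _ in self.primitives] + [w for _, w in self.functions]
        colours = [c for _, c in self.primitives]
        if len(set(words)) != len(words):
            raise ValueError("word assignment must be injective")
        if len(set(colours)) != len(colours):
            raise ValueError("colour assignment must be injective")

    @property
    def primitive_map(self) -> dict[str, str]:
        return dict(self.primitives)

    @property
    def function_map(self) -> dict[str, str]:
        return dict(self.functions)

    @property
    def words(self) -> tuple[str, ...]:
        return tuple([w for w, _ in self.primitives] + [w for _, w in self.functions])

    def word_for_role(self, role: str) -> str:
        if role in self.function_map:
            return self.function_map[role]
        idx = PRIMITIVE_ROLES.index(role)
        return self.primitives[idx][0]

    def colour_for_role(self, role: str) -> str:
        idx = PRIMITIVE_ROLES.index(role)
        return self.primitives[idx][1]


CANONICAL_ASSIGNMENT = Assignment(
    primitives=(("dax", "RED"), ("wif", "GREEN"), ("lug", "BLUE"), ("zup", "YELLOW")),
    functions=(("f1", "fep"), ("f2", "blicket"), ("f3", "kiki")),
)


def gold_grammar(
    assignment: Assignment = CANONICAL_ASSIGNMENT,
    output_pool: Sequence[str] = COLOUR_POOL,
) -> InterpretationGrammar:
    """The grammar defining the human few-shot task, under an assignment.

    Function 1 repeats its primitive argument three times; function 2 wraps
    its first primitive argument around its second; function 3 concatenates
    the evaluations of its two string arguments in reverse order; a final
    concatenation rule joins adjacent evaluable strings left to right.
    Priority order: primitives, f1, f2, f3, concatenation.
    """
    f = assignment.function_map
    if set(f) != set(FUNCTION_ROLES) or len(assignment.primitives) < 4:
        raise ValueError("assignment must cover roles f1..f3 and 4 primitives")
    rules = [Rule((w,), (c,)) for w, c in assignment.primitives]
    rules.append(Rule(("u1", f["f1"]), ("u1", "u1", "u1")))
    rules.append(Rule(("u1", f["f2"], "u2"), ("u1", "u2", "u1")))
    rules.append(Rule(("x1", f["f3"], "x2"), ("x2", "x1")))
    rules.append(Rule(("x1", "x2"), ("x1", "x2")))
    return InterpretationGrammar(
        rules=rules,
        input_vocab=assignment.words,
        output_vocab=tuple(output_pool),
    )


def random_assignment(
    rng: np.random.Generator,
    word_pool: Sequence[str] = WORD_POOL,
    colour_pool: Sequence[str] = COLOUR_POOL,
) -> Assignment:
    """Uniform injective draw of 7 words and 4 colours from the pools.

    With the default 6-colour pool, two colours stay unused, mirroring the
    response interface of the behavioural task.
    """
    if len(word_pool) < 7:
        raise ValueError("word pool must provide at least 7 words")
    if len(colour_pool) < 4:
        raise ValueError("colour pool must provide at least 4 colours")
    words = rng.choice(len(word_pool), size=7, replace=False)
    colours = rng.choice(len(colour_pool), size=4, replace=False)
    prim = tuple(
        (word_pool[w], colour_pool[c]) for w, c in zip(words[:4], colours)
    )
    funcs = tuple(zip(FUNCTION_ROLES, (word_pool[w] for w in words[4:])))
    return Assignment(primitives=prim, functions=funcs)
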