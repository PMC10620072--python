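"""Random grammars and meta-training episodes.

Each episode is one seq2seq task: a latent interpretation grammar, 14 study
input/output pairs and 10 query pairs, all sampled as unique input sequences
(length <= 8) that the grammar parses to outputs (length <= 8). Grammars are
sampled from a simple meta-grammar: 4 primitive rules pairing words with
colours without replacement, 3 function rules with random name, arity and
argument classes, and a fixed final left-to-right concatenation rule.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .grammar import (
    COLOUR_POOL,
    WORD_POOL,
    InterpretationGrammar,
    Rule,
    UnparseableError,
    DepthExceededError,
    gold_grammar,
    is_variable,
)

__all__ = [
    "ExamplePair",
    "Episode",
    "EpisodeConfig",
    "SamplingExhaustedError",
    "sample_grammar",
    "sample_episode",
    "grammars_equivalent",
    "build_corpus",
    "write_jsonl",
    "read_jsonl",
]

#: Input-word surface forms for meta-training episodes (8 possible words).
EPISODE_WORDS = WORD_POOL[:8]


class SamplingExhaustedError(RuntimeError):
    """The attempt budget ran out before the example quota was met."""


@dataclass(frozen=True)
class ExamplePair:
    input: tuple[str, ...]
    output: tuple[str, ...]
    tag: str = "study"  # {study, query}
    provenance: str = "algebraic"  # {algebraic, one_to_one, noisy_rule, copy, human}


@dataclass
class Episode:
    """Study pairs + query pairs, with the latent grammar when generated."""

    study: list[ExamplePair]
    query: list[ExamplePair]
    grammar: Optional[InterpretationGrammar] = None


@dataclass(frozen=True)
class EpisodeConfig:
    n_input_symbols: int = 8
    n_output_symbols: int = 6
    n_primitives: int = 4
    n_functions: int = 3
    n_study: int = 14
    n_query: int = 10
    max_len: int = 8
    rhs_max_len: int = 8
    noise_p: float = 0.01
    noise_targets: tuple[str, ...] = ("study", "query")
    force_rhs_use_all_args: bool = False
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_p <= 1.0:
            raise ValueError("noise_p must lie in [0, 1]")
        for name in ("n_input_symbols", "n_output_symbols", "n_study", "n_query",
                     "max_len", "rhs_max_len", "n_primitives"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_functions < 0:
            raise ValueError("n_functions must be >= 0")

    @property
    def words(self) -> tuple[str, ...]:
        return WORD_POOL[: self.n_input_symbols]

    @property
    def symbols(self) -> tuple[str, ...]:
        return COLOUR_POOL[: self.n_output_symbols]


def sample_grammar(rng: np.random.Generator, config: EpisodeConfig = EpisodeConfig()) -> InterpretationGrammar:
    """Draw one interpretation grammar from the meta-grammar.

    Primitive rules pair words and colours injectively; each function rule
    picks a name word, arity 1 (name after the argument) or 2 (name between
    arguments), an argument class u/x per argument, and an RHS of 1..rhs_max_len
    slots over the LHS arguments. Sampling distributions are uniform.
    The concatenation rule is fixed and always listed last.
    """
    words = config.words
    symbols = config.symbols
    n_roles = config.n_primitives + config.n_functions
    word_idx = rng.choice(len(words), size=n_roles, replace=False)
    prim_words = [words[i] for i in word_idx[: config.n_primitives]]
    func_words = [words[i] for i in word_idx[config.n_primitives:]]
    sym_idx = rng.choice(len(symbols), size=config.n_primitives, replace=False)
    rules = [Rule((w,), (symbols[s],)) for w, s in zip(prim_words, sym_idx)]

    for name in func_words:
        arity = int(rng.integers(1, 3))
        arg_vars = []
        for k in range(arity):
            klass = "u" if rng.integers(2) == 0 else "x"
            arg_vars.append(f"{klass}{k + 1}")
        if arity == 1:
            lhs = (arg_vars[0], name)
        else:
            lhs = (arg_vars[0], name, arg_vars[1])
        while True:
            rhs_len = int(rng.integers(1, config.rhs_max_len + 1))
            rhs = tuple(arg_vars[int(i)] for i in rng.integers(len(arg_vars), size=rhs_len))
            if not config.force_rhs_use_all_args or set(rhs) == set(arg_vars):
                break
        rules.append(Rule(lhs, rhs))

    rules.append(Rule(("x1", "x2"), ("x1", "x2")))
    return InterpretationGrammar(
        rules=rules, input_vocab=tuple(prim_words + func_words), output_vocab=symbols
    )


def _apply_noise(
    output: tuple[str, ...], rng: np.random.Generator, p: float, symbols: Sequence[str]
) -> tuple[str, ...]:
    if p <= 0.0:
        return output
    out = list(output)
    for i in range(len(out)):
        if rng.random() < p:
            out[i] = symbols[int(rng.integers(len(symbols)))]
    return tuple(out)


def sample_episode(
    rng: np.random.Generator,
    grammar: InterpretationGrammar,
    config: EpisodeConfig = EpisodeConfig(),
) -> Episode:
    """Rejection-sample unique parseable inputs into study and query sets.

    Inputs are uniform word sequences of uniform length 1..max_len over the
    grammar's vocabulary, kept when they parse to an output of length
    <= max_len and are not already taken. Query inputs are distinct from the
    study inputs. Output noise (noise_p per symbol) is applied after the
    algebraic outputs are computed.
    """
    vocab = grammar.input_vocab
    need = config.n_study + config.n_query
    taken: dict[tuple[str, ...], tuple[str, ...]] = {}
    attempts = 0
    while len(taken) < need:
        attempts += 1
        if attempts > config.max_attempts:
            raise SamplingExhaustedError(
                f"could not draw {need} unique parseable inputs in "
                f"{config.max_attempts} attempts"
            )
        length = int(rng.integers(1, config.max_len + 1))
        seq = tuple(vocab[int(i)] for i in rng.integers(len(vocab), size=length))
        if seq in taken:
            continue
        try:
            out = grammar.evaluate(seq)
        except (UnparseableError, DepthExceededError):
            continue
        if len(out) > config.max_len:
            continue
        taken[seq] = out

    items = list(taken.items())
    order = rng.permutation(len(items))  # study order shuffled per episode
    study, query = [], []
    for rank, idx in enumerate(order):
        inp, out = items[int(idx)]
        tag = "study" if rank < config.n_study else "query"
        if tag in config.noise_targets:
            out = _apply_noise(out, rng, config.noise_p, config.symbols)
        pair = ExamplePair(input=inp, output=out, tag=tag)
        (study if tag == "study" else query).append(pair)
    return Episode(study=study, query=query, grammar=grammar)


# -- structural equivalence -------------------------------------------------

def _rule_signature(rule: Rule) -> tuple:
    """Shape of a rule with word identities abstracted away."""
    lhs = tuple(t if is_variable(t) else "<name>" for t in rule.lhs)
    rhs = rule.rhs if not rule.is_primitive else ("<sym>",)
    return (lhs, rhs)


def grammars_equivalent(
    g1: InterpretationGrammar,
    g2: InterpretationGrammar,
    mode: str = "rule_permutation",
) -> bool:
    """Structural equivalence used by the novelty filter.

    ``rule_permutation`` compares the rule multisets, ignoring listing order.
    ``rule_and_symbol_permutation`` additionally searches over bijections of
    the input words and output symbols; the search is pruned by rule-shape
    signatures, so only primitive words map to primitive words and function
    names map to names of same-shaped functions.
    """
    if mode == "rule_permutation":
        return sorted(r.serialize() for r in g1.rules) == sorted(
            r.serialize() for r in g2.rules
        )
    if mode != "rule_and_symbol_permutation":
        raise ValueError(f"unknown mode {mode!r}")

    p1, p2 = sorted(g1.primitives), sorted(g2.primitives)
    f1 = [r for r in g1.rules if not r.is_primitive]
    f2 = [r for r in g2.rules if not r.is_primitive]
    if len(p1) != len(p2) or len(f1) != len(f2):
        return False
    # Function-name candidates constrained by rule shape.
    named1 = [r for r in f1 if any(not is_variable(t) for t in r.lhs)]
    named2 = [r for r in f2 if any(not is_variable(t) for t in r.lhs)]
    anon1 = sorted(r.serialize() for r in f1 if r not in named1)
    anon2 = sorted(r.serialize() for r in f2 if r not in named2)
    if anon1 != anon2 or len(named1) != len(named2):
        return False

    def name_of(rule: Rule) -> str:
        return next(t for t in rule.lhs if not is_variable(t))

    sig2 = {}
    for r in named2:
        sig2.setdefault(_rule_signature(r), []).append(r)

    def try_funcs(i: int, word_map: dict) -> bool:
        if i == len(named1):
            return try_prims(word_map)
        r = named1[i]
        for cand in sig2.get(_rule_signature(r), []):
            tgt = name_of(cand)
            if tgt in word_map.values():
                continue
            word_map[name_of(r)] = tgt
            if try_funcs(i + 1, word_map):
                return True
            del word_map[name_of(r)]
        return False

    def try_prims(word_map: dict) -> bool:
        prims1 = sorted(g1.primitives.items())
        targets = list(g2.primitives.items())
        for perm in itertools.permutations(range(len(targets))):
            wm = dict(word_map)
            sm: dict[str, str] = {}
            ok = True
            for (w1, s1), j in zip(prims1, perm):
                w2, s2 = targets[j]
                if w2 in wm.values() or (s1 in sm and sm[s1] != s2) or (
                    s2 in sm.values() and sm.get(s1) != s2
                ):
                    ok = False
                    break
                wm[w1] = w2
                sm[s1] = s2
            if not ok:
                continue
            if _check_map(g1, g2, wm, sm):
                return True
        return False

    def _check_map(ga, gb, wm, sm) -> bool:
        mapped = []
        for r in ga.rules:
            lhs = tuple(t if is_variable(t) else wm.get(t, t) for t in r.lhs)
            rhs = (sm[r.rhs[0]],) if r.is_primitive else r.rhs
            mapped.append((lhs, rhs))
        actual = [
            (r.lhs, r.rhs) for r in gb.rules
        ]
        return sorted(mapped) == sorted(actual)

    return try_funcs(0, {})


# -- corpora ----------------------------------------------------------------

def _grammar_signature(g: InterpretationGrammar) -> tuple[str, ...]:
    """Canonical form under rule permutation (mode-1 equivalence class)."""
    return tuple(sorted(r.serialize() for r in g.rules))


def episode_to_record(ep: Episode) -> dict:
    rec = {
        "grammar": ep.grammar.serialize() if ep.grammar is not None else None,
        "study": [
            {"input": list(p.input), "output": list(p.output), "provenance": p.provenance}
            for p in ep.study
        ],
        "query": [
            {"input": list(p.input), "output": list(p.output), "provenance": p.provenance}
            for p in ep.query
        ],
    }
    return rec


def record_to_episode(rec: dict) -> Episode:
    grammar = (
        InterpretationGrammar.parse(rec["grammar"]) if rec.get("grammar") else None
    )
    def pairs(key, tag):
        return [
            ExamplePair(
                input=tuple(p["input"]),
                output=tuple(p["output"]),
                tag=tag,
                provenance=p.get("provenance", "algebraic"),
            )
            for p in rec[key]
        ]
    return Episode(study=pairs("study", "study"), query=pairs("query", "query"), grammar=grammar)


def write_jsonl(episodes: Iterable[Episode], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for ep in episodes:
            fh.write(json.dumps(episode_to_record(ep), sort_keys=True, separators=(",", ":")))
            fh.write("\n")


def read_jsonl(path: str | Path) -> list[Episode]:
    with open(path) as fh:
        return [record_to_episode(json.loads(line)) for line in fh if line.strip()]


def build_corpus(
    rng: np.random.Generator,
    n_train: int = 100_000,
    n_val: int = 200,
    config: EpisodeConfig = EpisodeConfig(),
    exclude: Sequence[InterpretationGrammar] = (),
    out_dir: Optional[str | Path] = None,
) -> tuple[list[Episode], list[Episode]]:
    """Fixed training + validation corpora with novelty checks.

    Validation grammars must differ from every training grammar under rule
    permutation, and both corpora must differ from the gold task grammar (and
    any extra ``exclude`` grammars) under rule *and* symbol permutation.
    When ``out_dir`` is given, writes train.jsonl / val.jsonl there.
    """
    reserved = list(exclude) or [gold_grammar()]

    def admissible(g: InterpretationGrammar) -> bool:
        return not any(
            grammars_equivalent(g, r, mode="rule_and_symbol_permutation")
            for r in reserved
        )

    train: list[Episode] = []
    train_sigs: set[tuple[str, ...]] = set()
    while len(train) < n_train:
        g = sample_grammar(rng, config)
        if not admissible(g):
            continue
        try:
            ep = sample_episode(rng, g, config)
        except SamplingExhaustedError:
            continue
        train.append(ep)
        train_sigs.add(_grammar_signature(g))

    val: list[Episode] = []
    while len(val) < n_val:
        g = sample_grammar(rng, config)
        if _grammar_signature(g) in train_sigs or not admissible(g):
            continue
        try:
            ep = sample_episode(rng, g, config)
        except SamplingExhaustedError:
            continue
        val.append(ep)

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_jsonl(train, out_dir / "train.jsonl")
        write_jsonl(val, out_dir / "val.jsonl")
    return train, val
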