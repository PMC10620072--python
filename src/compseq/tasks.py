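"""Task surfaces for the behavioural experiments.

The exact study/query item lists of the original few-shot experiment are not
part of this package's inputs; the fixture below is a RECONSTRUCTED surface,
synthetic in that sense, built to satisfy the documented task constraints:

* curriculum of 4 primitives, two demonstrations of each of the three
  functions, and four function compositions (14 study items);
* 10 query items, none of which can be obtained from a study item of the
  same structural template by changing a single primitive word (the one
  permitted exception: a single novel primitive as argument to function 1);
* query items include two-symbol outputs and outputs longer than any study
  output, probing longer compositions than were studied.

Items are stored as role templates (p1..p4 primitives, f1..f3 functions) and
realized under a word/colour :class:`~compseq.grammar.Assignment`, exactly as
the task surface was re-randomized per participant.
"""

from __future__ import annotations

from typing import Sequence

from .episodes import Episode, ExamplePair
from .grammar import (
    CANONICAL_ASSIGNMENT,
    WORD_POOL,
    Assignment,
    InterpretationGrammar,
    gold_grammar,
)

__all__ = [
    "FEWSHOT_STUDY_TEMPLATES",
    "FEWSHOT_QUERY_TEMPLATES",
    "OPEN_ENDED_TEMPLATES",
    "fewshot_task",
    "fewshot_episode",
    "open_ended_instructions",
    "substitution_distance",
]

# 14 study items: primitives; f1 x2; f2 x2; f3 x2; compositions x4.
FEWSHOT_STUDY_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("p1",),
    ("p2",),
    ("p3",),
    ("p4",),
    ("p1", "f1"),
    ("p3", "f1"),
    ("p1", "f2", "p3"),
    ("p2", "f2", "p1"),
    ("p1", "f3", "p3"),
    ("p3", "f3", "p2"),
    ("p3", "f1", "f3", "p2"),
    ("p2", "f3", "p1", "f2", "p3"),
    ("p3", "f3", "p2", "f1"),
    ("p1", "f2", "p4", "f3", "p2"),
)

# 10 query items; outputs of length 2 up to 6 (longer than any study output).
FEWSHOT_QUERY_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("p4", "f1"),  # single novel primitive fed to function 1 (permitted 1-sub)
    ("p4", "f2", "p2"),
    ("p4", "f3", "p1"),
    ("p2", "f3", "p4"),
    ("p2", "f2", "p1", "f3", "p3"),
    ("p4", "f1", "f3", "p3"),
    ("p4", "f3", "p1", "f2", "p2"),
    ("p4", "f2", "p1", "f3", "p3", "f1"),
    ("p2", "f1", "f3", "p4", "f2", "p3"),
    ("p1", "f1", "f3", "p4", "f1"),
)

# 7 open-ended instructions over 5 words: five singletons, two two-word
# combinations. Only two of the original instructions are documented; the
# rest of this default list is a synthetic reconstruction and is configurable.
OPEN_ENDED_TEMPLATES: tuple[tuple[str, ...], ...] = (
    ("w1",),
    ("w2",),
    ("w3",),
    ("w4",),
    ("w5",),
    ("w1", "w1"),
    ("w1", "w2"),
)


def _realize(template: Sequence[str], assignment: Assignment) -> tuple[str, ...]:
    return tuple(assignment.word_for_role(role) for role in template)


def fewshot_task(
    assignment: Assignment = CANONICAL_ASSIGNMENT,
) -> tuple[list[ExamplePair], list[ExamplePair], InterpretationGrammar]:
    """Realized study pairs, query pairs and gold grammar under an assignment."""
    grammar = gold_grammar(assignment)
    study = [
        ExamplePair(input=inp, output=grammar.evaluate(inp), tag="study")
        for inp in (_realize(t, assignment) for t in FEWSHOT_STUDY_TEMPLATES)
    ]
    query = [
        ExamplePair(input=inp, output=grammar.evaluate(inp), tag="query")
        for inp in (_realize(t, assignment) for t in FEWSHOT_QUERY_TEMPLATES)
    ]
    return study, query, grammar


def fewshot_episode(assignment: Assignment = CANONICAL_ASSIGNMENT) -> Episode:
    study, query, grammar = fewshot_task(assignment)
    return Episode(study=study, query=query, grammar=grammar)


def open_ended_instructions(
    words: Sequence[str] = WORD_POOL[:5],
    templates: Sequence[Sequence[str]] = OPEN_ENDED_TEMPLATES,
) -> list[tuple[str, ...]]:
    """Realize the open-ended instruction list over a 5-word vocabulary."""
    if len(words) < 5:
        raise ValueError("open-ended task uses 5 possible words")
    table = {f"w{i + 1}": w for i, w in enumerate(words)}
    return [tuple(table[t] for t in template) for template in templates]


def substitution_distance(a: Sequence[str], b: Sequence[str], assignment: Assignment) -> int | None:
    """Number of primitive-word substitutions turning ``a`` into ``b``.

    Defined only for items sharing a structural template: same length and
    identical function words in identical positions. Returns None otherwise.
    """
    if len(a) != len(b):
        return None
    functions = set(assignment.function_map.values())
    dist = 0
    for wa, wb in zip(a, b):
        if (wa in functions) != (wb in functions):
            return None
        if wa in functions:
            if wa != wb:
                return None
        elif wa != wb:
            dist += 1
    return dist
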