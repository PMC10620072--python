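"""Behaviourally informed transformation of algebraic query outputs.

Human few-shot responses are algebraic roughly 80% of the time; the rest are
dominated by two heuristics. This module implements that mixture for
meta-training targets: with probability ``p_algebraic`` a query keeps its
algebraic output; otherwise a fair coin picks between a stochastic one-to-one
translation (each input word mapped left-to-right to a single output symbol)
and a noisy rule application in which each two-argument function may flip the
role of its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .episodes import Episode, ExamplePair
from .grammar import InterpretationGrammar, Rule, UnparseableError, is_variable

__all__ = ["BiasConfig", "one_to_one_translate", "flip_two_arg", "transform_episode"]


@dataclass(frozen=True)
class BiasConfig:
    p_algebraic: float = 0.8
    p_one_to_one_given_heuristic: float = 0.5
    p_flip_per_two_arg_function: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "p_algebraic",
            "p_one_to_one_given_heuristic",
            "p_flip_per_two_arg_function",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def isolated_primitive_map(study: Sequence[ExamplePair]) -> dict[str, str]:
    """Word -> symbol map from study pairs that are single word -> single symbol."""
    return {
        p.input[0]: p.output[0]
        for p in study
        if len(p.input) == 1 and len(p.output) == 1
    }


def one_to_one_translate(
    study: Sequence[ExamplePair],
    query_input: Sequence[str],
    rng: np.random.Generator,
    output_pool: Sequence[str],
) -> tuple[str, ...]:
    """Left-to-right word-by-word translation of a query.

    A word showing an isolated primitive mapping among the study pairs keeps
    that mapping; any other word (for example a function name) receives an
    arbitrary output symbol, drawn uniformly and independently per occurrence.
    Output length always equals input length.
    """
    known = isolated_primitive_map(study)
    out = []
    for w in query_input:
        if w in known:
            out.append(known[w])
        else:
            out.append(output_pool[int(rng.integers(len(output_pool)))])
    return tuple(out)


def flip_two_arg(
    grammar: InterpretationGrammar,
    rng: np.random.Generator,
    p_flip: float = 0.5,
) -> InterpretationGrammar:
    """Independently flip the argument roles of each two-argument function.

    With probability ``p_flip`` per two-argument rule, every RHS reference to
    the first argument becomes a reference to the second and vice versa.
    One-argument functions and primitive rules are untouched.
    """
    new_rules = []
    for rule in grammar.rules:
        varnames = rule.variables
        if len(varnames) == 2 and any(not is_variable(t) for t in rule.lhs):
            if rng.random() < p_flip:
                swap = {varnames[0]: varnames[1], varnames[1]: varnames[0]}
                rhs = tuple(swap.get(s, s) for s in rule.rhs)
                rule = Rule(rule.lhs, rhs)
        new_rules.append(rule)
    return InterpretationGrammar(
        rules=new_rules,
        input_vocab=grammar.input_vocab,
        output_vocab=grammar.output_vocab,
    )


def transform_episode(
    episode: Episode,
    rng: np.random.Generator,
    config: BiasConfig = BiasConfig(),
) -> Episode:
    """Apply the 80/20 algebraic/heuristic mixture to the query outputs.

    Study pairs and query inputs are untouched; each query independently keeps
    its algebraic output with probability ``p_algebraic`` or is replaced by a
    heuristic output. Flip subsets are resampled per query. Provenance tags
    record which path produced each output.
    """
    if episode.grammar is None:
        raise ValueError("bias transform needs the episode's latent grammar")
    pool = episode.grammar.output_vocab
    new_queries = []
    for pair in episode.query:
        if rng.random() < config.p_algebraic:
            new_queries.append(pair)
            continue
        if rng.random() < config.p_one_to_one_given_heuristic:
            out = one_to_one_translate(episode.study, pair.input, rng, pool)
            new_queries.append(dc_replace(pair, output=out, provenance="one_to_one"))
        else:
            flipped = flip_two_arg(
                episode.grammar, rng, config.p_flip_per_two_arg_function
            )
            try:
                out = flipped.evaluate(pair.input)
            except UnparseableError:  # cannot happen for flips of parseable inputs
                out = pair.output
            new_queries.append(dc_replace(pair, output=out, provenance="noisy_rule"))
    return Episode(study=episode.study, query=new_queries, grammar=episode.grammar)
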