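"""Synthetic behavioural cohorts with the statistical structure of the
human experiments, so every pipeline stage is testable without downloads.

Few-shot participants respond to the 10 query instructions under an
~80%/20% algebraic/heuristic mixture (the oracle-with-biases model); the
open-ended cohort answers 7 instructions by chained sampling from the
three-bias model (one-to-one + iconic concatenation + mutual exclusivity)
with a lapse rate. Defaults mirror the cohort sizes of the original
experiments (25 few-shot, 29 open-ended).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .behavior import (
    BehaviourDataset,
    OpenEndedBiasModel,
    OracleBiasModel,
    ResponseRecord,
)
from .biases import BiasConfig
from .grammar import random_assignment
from .tasks import fewshot_task, open_ended_instructions

__all__ = [
    "ParticipantProfile",
    "simulate_fewshot_cohort",
    "simulate_open_ended_cohort",
    "import_behaviour",
    "export_behaviour",
]


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative settings for one synthetic participant population."""

    p_algebraic: float = 0.807  # measured human few-shot accuracy
    p_one_to_one_given_heuristic: float = 0.5
    p_flip_per_two_arg_function: float = 0.5
    lapse: float = 0.0

    def bias_config(self) -> BiasConfig:
        return BiasConfig(
            p_algebraic=self.p_algebraic,
            p_one_to_one_given_heuristic=self.p_one_to_one_given_heuristic,
            p_flip_per_two_arg_function=self.p_flip_per_two_arg_function,
        )


def simulate_fewshot_cohort(
    rng: np.random.Generator,
    n_participants: int = 25,
    profile: ParticipantProfile = ParticipantProfile(),
) -> BehaviourDataset:
    """Synthetic few-shot cohort: per participant a fresh random assignment
    and 10 query responses drawn from the oracle-with-biases model."""
    model = OracleBiasModel(config=profile.bias_config())
    records = []
    for p in range(n_participants):
        assignment = random_assignment(rng)
        study, query, grammar = fewshot_task(assignment)
        for t, q in enumerate(query):
            resp = model.sample(rng, q.input, study, grammar, lam=profile.lapse)
            records.append(
                ResponseRecord(
                    participant_id=f"fs{p:03d}",
                    task="fewshot",
                    trial_index=t,
                    query=q.input,
                    response=resp,
                    assignment=assignment,
                )
            )
    return BehaviourDataset(records)


def simulate_open_ended_cohort(
    rng: np.random.Generator,
    n_participants: int = 29,
    profile: ParticipantProfile = ParticipantProfile(),
    instructions: Optional[Sequence[Sequence[str]]] = None,
) -> BehaviourDataset:
    """Synthetic open-ended cohort: 7-instruction chains from the three-bias model."""
    model = OpenEndedBiasModel()
    records = []
    for p in range(n_participants):
        assignment = random_assignment(rng)
        instr = (
            [tuple(x) for x in instructions]
            if instructions is not None
            else open_ended_instructions(assignment.words[:5])
        )
        history: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
        for t, x in enumerate(instr):
            y = model.sample_response(rng, x, history, lam=profile.lapse)
            history.append((x, y))
            records.append(
                ResponseRecord(
                    participant_id=f"oe{p:03d}",
                    task="open_ended",
                    trial_index=t,
                    query=x,
                    response=y,
                    assignment=assignment,
                )
            )
    return BehaviourDataset(records)


def import_behaviour(path: str | Path) -> BehaviourDataset:
    """Load a normalized behaviour TSV (see :class:`BehaviourDataset`).

    The schema is the package's interchange format: columns participant_id,
    task, trial_index, query (space-separated words), response
    (space-separated colour labels) and assignment (JSON). Externally
    deposited datasets should be mapped to this format once, then loaded
    here; schema violations raise with the offending row number.
    """
    return BehaviourDataset.from_tsv(path)


def export_behaviour(dataset: BehaviourDataset, path: str | Path) -> None:
    dataset.to_tsv(path)
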