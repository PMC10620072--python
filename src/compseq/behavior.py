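"""Probabilistic models of behavioural responses with lapse-rate likelihoods.

Responses are sequences over the 6 output symbols; likelihoods are evaluated
per position over the extended symbol set S = 6 colours + end-of-sequence
(|S| = 7). Every model mixes its prediction with a uniform lapse:

    P(s) = (1 - lambda) * P_M(s) + lambda / |S|

and positions where the model has no prediction (the response extends beyond
the model's predicted sequence) fall back to the uniform 1/|S|.

Models follow a Model/Results convention: construct a model, call ``fit`` on
a :class:`BehaviourDataset` to maximize the total log-likelihood over the
lapse rate, and read estimates off the returned :class:`LapseFitResults`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .biases import BiasConfig, isolated_primitive_map
from .episodes import ExamplePair
from .grammar import (
    COLOUR_POOL,
    Assignment,
    InterpretationGrammar,
    UnparseableError,
    gold_grammar,
)

__all__ = [
    "EOS",
    "SymbolSpace",
    "ResponseRecord",
    "BehaviourDataset",
    "lapse_mix",
    "sequence_loglik",
    "BehaviourModel",
    "UniformBaselineModel",
    "OracleModel",
    "OracleBiasModel",
    "OpenEndedBiasModel",
    "LapseFitResults",
]

EOS = "<EOS>"


class SymbolSpace:
    """Index bookkeeping for the 6 output symbols plus the EOS marker."""

    def __init__(self, colours: Sequence[str] = COLOUR_POOL):
        self.colours = tuple(colours)
        self.symbols = self.colours + (EOS,)
        self.index = {s: i for i, s in enumerate(self.symbols)}
        self.size = len(self.symbols)

    def uniform(self) -> np.ndarray:
        return np.full(self.size, 1.0 / self.size)

    def delta(self, symbol: str) -> np.ndarray:
        d = np.zeros(self.size)
        d[self.index[symbol]] = 1.0
        return d


DEFAULT_SPACE = SymbolSpace()


def lapse_mix(
    model_dist: Optional[np.ndarray], lam: float, space: SymbolSpace = DEFAULT_SPACE
) -> np.ndarray:
    """Mix a model distribution with the uniform lapse distribution."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lapse rate must lie in [0, 1]")
    if model_dist is None:
        return space.uniform()
    model_dist = np.asarray(model_dist, dtype=float)
    if model_dist.shape != (space.size,) or model_dist.min() < -1e-12 or not math.isclose(
        model_dist.sum(), 1.0, abs_tol=1e-9
    ):
        raise ValueError("malformed model distribution")
    return (1.0 - lam) * model_dist + lam / space.size


def sequence_loglik(
    dists: Sequence[Optional[np.ndarray]],
    response: Sequence[str],
    lam: float,
    space: SymbolSpace = DEFAULT_SPACE,
) -> float:
    """Log-likelihood (nats) of a response plus its terminating EOS.

    ``dists`` holds the model's pre-lapse distribution per position; entries
    beyond its length, or None entries, score as the uniform fallback. The
    response is scored symbol by symbol, with EOS appended at position
    ``len(response)``.
    """
    tokens = list(response) + [EOS]
    total = 0.0
    for t, sym in enumerate(tokens):
        pre = dists[t] if t < len(dists) else None
        p = lapse_mix(pre, lam, space)[space.index[sym]]
        if p <= 0.0:
            return -math.inf
        total += math.log(p)
    return total


@dataclass(frozen=True)
class ResponseRecord:
    participant_id: str
    task: str  # {fewshot, open_ended}
    trial_index: int
    query: tuple[str, ...]
    response: tuple[str, ...]
    assignment: Optional[Assignment] = None


class BehaviourDataset:
    """Per-participant query/response records with their word/colour assignments."""

    COLUMNS = ("participant_id", "task", "trial_index", "query", "response", "assignment")

    def __init__(self, records: Sequence[ResponseRecord]):
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.participant_id, None)
        return list(seen)

    def by_participant(self) -> dict[str, list[ResponseRecord]]:
        out: dict[str, list[ResponseRecord]] = {}
        for r in self.records:
            out.setdefault(r.participant_id, []).append(r)
        for recs in out.values():
            recs.sort(key=lambda r: r.trial_index)
        return out

    def subset(self, participant_ids: Sequence[str]) -> "BehaviourDataset":
        keep = set(participant_ids)
        return BehaviourDataset([r for r in self.records if r.participant_id in keep])

    def n_symbol_slots(self) -> int:
        """Total scored positions: response symbols plus one EOS per response."""
        return sum(len(r.response) + 1 for r in self.records)

    # -- tabular round trip ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            asg = ""
            if r.assignment is not None:
                asg = json.dumps(
                    {
                        "primitives": list(map(list, r.assignment.primitives)),
                        "functions": list(map(list, r.assignment.functions)),
                    },
                    sort_keys=True,
                )
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "task": r.task,
                    "trial_index": r.trial_index,
                    "query": " ".join(r.query),
                    "response": " ".join(r.response),
                    "assignment": asg,
                }
            )
        return pd.DataFrame(rows, columns=list(self.COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, colours: Sequence[str] = COLOUR_POOL
    ) -> "BehaviourDataset":
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        valid = set(colours)
        records = []
        for i, row in df.iterrows():
            response = tuple(str(row["response"]).split())
            bad = [s for s in response if s not in valid]
            if bad:
                raise ValueError(f"row {i}: unknown colour label(s) {bad}")
            asg = None
            raw = row.get("assignment", "")
            if isinstance(raw, str) and raw.strip():
                d = json.loads(raw)
                asg = Assignment(
                    primitives=tuple((w, c) for w, c in d["primitives"]),
                    functions=tuple((k, w) for k, w in d["functions"]),
                )
            records.append(
                ResponseRecord(
                    participant_id=str(row["participant_id"]),
                    task=str(row["task"]),
                    trial_index=int(row["trial_index"]),
                    query=tuple(str(row["query"]).split()),
                    response=response,
                    assignment=asg,
                )
            )
        return cls(records)

    @classmethod
    def from_tsv(cls, path: str | Path, colours: Sequence[str] = COLOUR_POOL) -> "BehaviourDataset":
        return cls.from_frame(pd.read_csv(path, sep="\t", keep_default_na=False), colours)


# -- models -----------------------------------------------------------------


class BehaviourModel:
    """Base class: per-position predictive distributions + lapse fitting."""

    name = "behaviour-model"

    def __init__(self, space: SymbolSpace = DEFAULT_SPACE):
        self.space = space

    def position_dists(
        self, record: ResponseRecord, history: Sequence[ResponseRecord] = ()
    ) -> list[Optional[np.ndarray]]:
        """Pre-lapse distribution per scored position (incl. the EOS slot).

        Returns one entry per position 0..L where L = len(record.response);
        None marks positions where the model makes no prediction.
        """
        raise NotImplementedError

    def loglik(self, dataset: BehaviourDataset, lam: float) -> float:
        total = 0.0
        for recs in dataset.by_participant().values():
            for i, rec in enumerate(recs):
                dists = self.position_dists(rec, history=recs[:i])
                total += sequence_loglik(dists, rec.response, lam, self.space)
        return total

    def fit(self, dataset: BehaviourDataset) -> "LapseFitResults":
        """Maximize the total log-likelihood over the lapse rate in [0, 1]."""
        if len(dataset) == 0:
            raise ValueError("dataset is empty")

        res = minimize_scalar(
            lambda lam: -self.loglik(dataset, lam),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam = float(np.clip(res.x, 0.0, 1.0))
        # bounded search never probes the endpoints; take them if better
        ll = -res.fun
        for edge in (0.0, 1.0):
            ll_edge = self.loglik(dataset, edge)
            if ll_edge > ll + 1e-12:
                lam, ll = edge, ll_edge
        return LapseFitResults(
            model=self, lambda_=lam, loglik=ll, n_responses=len(dataset),
            n_slots=dataset.n_symbol_slots(),
        )


@dataclass
class LapseFitResults:
    """Lapse-rate fit of a behaviour model: estimates and diagnostics."""

    model: BehaviourModel
    lambda_: float
    loglik: float
    n_responses: int
    n_slots: int

    def summary(self) -> str:
        lines = [
            "Lapse-rate fit",
            "=" * 46,
            f"model:               {self.model.name}",
            f"responses:           {self.n_responses}",
            f"scored positions:    {self.n_slots}",
            f"lambda (lapse rate): {self.lambda_:.4f}",
            f"log-likelihood:      {self.loglik:.1f} nats",
            "=" * 46,
        ]
        return "\n".join(lines)


class UniformBaselineModel(BehaviourModel):
    """Samples symbols uniformly from S at every position; lambda has no effect."""

    name = "baseline (uniform)"

    def position_dists(self, record, history=()):
        return [self.space.uniform()] * (len(record.response) + 1)


class OracleModel(BehaviourModel):
    """Assumes the task grammar is inferred perfectly; errors are lapses.

    The prediction for each query is a point mass on the algebraic output of
    the gold grammar under the record's word/colour assignment.
    """

    name = "symbolic (oracle)"

    def predict_sequence(self, record: ResponseRecord) -> tuple[str, ...]:
        if record.assignment is None:
            raise ValueError("oracle needs the record's assignment")
        return gold_grammar(record.assignment).evaluate(record.query)

    def position_dists(self, record, history=()):
        target = self.predict_sequence(record)
        dists: list[Optional[np.ndarray]] = [self.space.delta(s) for s in target]
        dists.append(self.space.delta(EOS))
        n_extra = len(record.response) + 1 - len(dists)
        if n_extra > 0:
            dists.extend([None] * n_extra)
        return dists[: len(record.response) + 1] if len(dists) > len(record.response) + 1 else dists


@dataclass
class _Branch:
    """One outcome branch of the bias transform, as a factorized sequence law.

    ``factors`` has one distribution per output position; the branch emits
    EOS at position ``len(factors)`` and nothing beyond.
    """

    weight: float
    factors: list[np.ndarray]


class OracleBiasModel(BehaviourModel):
    """Oracle prediction passed through the bias-based transformation.

    The finite mixture over output sequences induced by the transform --
    algebraic output, one-to-one translation, or evaluation under each subset
    of argument-flipped two-argument functions -- is enumerated exactly and
    marginalized to per-position distributions (default), or scored as a
    whole-sequence mixture when ``scoring="sequence"``.
    """

    name = "symbolic (oracle/biases)"

    def __init__(
        self,
        config: BiasConfig = BiasConfig(),
        study: Optional[Sequence[ExamplePair]] = None,
        scoring: str = "position",
        space: SymbolSpace = DEFAULT_SPACE,
    ):
        super().__init__(space)
        if scoring not in ("position", "sequence"):
            raise ValueError("scoring must be 'position' or 'sequence'")
        self.config = config
        self.scoring = scoring
        self._study_override = list(study) if study is not None else None
        self._branch_cache: dict = {}

    # -- branch enumeration ------------------------------------------------

    def _study_for(self, record: ResponseRecord) -> list[ExamplePair]:
        if self._study_override is not None:
            return self._study_override
        from .tasks import fewshot_task  # deferred: tasks imports episodes

        key = record.assignment
        cached = self._branch_cache.get(("study", key))
        if cached is None:
            cached, _, _ = fewshot_task(record.assignment)
            self._branch_cache[("study", key)] = cached
        return cached

    def branches(
        self,
        query: Sequence[str],
        study: Sequence[ExamplePair],
        grammar: InterpretationGrammar,
    ) -> list[_Branch]:
        key = (tuple(query), tuple(p.input + ("->",) + p.output for p in study))
        cached = self._branch_cache.get(key)
        if cached is not None:
            return cached
        out = self._enumerate_branches(tuple(query), study, grammar)
        self._branch_cache[key] = out
        return out

    def _enumerate_branches(
        self,
        query: Sequence[str],
        study: Sequence[ExamplePair],
        grammar: InterpretationGrammar,
    ) -> list[_Branch]:
        cfg = self.config
        colours = grammar.output_vocab
        out: list[_Branch] = []

        def delta_branch(weight: float, seq: Sequence[str]) -> _Branch:
            return _Branch(weight, [self.space.delta(s) for s in seq])

        algebraic = grammar.evaluate(query)
        out.append(delta_branch(cfg.p_algebraic, algebraic))

        w_heur = 1.0 - cfg.p_algebraic
        if w_heur > 0.0:
            # one-to-one translation: per-position factorized law
            w_oto = w_heur * cfg.p_one_to_one_given_heuristic
            if w_oto > 0.0:
                known = isolated_primitive_map(study)
                factors = []
                for w in query:
                    if w in known:
                        factors.append(self.space.delta(known[w]))
                    else:
                        d = np.zeros(self.space.size)
                        for c in colours:
                            d[self.space.index[c]] = 1.0 / len(colours)
                        factors.append(d)
                out.append(_Branch(w_oto, factors))

            # noisy rule application: enumerate flip subsets
            w_rule = w_heur * (1.0 - cfg.p_one_to_one_given_heuristic)
            if w_rule > 0.0:
                two_arg = [
                    i
                    for i, r in enumerate(grammar.rules)
                    if len(r.variables) == 2 and r in grammar.function_rules
                ]
                p = cfg.p_flip_per_two_arg_function
                n = len(two_arg)
                for mask in range(2 ** n):
                    flips = [two_arg[b] for b in range(n) if mask >> b & 1]
                    w = w_rule * (p ** len(flips)) * ((1 - p) ** (n - len(flips)))
                    if w <= 0.0:
                        continue
                    rules = list(grammar.rules)
                    for i in flips:
                        r = rules[i]
                        a, b = r.variables
                        swap = {a: b, b: a}
                        rules[i] = type(r)(r.lhs, tuple(swap.get(s, s) for s in r.rhs))
                    flipped = InterpretationGrammar(
                        rules=rules,
                        input_vocab=grammar.input_vocab,
                        output_vocab=grammar.output_vocab,
                    )
                    try:
                        seq = flipped.evaluate(query)
                    except UnparseableError:
                        seq = algebraic
                    out.append(delta_branch(w, seq))
        return out

    # -- scoring -------------------------------------------------------------

    def _branch_dist_at(self, branch: _Branch, t: int) -> np.ndarray:
        if t < len(branch.factors):
            return branch.factors[t]
        if t == len(branch.factors):
            return self.space.delta(EOS)
        return self.space.uniform()  # branch has ended: no prediction

    def position_dists(self, record, history=()):
        grammar = gold_grammar(record.assignment)
        study = self._study_for(record)
        branches = self.branches(record.query, study, grammar)
        L = len(record.response) + 1
        dists = []
        for t in range(L):
            d = np.zeros(self.space.size)
            for b in branches:
                d += b.weight * self._branch_dist_at(b, t)
            dists.append(d / d.sum())
        return dists

    def loglik(self, dataset, lam):
        if self.scoring == "position":
            return super().loglik(dataset, lam)
        total = 0.0
        for rec in dataset:
            grammar = gold_grammar(rec.assignment)
            branches = self.branches(rec.query, self._study_for(rec), grammar)
            tokens = list(rec.response) + [EOS]
            like = 0.0
            for b in branches:
                p = 1.0
                for t, sym in enumerate(tokens):
                    mixed = lapse_mix(self._branch_dist_at(b, t), lam, self.space)
                    p *= mixed[self.space.index[sym]]
                like += b.weight * p
            total += math.log(like) if like > 0 else -math.inf
        return total

    def sequence_probs(
        self,
        query: Sequence[str],
        study: Sequence[ExamplePair],
        grammar: InterpretationGrammar,
    ) -> dict[tuple[str, ...], float]:
        """Exact pre-lapse probability of every output sequence (enumerated)."""
        probs: dict[tuple[str, ...], float] = {}
        colours = grammar.output_vocab
        for b in self.branches(query, study, grammar):
            partial: list[tuple[tuple[str, ...], float]] = [((), b.weight)]
            for f in b.factors:
                nxt = []
                for seq, w in partial:
                    for c in colours:
                        pc = f[self.space.index[c]]
                        if pc > 0:
                            nxt.append((seq + (c,), w * pc))
                partial = nxt
            for seq, w in partial:
                probs[seq] = probs.get(seq, 0.0) + w
        return probs

    def sample(
        self,
        rng: np.random.Generator,
        query: Sequence[str],
        study: Sequence[ExamplePair],
        grammar: InterpretationGrammar,
        lam: float = 0.0,
        max_len: int = 8,
    ) -> tuple[str, ...]:
        """Draw one response from the lapse-mixed transform mixture."""
        branches = self.branches(query, study, grammar)
        weights = np.array([b.weight for b in branches])
        b = branches[int(rng.choice(len(branches), p=weights / weights.sum()))]
        out: list[str] = []
        t = 0
        while len(out) <= max_len:
            mixed = lapse_mix(self._branch_dist_at(b, t), lam, self.space)
            sym = self.space.symbols[int(rng.choice(self.space.size, p=mixed))]
            if sym == EOS:
                break
            out.append(sym)
            t += 1
        return tuple(out)


class OpenEndedBiasModel(BehaviourModel):
    """Three-bias model of open-ended responding.

    Each input token is translated left-to-right into one output token
    (iconic concatenation + one-to-one). A token's colour is drawn in
    proportion to how often that word aligned with each colour in earlier
    pairs; a never-seen word draws uniformly from the colours unused so far
    in the participant's responses (mutual exclusivity), falling back to
    uniform over all colours when none remain. Alignment counts also include
    the already-produced prefix of the current response, so repeated words
    within one instruction translate consistently.
    """

    name = "symbolic (open-ended biases)"

    def __init__(
        self,
        colours: Sequence[str] = COLOUR_POOL,
        within_response_counts: bool = True,
        space: SymbolSpace = DEFAULT_SPACE,
    ):
        super().__init__(space)
        self.colours = tuple(colours)
        self.within_response_counts = within_response_counts

    def _token_dist(
        self,
        word: str,
        counts: dict[str, dict[str, float]],
        used_colours: set[str],
    ) -> np.ndarray:
        d = np.zeros(self.space.size)
        word_counts = counts.get(word)
        if word_counts:
            total = sum(word_counts.values())
            for c, k in word_counts.items():
                d[self.space.index[c]] = k / total
            return d
        unused = [c for c in self.colours if c not in used_colours]
        if not unused:
            unused = list(self.colours)
        for c in unused:
            d[self.space.index[c]] = 1.0 / len(unused)
        return d

    @staticmethod
    def _accumulate(counts, x: Sequence[str], y: Sequence[str]) -> None:
        for w, c in zip(x, y):  # position-wise up to the shorter length
            counts.setdefault(w, {}).setdefault(c, 0.0)
            counts[w][c] += 1.0

    def step_dists(
        self,
        x: Sequence[str],
        history: Sequence[tuple[tuple[str, ...], tuple[str, ...]]],
        y_partial_source: Optional[Sequence[str]] = None,
    ) -> list[np.ndarray]:
        """Pre-lapse distribution for each output position of one response.

        ``y_partial_source`` supplies the observed prefix tokens used for
        within-response count updates when scoring (teacher forcing); when
        None the caller must sample token by token via :meth:`sample_response`.
        """
        counts: dict[str, dict[str, float]] = {}
        used: set[str] = set()
        for hx, hy in history:
            self._accumulate(counts, hx, hy)
            used.update(hy)
        dists = []
        for t, w in enumerate(x):
            dists.append(self._token_dist(w, counts, used))
            if self.within_response_counts and y_partial_source is not None and t < len(y_partial_source):
                self._accumulate(counts, [w], [y_partial_source[t]])
        return dists

    def position_dists(self, record, history=()):
        hist_pairs = [(h.query, h.response) for h in history]
        dists: list[Optional[np.ndarray]] = list(
            self.step_dists(record.query, hist_pairs, y_partial_source=record.response)
        )
        dists.append(self.space.delta(EOS))  # model length = input length
        n_extra = len(record.response) + 1 - len(dists)
        if n_extra > 0:
            dists.extend([None] * n_extra)
        return dists[: len(record.response) + 1]

    def sample_response(
        self,
        rng: np.random.Generator,
        x: Sequence[str],
        history: Sequence[tuple[tuple[str, ...], tuple[str, ...]]],
        lam: float = 0.0,
        max_len: int = 8,
    ) -> tuple[str, ...]:
        counts: dict[str, dict[str, float]] = {}
        used: set[str] = set()
        for hx, hy in history:
            self._accumulate(counts, hx, hy)
            used.update(hy)
        out: list[str] = []
        t = 0
        while len(out) <= max_len:
            if t < len(x):
                pre = self._token_dist(x[t], counts, used)
            elif t == len(x):
                pre = self.space.delta(EOS)
            else:
                pre = None
            mixed = lapse_mix(pre, lam, self.space)
            sym = self.space.symbols[int(rng.choice(self.space.size, p=mixed))]
            if sym == EOS:
                break
            out.append(sym)
            if self.within_response_counts and t < len(x):
                self._accumulate(counts, [x[t]], [sym])
            t += 1
        return tuple(out)
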