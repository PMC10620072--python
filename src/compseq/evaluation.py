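"""Evaluation protocols: exact-match, likelihood comparison, chained
open-ended sampling/scoring, cross-validation and bias classification.

Exact match is judged against the task's gold interpretation grammar, with
performance averaged over random word/colour assignments. Human-likelihood
comparisons score total log-likelihood (nats) with a fitted lapse rate. The
open-ended task factorizes a joint response as a chain: response *i*
conditions on pairs 1..i-1 as study examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np

from .behavior import (
    DEFAULT_SPACE,
    EOS,
    BehaviourDataset,
    BehaviourModel,
    OpenEndedBiasModel,
    ResponseRecord,
    SymbolSpace,
    sequence_loglik,
)
from .episodes import ExamplePair
from .grammar import (
    COLOUR_POOL,
    WORD_POOL,
    Assignment,
    InterpretationGrammar,
    Rule,
    UnparseableError,
    gold_grammar,
    random_assignment,
)
from .net import SeqToSeqTransformer, encode_source
from .tasks import fewshot_task

__all__ = [
    "chance_exact_match",
    "EvalReport",
    "Responder",
    "OracleResponder",
    "NetResponder",
    "NetBehaviourModel",
    "eval_fewshot",
    "loglik_of_dataset",
    "open_ended_chain",
    "crossval_open_ended",
    "classify_response",
    "item_correlation",
    "mutual_exclusivity_rate",
    "participant_bias_rates",
]


def chance_exact_match(output_length: int, n_symbols: int = 6) -> float:
    """Probability of guessing a known-length output uniformly (e.g. 1/36 for length 2)."""
    return float(n_symbols) ** (-output_length)


class Responder(Protocol):
    """Anything that answers a query given in-context study examples."""

    def respond(
        self,
        study: Sequence[ExamplePair],
        query: Sequence[str],
        rng: Optional[np.random.Generator] = None,
    ) -> tuple[str, ...]:
        ...


class OracleResponder:
    """Answers with the gold-grammar output (needs the assignment's grammar)."""

    def __init__(self, grammar: InterpretationGrammar):
        self.grammar = grammar

    def respond(self, study, query, rng=None):
        return self.grammar.evaluate(query)


class NetResponder:
    """Wraps a trained transformer; greedy when rng is None, sampled otherwise."""

    def __init__(self, net: SeqToSeqTransformer):
        self.net = net

    def respond(self, study, query, rng=None):
        source = encode_source(study, query)
        if rng is None:
            return self.net.greedy_decode(source)
        return self.net.sample_decode(source, rng)


@dataclass
class EvalReport:
    """Few-shot evaluation summary across random assignments."""

    n_assignments: int
    greedy_exact_match: float
    sampled_exact_match: Optional[float]
    per_item_greedy: list[float]
    per_item_sampled: Optional[list[float]]
    longer_output_greedy: Optional[float] = None
    error_tallies: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_assignments": self.n_assignments,
            "greedy_exact_match": self.greedy_exact_match,
            "sampled_exact_match": self.sampled_exact_match,
            "per_item_greedy": self.per_item_greedy,
            "per_item_sampled": self.per_item_sampled,
            "longer_output_greedy": self.longer_output_greedy,
            "error_tallies": self.error_tallies,
        }


def _make_responder(obj, grammar) -> Responder:
    if obj == "oracle":
        return OracleResponder(grammar)
    return obj


def eval_fewshot(
    responder,
    rng: np.random.Generator,
    n_assignments: int = 100,
    n_samples_per_item: int = 0,
    responder_factory: Optional[Callable[[Assignment], Responder]] = None,
) -> EvalReport:
    """Exact-match evaluation on the few-shot task across random assignments.

    For each assignment, the task surface is regenerated, the responder
    decodes greedily (its best response) and optionally samples; exact match
    is judged against the gold-grammar output. ``responder`` may be the
    string ``"oracle"``, a :class:`Responder`, or None with a
    ``responder_factory`` building one per assignment.
    """
    n_items = None
    greedy_hits = None
    sampled_hits = None
    sampled_n = 0
    longer_hits = longer_n = 0
    tallies: dict[str, int] = {}
    for _ in range(n_assignments):
        assignment = random_assignment(rng)
        study, query, grammar = fewshot_task(assignment)
        if responder_factory is not None:
            rsp = responder_factory(assignment)
        else:
            rsp = _make_responder(responder, grammar)
        if n_items is None:
            n_items = len(query)
            greedy_hits = np.zeros(n_items)
            sampled_hits = np.zeros(n_items)
        study_len_max = max(len(p.output) for p in study)
        for i, q in enumerate(query):
            gold = q.output
            got = rsp.respond(study, q.input, rng=None)
            hit = got == gold
            greedy_hits[i] += hit
            if len(gold) > study_len_max:
                longer_n += 1
                longer_hits += hit
            if not hit:
                for lbl in classify_response(q.input, got, assignment, study):
                    tallies[lbl] = tallies.get(lbl, 0) + 1
            for _s in range(n_samples_per_item):
                s = rsp.respond(study, q.input, rng=rng)
                sampled_hits[i] += s == gold
                sampled_n += 1
    per_item = list(greedy_hits / n_assignments)
    report = EvalReport(
        n_assignments=n_assignments,
        greedy_exact_match=float(np.mean(per_item)),
        sampled_exact_match=(
            float(sampled_hits.sum() / sampled_n) if sampled_n else None
        ),
        per_item_greedy=per_item,
        per_item_sampled=(
            list(sampled_hits / (n_assignments * n_samples_per_item))
            if sampled_n
            else None
        ),
        longer_output_greedy=(longer_hits / longer_n if longer_n else None),
        error_tallies=tallies,
    )
    return report


# -- likelihood scoring ------------------------------------------------------


class NetBehaviourModel(BehaviourModel):
    """Scores behavioural records with a trained transformer's predictive
    distributions, lapse-mixed like every other model.

    Few-shot records are scored in the context of the task's study examples
    under the record's assignment; open-ended records use the participant's
    earlier (query, response) pairs as study examples.
    """

    name = "transformer"

    def __init__(self, net: SeqToSeqTransformer, space: SymbolSpace = DEFAULT_SPACE):
        super().__init__(space)
        self.net = net
        classes = net.config.output_classes  # symbols + EOS
        self._perm = [
            self.space.index[c if c != "<EOS>" else EOS] for c in classes
        ]

    def _source_for(self, record: ResponseRecord, history) -> list[str]:
        if record.task == "open_ended":
            study = [
                ExamplePair(input=h.query, output=h.response, tag="study")
                for h in history
            ]
        else:
            study, _, _ = fewshot_task(record.assignment)
        return encode_source(study, record.query)

    def position_dists(self, record, history=()):
        source = self._source_for(record, history)
        rows = self.net.response_distributions(source, record.response)
        out = []
        for row in rows:
            d = np.zeros(self.space.size)
            for j, k in enumerate(self._perm):
                d[k] = row[j]
            out.append(d)
        return out


def loglik_of_dataset(
    model: BehaviourModel,
    dataset: BehaviourDataset,
    lam: float,
    n_passes: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Total log-likelihood of a dataset under a model at a given lapse rate.

    With ``n_passes > 1`` the dataset is rescored under freshly randomized
    per-participant record orderings and word/colour relabellings, and the
    per-pass totals are averaged -- a no-op for models that are symmetric
    under those randomizations.
    """
    if n_passes <= 1:
        return model.loglik(dataset, lam)
    if rng is None:
        raise ValueError("n_passes > 1 needs an rng")
    totals = []
    for _ in range(n_passes):
        shuffled = _randomize_pass(dataset, rng)
        totals.append(model.loglik(shuffled, lam))
    return float(np.mean(totals))


def _randomize_pass(dataset: BehaviourDataset, rng: np.random.Generator) -> BehaviourDataset:
    word_perm = dict(zip(WORD_POOL, (WORD_POOL[i] for i in rng.permutation(len(WORD_POOL)))))
    col_perm = dict(zip(COLOUR_POOL, (COLOUR_POOL[i] for i in rng.permutation(len(COLOUR_POOL)))))
    records = []
    for pid, recs in dataset.by_participant().items():
        order = rng.permutation(len(recs))
        for new_idx, old_idx in enumerate(order):
            r = recs[int(old_idx)]
            asg = r.assignment
            if asg is not None:
                asg = Assignment(
                    primitives=tuple((word_perm[w], col_perm[c]) for w, c in asg.primitives),
                    functions=tuple((k, word_perm[w]) for k, w in asg.functions),
                )
            records.append(
                ResponseRecord(
                    participant_id=pid,
                    task=r.task,
                    trial_index=new_idx,
                    query=tuple(word_perm.get(w, w) for w in r.query),
                    response=tuple(col_perm.get(c, c) for c in r.response),
                    assignment=asg,
                )
            )
    return BehaviourDataset(records)


# -- open-ended chain --------------------------------------------------------


def open_ended_chain_sample(
    model: OpenEndedBiasModel,
    instructions: Sequence[Sequence[str]],
    rng: np.random.Generator,
    lam: float = 0.0,
) -> list[tuple[str, ...]]:
    """Sample a joint response chain: pair *i* becomes history for pair *i+1*."""
    if not instructions:
        raise ValueError("empty instruction list")
    history: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    responses = []
    for x in instructions:
        y = model.sample_response(rng, tuple(x), history, lam=lam)
        responses.append(y)
        history.append((tuple(x), y))
    return responses


def open_ended_chain(
    model: BehaviourModel,
    records: Sequence[ResponseRecord],
    lam: float,
    mode: str = "score",
    rng: Optional[np.random.Generator] = None,
) -> float | list[tuple[str, ...]]:
    """Score (or sample) one participant's chained open-ended responses.

    Scoring sums the stepwise log-likelihoods of the exact chain
    factorization; sampling requires an :class:`OpenEndedBiasModel` (or any
    model exposing ``sample_response``).
    """
    if mode == "sample":
        return open_ended_chain_sample(model, [r.query for r in records], rng, lam)
    total = 0.0
    recs = sorted(records, key=lambda r: r.trial_index)
    for i, rec in enumerate(recs):
        dists = model.position_dists(rec, history=recs[:i])
        total += sequence_loglik(dists, rec.response, lam, model.space)
    return total


def crossval_open_ended(
    model_factory: Callable[[BehaviourDataset], BehaviourModel],
    dataset: BehaviourDataset,
    k: int = 5,
    runs: int = 3,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Participant-level k-fold cross-validation of held-out log-likelihood.

    Per fold: build/fit the model (including its lapse rate) on the training
    participants, then score the held-out participants at the fitted lapse.
    Returns the fold-summed held-out LL averaged over ``runs`` random fold
    assignments.
    """
    rng = rng or np.random.default_rng(0)
    pids = dataset.participants()
    if len(pids) < k:
        raise ValueError("fewer participants than folds")
    run_totals = []
    fold_records = []
    for _run in range(runs):
        order = rng.permutation(len(pids))
        folds = [sorted(order[i::k]) for i in range(k)]
        total = 0.0
        for fi, fold in enumerate(folds):
            held = [pids[int(i)] for i in fold]
            train_ids = [p for p in pids if p not in held]
            assert not set(held) & set(train_ids)
            train_ds = dataset.subset(train_ids)
            model = model_factory(train_ds)
            fit = model.fit(train_ds)
            held_ds = dataset.subset(held)
            total += model.loglik(held_ds, fit.lambda_)
            fold_records.append({"run": _run, "fold": fi, "held_out": held})
        run_totals.append(total)
    return {
        "heldout_loglik": float(np.mean(run_totals)),
        "per_run": [float(t) for t in run_totals],
        "folds": fold_records,
    }


# -- response classification -------------------------------------------------


def classify_response(
    query: Sequence[str],
    response: Sequence[str],
    assignment: Assignment,
    study: Sequence[ExamplePair] = (),
) -> set[str]:
    """Label a response: algebraic, one_to_one, iconic_concat and/or other.

    * algebraic -- equals the gold-grammar output;
    * one_to_one -- one symbol per input word, with every primitive word
      mapped to its own colour;
    * iconic_concat -- for queries containing function 3, equals the
      evaluation under the gold grammar with function 3's arguments flipped
      (input order preserved in the output);
    * other -- none of the above.
    """
    query = tuple(query)
    response = tuple(response)
    grammar = gold_grammar(assignment)
    labels: set[str] = set()
    try:
        if grammar.evaluate(query) == response:
            labels.add("algebraic")
    except UnparseableError:
        pass

    # one-to-one in either flavour: every word translated to one symbol
    # (primitive positions carrying their own colour), or only the primitive
    # words translated, in input order, with function words skipped.
    prim = assignment.primitive_map
    word_by_word = len(response) == len(query) and all(
        response[i] == prim[w] for i, w in enumerate(query) if w in prim
    )
    primitives_only = response == tuple(prim[w] for w in query if w in prim)
    if word_by_word or primitives_only:
        labels.add("one_to_one")

    f3_word = assignment.function_map["f3"]
    if f3_word in query:
        flipped_rules = []
        for r in grammar.rules:
            if f3_word in r.lhs and len(r.variables) == 2:
                a, b = r.variables
                swap = {a: b, b: a}
                r = Rule(r.lhs, tuple(swap.get(s, s) for s in r.rhs))
            flipped_rules.append(r)
        flipped = InterpretationGrammar(
            rules=flipped_rules,
            input_vocab=grammar.input_vocab,
            output_vocab=grammar.output_vocab,
        )
        try:
            if flipped.evaluate(query) == response:
                labels.add("iconic_concat")
        except UnparseableError:
            pass

    if not labels:
        labels.add("other")
    return labels


def mutual_exclusivity_rate(dataset: BehaviourDataset) -> float:
    """Fraction of participants whose responses are all pairwise distinct."""
    per = dataset.by_participant()
    ok = sum(
        1 for recs in per.values() if len({r.response for r in recs}) == len(recs)
    )
    return ok / len(per)


def participant_bias_rates(
    dataset: BehaviourDataset, threshold: float = 0.5
) -> dict[str, float]:
    """Fraction of participants 'following' each bias.

    A participant follows a bias when strictly more than ``threshold`` of
    their applicable responses carry the label (one_to_one over all items;
    iconic_concat over items containing function 3). Mutual exclusivity is
    the all-unique-responses criterion.
    """
    per = dataset.by_participant()
    follows = {"one_to_one": 0, "iconic_concat": 0, "algebraic": 0}
    for recs in per.values():
        counts = {k: 0 for k in follows}
        applicable = {k: 0 for k in follows}
        for r in recs:
            if r.assignment is None:
                continue
            study, _, _ = fewshot_task(r.assignment)
            labels = classify_response(r.query, r.response, r.assignment, study)
            f3 = r.assignment.function_map["f3"] in r.query
            applicable["one_to_one"] += 1
            applicable["algebraic"] += 1
            if f3:
                applicable["iconic_concat"] += 1
            for k in follows:
                if k in labels and (k != "iconic_concat" or f3):
                    counts[k] += 1
        for k in follows:
            if applicable[k] and counts[k] / applicable[k] > threshold:
                follows[k] += 1
    n = len(per)
    out = {k: v / n for k, v in follows.items()}
    out["mutual_exclusivity"] = mutual_exclusivity_rate(dataset)
    return out


# -- item-level correlation --------------------------------------------------


def item_correlation(
    model_item_acc: Sequence[float],
    human_item_acc: Sequence[float],
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Pearson r between per-item accuracies with a two-tailed permutation p.

    Returns ``r`` as NaN (and p as None) when either vector is constant.
    """
    a = np.asarray(model_item_acc, dtype=float)
    b = np.asarray(human_item_acc, dtype=float)
    if a.shape != b.shape:
        raise ValueError("item vectors must have equal length")
    if a.std() == 0 or b.std() == 0:
        return {"r": float("nan"), "p": None, "n_items": len(a)}
    rng = rng or np.random.default_rng(0)
    r_obs = float(np.corrcoef(a, b)[0, 1])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(a))
        r_p = float(np.corrcoef(a[perm], b)[0, 1])
        if abs(r_p) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"r": r_obs, "p": p, "n_items": len(a)}
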