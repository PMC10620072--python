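# Methods

## The modelling problem

`compseq` studies systematic compositional generalization in sequence
transduction: given a handful of study examples pairing word sequences
(instructions) with output-symbol sequences (coloured circles), produce
outputs for novel instructions. The package implements four interlocking
pieces:

1. a **rewrite-rule semantics** (interpretation grammars) that defines what
   the correct, algebraic answer is;
2. a **meta-learning pipeline** that trains a standard encoder–decoder
   transformer across an endless stream of such tasks, each generated from a
   fresh latent grammar, so that in-context task inference emerges;
3. **probabilistic behaviour models** that describe how people actually
   respond — mostly algebraically, with residual inductive biases
   (one-to-one translation, iconic concatenation, mutual exclusivity) and a
   lapse rate;
4. **evaluation protocols** comparing models and (synthetic or imported)
   human cohorts by exact match and log-likelihood.

## Interpretation grammars

A grammar is an ordered rule list. Primitive rules map one word to one
symbol. Function rules have a left-hand side with exactly one literal (the
function name) and one or two variables: `u` variables bind a single
primitive word, `x` variables bind any non-empty string. The right-hand side
concatenates recursively evaluated arguments (length ≤ 8 slots). The final
rule is always iconic left-to-right concatenation.

Evaluation is whole-string matching with first-match rule priority and
backtracking: segmentations are enumerated leftmost-shortest over earlier
variables, and the first segmentation whose bound sub-strings all evaluate
recursively wins. This reproduces all five documented worked examples of the
few-shot task grammar and makes function 3 (which takes string arguments on
both sides) take scope over the narrower functions. A recursion-depth cap of
50 guards degenerate sampled grammars; task inputs (≤ 8 words) never
approach it.

The few-shot task grammar binds, under a canonical assignment: four
primitive colours; function 1 = triple repetition of a primitive argument
(`⟦u1 f1⟧ → ⟦u1⟧⟦u1⟧⟦u1⟧`); function 2 = wrapping
(`⟦u1 f2 u2⟧ → ⟦u1⟧⟦u2⟧⟦u1⟧`); function 3 = reverse concatenation of string
arguments (`⟦x1 f3 x2⟧ → ⟦x2⟧⟦x1⟧`). Assignments of 7 words (from a 9-word
pool) and 4 colours (from 6; two always unused) are re-randomized per
participant or evaluation pass. The colour of the fourth primitive is a
configurable default, since only three primitive colours are pinned down by
the documented examples.

### Reconstructed task surface

The exact 14 study / 10 query item lists of the original behavioural
experiment are not among this package's inputs. `tasks.py` ships a
**reconstructed, synthetic** surface satisfying the documented constraints:
the curriculum (primitives; two demonstrations per function; four function
compositions), the rule that query items differ from same-template study
items by more than one primitive substitution (single exception: a novel
primitive fed to function 1), two-symbol outputs (the 2.8%-chance items) and
query outputs longer than any study output. Comparisons against the actual
human data require the deposited item lists via the TSV import; all shipped
fixtures are generated.

## Episode generation

Meta-training episodes are sampled from a meta-grammar: 4 primitive rules by
injective word–colour pairing, 3 function rules with uniform arity
(1: name after the argument; 2: name between arguments), uniform u/x
argument classes, and a uniform RHS of 1–8 slots over the LHS arguments (not
forced to use every argument; a flag can force inclusion). Study (14) and
query (10) inputs are rejection-sampled uniform word sequences of uniform
length 1–8 that parse to outputs of length ≤ 8, unique within an episode,
with an attempt budget of 10⁴. Output symbols are flipped uniformly with
probability 0.01 (applied to study and query targets; configurable) to give
the decoder some robustness.

Novelty filtering canonicalizes grammars as sorted rule multisets (rule
order is irrelevant for identity) and, against the reserved few-shot task
grammar, additionally searches word/colour bijections with rule-shape
pruning, so no training or validation grammar is a relabelling of the test
task.

## Bias transform

Each query of an episode independently keeps its algebraic output with
probability 0.8; otherwise a fair coin picks between (a) a one-to-one
translation — each input word mapped left-to-right to one symbol, using the
study set's isolated primitive mappings where available and an independent
uniform symbol otherwise — and (b) a noisy rule application in which every
two-argument function flips its argument roles with probability 0.5,
resampled per query. The 0.8 reflects the measured human algebraic response
rate (80.7%). The transform never touches study pairs or query inputs.

## Behaviour models and lapse likelihoods

Responses are scored per position over S = 6 colours + end-of-sequence
(|S| = 7), each position mixed with a uniform lapse:
P(s) = (1−λ)·P_M(s) + λ/|S|, with the uniform fallback when the model makes
no prediction at a position. λ is fitted by bounded scalar maximization of
the total log-likelihood (tolerance 1e-6), with the interval endpoints
checked explicitly. Models follow a Model → fit() → Results convention; the
Results object carries λ̂, the total log-likelihood in nats and a summary
table.

* **Baseline** — uniform over S everywhere (λ-invariant).
* **Oracle** — point mass on the task grammar's output; all errors are
  lapses.
* **Oracle with biases** — the *exact finite mixture* over output sequences
  induced by the bias transform, enumerated (algebraic branch; factorized
  one-to-one branch; one branch per flip subset of the two-argument
  functions) and marginalized per position. Whole-sequence mixture scoring
  is available behind `scoring="sequence"`; the default is per-position,
  matching the per-symbol lapse formula. The enumeration is validated
  against Monte-Carlo simulation of the transform.
* **Open-ended three-bias model** — each input token is translated
  left-to-right into one output token, sampled in proportion to alignment
  counts of that word in earlier (input, response) pairs; a never-seen word
  draws uniformly from the colours unused in earlier responses (mutual
  exclusivity), falling back to uniform over all six when none remain.
  Responses to the seven instructions are chained: pair *i* joins the
  history for pair *i+1*, giving the exact factorization
  P(y₁..y₇|x₁..x₇) = Π P(yᵢ|xᵢ, x<ᵢ, y<ᵢ).

Two deliberate choices in the open-ended model: alignment counts for pairs
of unequal length use position-wise alignment up to the shorter length, and
counts also include the already-produced prefix of the current response, so
a word repeated inside one instruction translates consistently. Without
within-response updating the fully-bias-consistent joint pattern would not
be the modal sample.

## Transformer

A standard encoder–decoder transformer: 3+3 layers, 8 heads, 128-dim
embeddings, 512-dim feedforward, GELU, sinusoidal positional encodings,
dropout 0.1 — 1,392,775 parameters (embedding matrices untied from the
output projection). The encoder consumes the query tokens followed by the
study pairs (`|` between examples, `->` between input and output); the
layout is a fixed convention covered by round-trip tests. Teacher forcing
with right-shifted targets; padding masked out of the token-averaged
cross-entropy. Adam, batch 25 episodes (effective sequence batch
(14+10)·25 = 600 including the auxiliary copy queries), learning rate 1e-3
with one-epoch warm-up then linear decay to 5e-5. With a validation corpus,
the best parameters across 100-step intervals are kept; regimes without one
train to completion. Greedy decoding caps at 9 steps (8 symbols + end
marker) and breaks logit ties toward the lowest class index.

The network runs on a compact vectorized reverse-mode autodiff core written
for this package (`autodiff.py`); gradients are finite-difference checked in
the test suite. Norm placement is configurable: `post` (the standard
arrangement, default) and `pre`, which optimizes more stably in the
very-small-model regime used for CPU-scale experiments. Embedding tables are
initialized at std 1/√d so token identity and positional encodings enter at
comparable scale. Float32 mode (`set_default_dtype`) roughly halves step
time.

### Training regimes

All regimes share the architecture and optimizer and differ only in stream
preparation: *algebraic-only* (raw episodes), *full* (bias-transformed
queries), *copy-only* (queries replaced by study items), *open-ended*
(participant-derived episodes, 0–5 study pairs), *joint* (few-shot +
open-ended + bridge episodes with study counts uniform 0–14), and the
*basic seq2seq* control: the same network with no study context, trained on
the 14 study items for 1,000 epochs with the best checkpoint chosen by
**test** loss — a deliberately favourable concession replicated as part of
the protocol — then greedy-decoded on the 10 queries.

## Problem sizes for CPU-scale runs

Full-scale meta-training (100,000 episodes × 50 epochs) is out of reach on a
CPU; the package's own experiments use reduced conditions, chosen once:

* The basic-seq2seq experiment keeps the full architecture and 1,000 epochs
  but aggregates over 3 runs instead of 10 (`scripts/acceptance.py`); the
  no-generalization outcome is insensitive to run count.
* The directional meta-learning comparison uses a pure lookup task —
  episodes over 4 words / 6 colours with no function rules, inputs of length
  ≤ 2, 4 study + 3 query items — a 2-layer, 4-head, 32-dim pre-norm model,
  batch 5, 6,000 episodes for 2 epochs, peak learning rate 2e-3. Exact match is measured
  on all held-out-episode instances (novel queries and in-context copy
  items), both of which require binding the episode's word–colour mapping
  from context; the no-context control is trained on the same instances with
  the study examples stripped. At this scale the meta-learner is far from
  ceiling — the claim tested is strictly-better-than-no-context, not
  human-level systematicity.

## What the synthetic cohorts do and do not show

The generators emulate the *statistical structure* of the behavioural data:
cohort sizes (25 few-shot / 29 open-ended), an 80.7% algebraic response
rate, the heuristic mixture, per-participant assignment randomization, and
chained open-ended responding with the three biases and a lapse rate. They
do not emulate attention lapses correlated across trials, learning within
the session, item-order effects, or the idiosyncratic instruction lists of
the original experiment. Passing the generator-fitter consistency tests
shows the likelihood machinery is correct and calibrated, not that the
models describe real participants; conclusions about real behaviour require
importing the deposited data through the TSV schema.

## Numerical choices

* Lapse optimization: `scipy.optimize.minimize_scalar(bounded)`, xatol 1e-6,
  endpoints compared explicitly (the optimum is frequently at λ = 0 on
  synthetic data).
* Distribution sanity: every emitted distribution must sum to 1 within
  1e-9; zero-probability scored positions return −inf rather than raising.
* Degenerate inputs: empty instructions are unparseable by definition;
  episode sampling raises after 10⁴ rejected proposals; the
  mutual-exclusivity fallback when all six colours are used is uniform over
  all colours.
* Greedy ties break to the lowest class index; all stochastic paths take an
  explicit `numpy.random.Generator`.

## Known limitations

* The scalable per-study-example encoding needed for long-context benchmark
  corpora is out of scope; the single concatenated source caps at
  14·18 + 8 = 260 tokens.
* CPU-scale meta-training demonstrates direction, not magnitude: headline
  full-scale results (near-perfect systematicity, human-likelihood table
  values for the trained transformer) require GPU-scale optimization.
* The one-to-one/iconic-concatenation participant "follows" statistics
  depend on an aggregation rule (majority of applicable responses,
  threshold configurable) that the source experiments did not pin down.
* Classification of one-to-one responses accepts both the word-by-word and
  the primitives-only readings (see the classification docstring); both are
  counted in the reported tallies.
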