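# compseq

Compositional sequence learning: interpretation grammars, meta-learned
seq2seq transformers, and models of human inductive biases.

## What problem this addresses

How do learners — human or neural — produce outputs for instructions they
have never seen, from just a few examples? A child who learns what "skip"
means can immediately "skip twice". `compseq` provides a complete,
CPU-friendly research stack for studying this kind of *systematic
compositional generalization* in an instruction-learning paradigm: short
pseudoword instructions (e.g. `dax fep`, `wif blicket dax`) must be
translated into sequences of abstract output symbols (coloured circles),
governed by a latent set of compositional rewrite rules.

It is aimed at computational cognitive scientists and machine-learning
researchers who want to (1) define few-shot seq2seq tasks through
**interpretation grammars**, (2) meta-train standard transformers across
streams of randomly generated tasks so that in-context task inference
emerges, (3) model behavioural response distributions — algebraic responding
mixed with **one-to-one**, **iconic-concatenation** and
**mutual-exclusivity** biases and a lapse rate — and (4) compare models and
cohorts by exact match and log-likelihood.

## The core objects

An interpretation grammar is an ordered list of rewrite rules with
first-match priority, e.g. (canonical assignment):

```
dax -> RED
wif -> GREEN
lug -> BLUE
zup -> YELLOW
u1 fep -> [u1] [u1] [u1]
u1 blicket u2 -> [u1] [u2] [u1]
x1 kiki x2 -> [x2] [x1]
x1 x2 -> [x1] [x2]
```

`u` variables bind one primitive word, `x` variables bind any non-empty
string; evaluation rewrites the whole input recursively, so
`wif blicket dax kiki lug` → `BLUE GREEN RED GREEN`.

Behavioural responses `y` to a query are scored per position over the six
symbols plus the end marker (|S| = 7) with a lapse rate λ:

    P(s) = (1 − λ) P_M(s) + λ / |S|

and every behaviour model (uniform baseline, grammar oracle, oracle with
the bias transform, the open-ended three-bias model, or a trained
transformer) plugs into the same `fit()` / Results machinery.

## Worked example

```python
import numpy as np
from compseq import gold_grammar, random_assignment
from compseq.behavior import OracleModel, OracleBiasModel, UniformBaselineModel
from compseq.synth import simulate_fewshot_cohort, ParticipantProfile

g = gold_grammar()
print(g.evaluate(("dax", "kiki", "lug")))        # ('BLUE', 'RED')

rng = np.random.default_rng(0)
cohort = simulate_fewshot_cohort(rng, n_participants=25,
                                 profile=ParticipantProfile(lapse=0.05))
for model in (UniformBaselineModel(), OracleModel(), OracleBiasModel()):
    fit = model.fit(cohort)
    print(f"{model.name:28s} lambda={fit.lambda_:.3f}  LL={fit.loglik:8.1f}")
```

prints

```
('BLUE', 'RED')
baseline (uniform)           lambda=1.000  LL= -2570.5
symbolic (oracle)            lambda=0.175  LL= -1015.0
symbolic (oracle/biases)     lambda=0.051  LL=  -911.4
```

Reading: the cohort was generated at an 80.7% algebraic response rate with
a 5% lapse. The uniform baseline scores each of the 1,321 scored positions
(response symbols plus end markers) at ln(1/7) regardless of λ. The oracle
must explain every heuristic error as a lapse, inflating λ̂ to 0.18; the
oracle-with-biases model recovers a λ̂ near the generating 5% and gains
~100 nats, because the one-to-one and argument-flip branches of its
enumerated mixture absorb the structured errors.

Training the no-context transformer control on the 14 study items:

```python
from compseq.net import NetConfig, TrainConfig, train_basic_seq2seq
from compseq.tasks import fewshot_task

study, query, _ = fewshot_task()
res = train_basic_seq2seq(study, query, NetConfig(), TrainConfig(seed=0),
                          n_epochs=1000)
print(res.train_exact_match, res.test_exact_match)   # 1.0 0.0
```

It memorizes all 14 study items but exactly matches 0/10 held-out queries:
without in-context study examples there is no route to the episode's
word–colour binding, so no systematic generalization.

## Command line

```bash
compseq generate-episodes --n-train 1000 --n-val 20 --seed 0 --out corpus/
compseq train --regime meta-bias --episodes corpus/ --seed 0 --out ck.npz
compseq eval-fewshot --checkpoint ck.npz --assignments 100
compseq simulate-participants --task fewshot --n 25 --seed 0 --out cohort.tsv
compseq fit-symbolic --model oracle-biases --data cohort.tsv
compseq crossval --data cohort.tsv --k 5 --runs 3
```

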