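# traitjudge

Simulation and analysis of **staircase-controlled two-alternative trait
judgments** — the experimental paradigm in which a participant first rates,
on a 0–100 visual-analog scale, how well each adjective of a lexicon
describes themself (*self rating*) and a well-known other (*other rating*),
and then repeatedly judges whether briefly presented groups of four
adjectives better describe the self or the other, followed by a 0–100
confidence report.

The package is aimed at researchers in decision making and metacognition
who want to prototype, power-analyse or validate this paradigm and its
analysis pipeline with simulated observers before (or alongside) running it
with humans.

## The machinery

**Evidence and stimulus control.** Each word carries evidence
`e = self_rating − other_rating ∈ [−100, 100]`. Two weighted up-down
staircases (one per condition) move along the major diagonal of the rating
space: one step toward the incorrect-favouring side after a correct
response, 2–2–3 steps (cycling) toward the correct-favouring side after an
error, capped at ±100. Expected movement vanishes at

```
p* = mean(up) / (mean(up) + down) = (7/3) / (7/3 + 1) = 0.7
```

so the task holds every observer near 70 % correct. Words for a trial are
drawn with probability proportional to an isotropic 2-D Gaussian centred on
the staircase position, divided by a kernel-density estimate of the
lexicon's occupancy of the evidence scale, so over-populated regions of `e`
are not over-represented; four words are drawn without replacement and
shuffled.

**Analyses.**

* *Choice functions*: per-trial stimulus strength (mean target-dimension
  rating minus mean non-target rating, scaled by its per-participant SD),
  logistic regression of correctness on strength per participant ×
  condition × confidence level (per-participant median split).
* *Reverse correlation*: per-word fluctuations around the staircase-centre
  expectation, normalised and averaged conditional on the choice, give a
  2 (chosen / non-chosen) × 4 (word position) matrix of **decision
  weights**; high- minus low-confidence decision weights give **confidence
  weights**.
* *Inference*: two-way repeated-measures ANOVA with generalized eta squared
  (η²_g), a mirror-image symmetry test (invert the non-chosen row and ask
  whether the congruence effect vanishes), and one-sample / paired t-tests.

**Simulated observers** choose by the sign of noisy mean evidence and
report confidence either from the absolute balance of evidence
(`balanced`) or from the chosen dimension only (`positive_evidence`), the
generative counterpart of decision-congruent, positive-evidence-biased
confidence.

## Worked example

```python
import numpy as np
import traitjudge as tj

lexicon = tj.generate_fixture_lexicon(104, rng_seed=1)
params = tj.ObserverParams()                     # balanced observer
rng = np.random.default_rng(11)
ratings = tj.generate_standard_ratings(lexicon, params, rng)
records = tj.run_session(lexicon, ratings, params,
                         tj.SessionConfig(n_trials=20_000), rng=rng)
print(f"accuracy {tj.accuracy(records):.4f}")
print(f"equilibrium {tj.equilibrium_accuracy():.2f}")
```

prints

```
accuracy 0.7000
equilibrium 0.70
```

— the staircase holds the simulated observer at its analytic 70 %-correct
equilibrium. Decision-weight symmetry on a batch of simulated balanced
observers (20 observers × 2000 trials):

```python
tables = []   # one session per observer, as above
for recs in sessions:
    tables.append(tj.decision_weights(recs)[0].values)
report = tj.symmetry_test(np.stack(tables))
print(report.raw_congruence.eta_g_sq, report.inverted_congruence.eta_g_sq)
```

gives a raw congruence effect of η²_g ≈ 0.84 that collapses below 0.01
once the non-chosen weights are inverted — chosen and non-chosen evidence
weigh on the simulated choices symmetrically, as a balance-of-evidence
rule must.

The same pipeline is available from the shell:

```
traitjudge make-fixtures --n-words 104 --seed 1 --lexicon lexicon.tsv
traitjudge simulate --lexicon lexicon.tsv --seed 7 --out log.csv
traitjudge analyze choice-functions log.csv --out fits.csv
traitjudge analyze weights log.csv --kind decision --out weights.csv
traitjudge analyze symmetry weights.csv
traitjudge analyze confidence-bias weights.csv
```

Every output is accompanied by a `.manifest.json` (config snapshot, seeds,
input digests) sufficient to reproduce it bit-exact.

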