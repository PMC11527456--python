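# Methods

## The paradigm being simulated

A participant supplies *standard ratings*: for each adjective of a
lexicon, a 0–100 rating of how well it describes themself and a second
rating for a well-known other. A word's evidence is
`e = self − other ∈ [−100, 100]`; the rating plane `[0,100]²` is the
stimulus space, and its major diagonal (`self + other = 100`) traverses
every value of `e`. In the judgment task proper, each trial presents four
adjectives; the participant decides whether the group better describes
the self or the other and then reports confidence on 0–100. "Correct"
means choosing the condition the trial's words were sampled to favour.

## Stimulus control

**Staircases.** One per condition, moving along the major diagonal,
capped at ±100. Start: the median `e` of the words favouring that
condition's correct response. Step size: the evidence range divided by 20
(10 on the theoretical ±100 scale; a per-participant empirical-range mode
is available via `use_empirical_range`). After a correct response the
staircase moves one step toward the incorrect-favouring side; after an
error it moves 2, 2 or 3 steps (cycling in that order, cursor kept per
staircase, not advanced by correct responses) toward the correct-favouring
side. Expected displacement is zero at accuracy
`mean(up)/(mean(up)+down) = (7/3)/(10/3) = 0.7`.

**Word sampling.** Selection probability ∝ isotropic 2-D Gaussian at the
staircase's diagonal position, divided by a Gaussian-KDE estimate of the
lexicon's 1-D density on the evidence scale, so that the sampled `e`
tracks the Gaussian's own marginal instead of the lexicon's occupancy.
Four words are drawn sequentially without replacement (renormalising after
each draw) and shuffled uniformly. Computation is done in log space; if a
centre is so remote that all weights underflow, mass falls back to the
nearest word with a logged warning.

The per-condition Gaussian width starts at `sigma_scale` × the distance
between the two staircases' start positions and is then *calibrated*: by
simulated draws at each start position, the two widths are rescaled until
the variances of the sampled words' ratings agree across conditions within
a relative tolerance (default 0.1, geometric-mean target, damped updates,
best iterate returned on non-convergence).

**Display durations** (metadata only in simulation) come from a
full-factorial linear model of lexical decision time in letters, syllables
and log10 frequency; the on-screen time is the predicted decision time
minus 117 ms, floored at 200 ms because an unconstrained linear model can
predict arbitrarily short times while readable presentation cannot be.

## Simulated observers

* **Ratings**: per word, (self, other) from a bivariate normal, mean 50,
  SD 35 per dimension, correlation 0.3 (the other is similar but not
  identical), clipped to [0,100]. The SD of 35 makes the generated clouds
  span the whole visual-analog scale with realistic mass at the endpoints
  — important, because the staircases must operate well inside the word
  cloud. With narrow clouds the staircase band reaches the edge of the
  support, where the sampled evidence shrinks toward the cloud centre;
  that shrinkage is anticorrelated with the choice signal and can cancel
  the reverse-correlation weights entirely. A bias term for the self
  dimension exists and defaults to 0.
* **Choice**: `d = mean(self_i − other_i) + ε`, `ε ~ N(0, 15)` evidence
  units; choose "self" iff `d > 0` (fair coin at exactly 0). Decision
  noise 15 puts the 70 %-correct point near evidence 8, comfortably inside
  the staircase range, with accuracy above 0.9 toward the caps.
* **Confidence**: `balanced` — offset 50 + gain 2 × |d| + report noise
  (SD 10), clamped to [0,100]; `positive_evidence` — the same, but the
  signal is the mean rating on the *chosen* dimension centred at that
  dimension's expected (staircase-centre) value, ignoring the non-chosen
  dimension.

`sigma_scale` defaults to 0.5. The proportionality constant between the
start-position distance and the sampling width is a free design choice;
0.5 makes the stimulus-driven variance of the evidence comparable to the
decision noise, which is the regime in which reverse correlation can
resolve the generative weighting at realistic trial counts (and which
reproduces decision-weight magnitudes around ±0.15). Much smaller widths
leave the choice dominated by internal noise and the weights near zero.

## Analyses

**Stimulus strength** is the mean rating on the trial's target dimension
minus the mean on the non-target dimension, divided by the participant's
sample SD of these raw values *without mean-centering*. Zero therefore
still denotes a neutral stimulus; with centering, zero would denote the
staircase-held average difficulty (where accuracy is 0.7 by construction)
and the intercept of the choice function would no longer measure response
bias. Choice functions are maximum-likelihood logistic regressions of
correctness on strength, per participant × condition × confidence level;
complete separation and single-class cells are flagged as non-converged
(and excluded from aggregation, with a count) instead of producing runaway
coefficients. The confidence median split labels trials strictly above the
per-participant median "high", ties going to "low" — deterministic and
conservative for the high-confidence contrast.

**Reverse correlation.** Fluctuation = presented rating − expected
(staircase-centre) rating, per word and dimension, read from the trial log
so the analysis is decoupled from the sampler. Fluctuations are divided by
their per-participant, per-dimension SD pooled over trials and positions,
relabelled chosen / non-chosen by the trial's response, and averaged,
giving the 2 × 4 decision-weight matrix. Confidence weights are the
decision weights of high- minus low-confidence trials, computed (and
normalised) separately per confidence level.

**Inference.** The two-way repeated-measures ANOVA uses the classical
fully-within decomposition; generalized eta squared follows the
Olejnik–Algina convention (all within-subject error strata plus the
subject stratum in the denominator). No sphericity correction is applied:
the critical congruence factor has two levels and needs none, and the
four-level position effects are reported uncorrected. A vanished error
stratum is reported as an exact fit (flagged, F = 0 or ∞) rather than an
error. The symmetry test runs the congruence × position ANOVA on the raw
weights and again after negating the non-chosen row; mirror symmetry is
supported when the raw congruence effect is present but the post-inversion
effect size is below a smallness threshold (default η²_g < .01). Bayes
factors are deliberately out of scope; the effect-size smallness plays
their role in the report.

## What the synthetic data do and do not show

The generator reproduces the *mechanisms*: staircase equilibrium at 0.7,
density-corrected sampling, balanced-evidence choices, and the two
confidence rules whose contrast yields symmetric decision weights with
either symmetric (balanced) or chosen-only (positive-evidence) confidence
weights. It does not emulate human rating noise, bimodal or item-specific
rating distributions, lapses, serial dependence, response times, or
memory effects such as the recency advantage of the final word; passing
tests therefore validate the pipeline's correctness and sensitivity, not
any claim about human parameter values (human slopes, accuracies and
effect sizes depend on human noise levels and are not targets here).

Two quantitative caveats measured during development:

* The 1-D density correction divides by a function of `e` only, which
  stretches selection along the anti-diagonal; under the default
  conditions this induces a within-trial (self, other) correlation of
  about −0.1. The circular-Gaussian kernel alone (correction off) leaves
  the correlation at zero, which is the sense in which selection is
  uncorrelated.
* The corrected sampling marginal matches the Gaussian's `e`-marginal only
  as well as the KDE tracks the lexicon's density. Silverman's rule
  over-smooths mixture-like densities; the marginal-fidelity tests use a
  bandwidth factor of 0.15 on dense fixtures, while sessions default to
  Silverman (at 104 words any bandwidth is a compromise, and the session
  results do not hinge on it).

## Problem sizes and numerics

Simulated batches use 20 observers × 2000 trials (analysis recovery) and
single sessions of 20,000 trials (equilibrium), sizes at which every
reported contrast is far from its decision threshold while the whole test
suite stays fast. All randomness flows from explicit seeds through
`numpy.random.Generator`; sessions are bit-reproducible given a seed.
z-scoring and SD normalisation use the n−1 convention. File readers parse
floats in round-trip mode so write/read cycles are bit-exact.
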