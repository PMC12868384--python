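# Methods

`hrvent` implements a Bayesian multilevel analysis that links minute
ventilation (V̇E, L·min⁻¹) to heart rate (HR, bpm) during treadmill
running in physically active females, together with the upstream
cardiopulmonary-exercise-test (CPET) processing that defines the exercise
intensity domains and a downstream predictor for field HR logs.  Because
the motivating study's raw data are not publicly deposited, the package
also ships a synthetic-cohort generator whose defaults reproduce the
published cohort statistics and posterior medians; all statistical claims
in the test suite are made on those synthetic cohorts.

## Models

Both models share the Gaussian observation model

    V̇E_i ~ Normal(μ_i, σ_within)

with subject-varying coefficients

    β_{j[i]} = β + b_j,   b_j ~ MVNormal(0, S),
    S = diag(σ_β) · R · diag(σ_β).

**Exponential (single equation).**  μ_i = β0_{j[i]} · exp(β1_{j[i]} · HR_i),
two varying coefficients (scale, rate).  Priors: β0 ~ Student-t(3, 4.2, 2.5),
β1 ~ Student-t(3, 0, 2.5), all SDs half-Student-t(3, 0, 2.5), R ~ LKJ(1).

**Linear with domain interaction.**  With 0/1 indicators for the heavy and
severe domains (moderate as reference),

    μ_i = β0_j + β1_j·HR + β2_j·I[heavy] + β3_j·I[heavy]·HR
          + β4_j·I[severe] + β5_j·I[severe]·HR,

all six coefficients varying between subjects with a full (unstructured)
6×6 correlation matrix.  Priors: β0 ~ Student-t(3, 64.7, 24.3), other
coefficients Student-t(3, 0, 24.3), SDs half-Student-t(3, 0, 24.3),
R ~ LKJ(1).  HR enters in raw bpm (uncentered), matching the scale on
which the published intercepts are printed; the priors are applied to the
parameters exactly as printed.  Derived quantities follow the published
parameterization: per-domain marginal slopes β1, β1+β3, β1+β5; composite
intercepts β0, β0+β2, β0+β4; pairwise slope contrasts with the
probability of direction (fraction of posterior draws strictly below 0);
and the individual 95% prediction half-width 1.96·median(σ_within).

A documented typographical conflict in the source: the abstract prints the
moderate-domain slope as 0.19 while the results section and coefficient
table give 0.54 (0.19 is the between-subject SD of the slope).  The
package treats 0.54 as authoritative everywhere.

## Posterior computation

No probabilistic-programming backend is used; the package ships its own
No-U-Turn sampler (multinomial trajectory sampling, generalized U-turn
criterion, dual-averaging step size targeting 0.9 acceptance, divergence
declared at an energy error of 1000) over a dense Euclidean metric.  The
metric is seeded from model structure (Gauss–Newton blocks per subject and
for the fixed effects) and refined over Stan-style warm-up windows; window
estimates are shrunk toward the current metric with weight n/(n+dim+5),
since short windows cannot identify a dense covariance, and the
init-buffer transient is excluded.  Two safeguards bound the cost of
adaptation failures: a window update whose re-found step size is more
than 30× smaller than the current one is discarded (a poisoned
short-window estimate is worse than no update), and any chain whose final
step size ends up below 1% of the median across chains is re-run once
with a fresh derived seed.  Tree depth is capped at 7 before the first
metric update and at `max_treedepth` (default 8 in `sample_posterior`)
afterwards; healthy chains on these posteriors run at depth ≤ 6, so the
cap only bounds pathological trajectories.  The correlation-transform
recursion is compiled with numba when available (a pure-numpy fallback is
used otherwise).

Unconstrained coordinates: log-SDs (with Jacobians) and tanh-transformed
canonical partial correlations for R.  On that scale the LKJ(η) prior
plus transform Jacobian has the closed form used in `_nuts.corr_chol_batch`;
its correctness was checked against the known LKJ(1) marginals (uniform
correlation in 2-D, Beta(3/2, 3/2) scaled to (−1, 1) in 3-D).  The
correlation block (≤ 15 coordinates) is differentiated by central finite
differences on the exact recursion; every other gradient is analytic, and
the Metropolis correction always uses the exact joint density, so sampling
is exact regardless of gradient shortcuts.

Two parameterizations, chosen for the geometry that the informative
per-subject CPET designs (tens of observations per subject) induce:

* **Linear-domains model: exact marginalization.**  The model is a Gaussian
  linear mixed model, so the subject effects are integrated out
  analytically.  Per subject, y_j ~ N(X_j β, X_j S X_jᵀ + σ²I); via the
  Woodbury identity everything reduces to 6×6 algebra on the sufficient
  statistics (X_jᵀX_j, X_jᵀy_j, y_jᵀy_j).  The matrix
  M_j = (S⁻¹ + X_jᵀX_j/σ²)⁻¹ is evaluated in the S-form
  S·(I + X_jᵀX_j S/σ²)⁻¹, which stays stable when components of σ_β
  collapse toward zero (a region the posterior genuinely visits for the
  weakly identified interaction SDs).  NUTS runs on the 28 remaining
  parameters; for each retained draw the subject effects are drawn exactly
  from their conditional Gaussian b_j | y, θ ~ N(M_j X_jᵀr_j/σ², M_j), so
  the joint stationary distribution is the full posterior
  (Rao–Blackwellization, with conditionally independent — hence
  excellently mixing — subject effects).
* **Exponential model: subject-centered coordinates.**  The sampler works
  on each subject's own coefficients c_j = β + b_j (prior
  c_j ~ MVN(β, S)); the likelihood touches only the strongly identified
  c_j and β enters through the prior alone, which removes the additive
  β/deviation ridge.  A plain non-centered parameterization was tried
  first and saturated the maximum tree depth (~10³ gradient evaluations
  per iteration): with this much per-subject data the z_j·σ_β products
  form ridges a global metric cannot whiten.  Because the Gaussian random
  intercept admits negative subject scales (σ_β0 = 7.28 around
  β0 = 2.86 makes them common in synthetic cohorts), per-subject
  initialization profiles the scale over a rate grid instead of fitting a
  log-linear model, and each subject's metric block is the Gauss–Newton
  curvature at that subject's own coefficients — the exponential model's
  curvature varies as exp(2·c1·HR), so population-level blocks are wrong
  by orders of magnitude.

The exponential mean's exponent is clipped at 50; states beyond it get
−∞ likelihood (rejected), never an overflow crash.  Default sampler
settings follow the published configuration: 4 chains, 4000 iterations
per chain including 1000 warm-up ("iterations" is read as including
warm-up).  All fits in the test suite and acceptance script use 4×(500+500)
or smaller, which the recovery results show is ample for these posteriors.
Convergence is summarized by split-chain Gelman–Rubin R̂ on every scalar
parameter (fixed effects, SDs, correlations, subject effects); fits with
max R̂ > 1.05 are flagged in metadata and raise a warning.  Identical
zero-variance chains define R̂ = 1 by convention.

## CPET processing

Breath-by-breath traces are reduced to 15-s bin means (trailing partial
bin discarded; ventilatory equivalents computed as ratios of bin means).
A test is accepted as maximal if the V̇O₂ plateau criterion holds
(stage-mean increase < 2.1 mL·kg⁻¹·min⁻¹ between the last two complete
60-s stages) or at least two of: maximal RER > 1.1, max HR ≥ 90% of
(220 − age), final RPE ≥ 19.

The ventilatory thresholds are located by a deterministic two-segment
continuous piecewise-linear (hinge) least-squares search over candidate
breakpoints (≥ 3 bins per segment, ties broken earliest): VT1 is the
minimum-RSS breakpoint of V̇E/V̇O₂ with an upward slope change whose
local (3-bin) V̇E/V̇CO₂ slope is at most 10% of the post-break V̇E/V̇O₂
slope; VT2 is the first upward breakpoint of V̇E/V̇CO₂, constrained to
fall after VT1.  The original study determined thresholds visually by two
blinded investigators; the deterministic surrogate makes the pipeline
reproducible, and manually determined thresholds can be supplied instead.
The threshold bin itself belongs to the higher domain (half-open
intervals), consistently across segmentation and field prediction.

## Synthetic data

The generator reproduces, as defaults, the published study conditions:
19 subjects; cohort anchors VT1 HR 153 ± 9 (at ~80% HRpeak), VT2 HR
172 ± 9 (~90%), HRpeak 190 ± 6, peak speed 14 ± 1.5 km·h⁻¹, V̇O₂peak
2807 ± 419 mL·min⁻¹; incremental protocol 5-min warm-up at 6 km·h⁻¹ then
+1 km·h⁻¹ per minute at 1% incline; and per-domain HR supports 114–171
(moderate), 141–188 (heavy), 157–199 (severe), 114–199 overall.  Cohort
physiologies are Gaussian at the anchor means/SDs with rejection of
tuples violating warm-up HR < VT1 < VT2 < HRpeak ≤ 230 (the rejection
shifts realized means by well under 1 bpm).  Warm-up-end HR defaults to
57% HRpeak, the lowest relative HR observed in the study.

Regression datasets place a deterministic, evenly spaced HR design in
each subject's threshold-delimited domain intervals (20 points per domain
by default; 60 points across the full range for the single-equation
design — the source does not state its per-subject observation count, so
these are explicit package choices) and add Normal(0, σ_within) noise.
Incremental traces are built at 1 Hz from piecewise-linear ventilatory
equivalents in time: V̇E/V̇O₂ flat at 24 until HR crosses the subject's
VT1, then linear to 38 at exhaustion; V̇E/V̇CO₂ flat at 26 until VT2,
then linear to 32 (peak RER 38/32 ≈ 1.19).  Multiplicative Gaussian noise
(default 3%) is applied independently per breath to the V̇O₂, V̇CO₂ and
V̇E channels; HR stays smooth and monotone.  V̇O₂ flattens over the final
two stages when the plateau flag is on (planted stage-mean increase
1.0 mL·kg⁻¹·min⁻¹).

What the generator does *not* emulate: breath-timing irregularity, V̇O₂
on-kinetics and slow components, drift or artifacts in the HR signal,
menstrual-cycle effects, and day-to-day within-subject variability.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the models' own assumptions, not robustness to
real-world CPET messiness.  One consequence of taking the published
hyperparameters literally: with σ_β0 = 7.28 around β0 = 2.86, roughly a
third of synthetic subjects receive a negative exponential scale (a
negative-valued V̇E curve).  The fitting machinery handles this honestly
— the Gaussian random-effect model simply admits it — but it is a reminder
that these Gaussian hyperparameters caricature the real cohort.

## Field prediction

Field HR logs are labelled by HR alone: user-supplied VT threshold HRs
when available, else VT1 = 80% HRpeak and VT2 = 90% HRpeak, with
HRpeak = 220 − age when unmeasured.  The published linear-domain
equations are discontinuous at the boundaries; the discontinuities are
preserved and reported, not smoothed, and an optional hysteresis (e.g.,
5 s) suppresses label chattering around a boundary.  Predictions outside
the fitted/published per-domain HR support are flagged as extrapolations.
Prediction bounds are μ ± 1.96·σ_within (posterior medians when a fit is
supplied).  All outputs are in L·min⁻¹ (the source prints the prediction
intervals with a "bpm" unit, treated as a typographical slip).

## Model comparison and fit summaries

Pointwise log-likelihoods use subject-level μ_i.  PSIS-LOO smooths the
largest 20% of importance weights by a generalized-Pareto fit (via
arviz's `psislw`), flags observations with tail index k > 0.7, and
reports ELPD with SE = √(n·Var(pointwise)); model differences use the
paired SE on pointwise differences.  Bayesian R² is the modeled-variance
definition Var(μ)/(Var(μ)+σ²) per draw, computed with subject-level
(partial-pooling) μ.  Credible intervals are equal-tailed 95% intervals
with linear interpolation between order statistics, bit-for-bit
reproducible given the draws.

## Problem sizes and reproducibility

The acceptance script regenerates everything from scratch at the full
study conditions (19 subjects; 20 obs/subject/domain for the
linear-domains design, 60 obs/subject for the exponential design) and
fits with 4 chains × (500 warm-up + 500 draws).  A 19-subject cohort's
realized population coefficients carry irreducible sampling noise (the
cohort-mean HR slope has SD σ_β1/√19 ≈ 0.044 around the generative
0.54), so each reported quantity is the median over a few independent
replicate cohorts — the same estimand with smaller Monte-Carlo error.
On one CPU a linear-domains fit takes ~1.5 minutes and an exponential
fit ~1.5 minutes.  The test suite's replicate study uses a lighter design
(10 obs/subject/domain, 2 chains × (150+250), 10 replicate seeds), chosen
so the full suite exercises the complete pipeline many times while
remaining comfortably interactive; the recovery margins at that size are
still wide relative to the 10% tolerances checked.  All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence`; no
global random state is used anywhere.

## Known limitations

* The sampler is specialized to these two model forms; it is not a
  general-purpose PPL, and the marginalized path exists only for the
  Gaussian linear mixed model.
* Exact reproduction of the published real-data numbers (ELPD difference
  −163.70 ± 22.10; R² 0.977/0.957) is impossible without the undeposited
  data; on matched synthetic cohorts the package reproduces the
  qualitative conclusions (domain model strongly preferred by ELPD-LOO;
  R² ≈ 0.98 vs ≈ 0.96) and recovers the generative parameters.
* Threshold detection assumes a single dominant breakpoint per
  ventilatory-equivalent series within the search window, which the
  synthetic traces satisfy by construction; real traces with plateaus or
  artifacts may need manual windows or manual thresholds.
* The LKJ(1) prior with a full 6×6 correlation leaves most correlations
  prior-dominated at J = 19 subjects, exactly as the wide published
  correlation intervals suggest.
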