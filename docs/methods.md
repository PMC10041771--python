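# Methods notes

## The Embryo-Uterus model

A transfer cycle ends with 0, 1 or 2 gestational sacs at 12 weeks. The
EU model treats this count as the product of a latent cycle-level
receptivity indicator `R ~ Bernoulli(u)` and per-embryo viability
indicators `V_j ~ Bernoulli(e_j)`, independent of each other given `R`:
`sacs = R · Σ V_j`. Both `u` and `e_j` are logistic:

* `u = logit⁻¹(α)` — intercept-only by default. Cycle-level covariates
  can be declared (`EUModelSpec.u_terms`, linear terms), but even a bare
  intercept does real work: it induces the positive correlation between
  embryos transferred together, which is what lets double transfers with
  exactly one sac enter the likelihood instead of being dropped as
  "partially observable".
* `e_j = logit⁻¹(β′x_j)` — per-embryo features: female age, t2, and the
  cleavage intervals t3−t2 and t5−t4 (hours). Intervals rather than
  absolute times make the E part insensitive to the t=0 convention
  differences between IVF (insemination) and ICSI (injection); the t=0
  convention is therefore recorded as metadata and never "corrected".

Marginalizing the latent states gives the closed forms used everywhere
(`cycle_outcome_distribution`); a brute-force enumeration over the
2^(1+m) latent states serves as the test oracle for them.

Identifiability: on SET-only data the likelihood depends on `(u, e)`
only through the product `u·e`, so the U intercept is weakly identified
and `fit_eu_model` warns. DET cycles break the ridge (the twin/singleton
split depends on `u` and `e` separately), but it can stay shallow; see
Optimization.

## Splines

Non-linear E-part effects use restricted cubic splines in Harrell's
parameterization, normalized by the squared outer-knot span so basis
columns stay on the scale of `x`. df = 1 is a plain linear term; df = d
places d+1 knots at fixed sample quantiles — (0.10, 0.50, 0.90) for 3
knots, (0.05, 0.35, 0.65, 0.95) for 4, (0.05, 0.275, 0.50, 0.725, 0.95)
for 5 — using the linear-interpolation quantile estimator, pinned for
reproducibility. Knots are frozen into the fitted model and serialized
with it, so external validation always evaluates the original basis.

## Optimization

`fit_eu_model` maximizes the joint likelihood with L-BFGS-B on
internally standardized covariates (z-scored design columns,
coefficients back-transformed for reporting). Gradients are analytic.
Multi-start: a warm start at the plain logistic-regression solution for
the E part (any-sac outcome per embryo) with the U intercept at
logit(0.9), plus seeded random restarts (default 5). The optimizer runs
with projected-gradient tolerance 1e-8; because the U direction can be
nearly flat, `converged` is declared honestly at a gradient sup-norm of
1e-5 on the standardized problem. Inside the optimizer, log-probabilities
are floored at log(1e-300) so an impossible-observation step is steeply
penalized rather than propagating -inf; the public `log_likelihood`
still returns -inf for genuinely impossible observations, and a fit
whose optimum has zero likelihood raises.

The covariance estimate is the inverse of a central-finite-difference
Hessian of the (original-scale) negative log-likelihood at the MLE; it
is flagged `covariance_unreliable` when the Hessian's condition number
exceeds 1e10 — which does happen when a sample pushes `u` toward 1
(boundary of the flat direction), and such fits honestly fail
3-standard-error recovery checks.

## Model development

* **Backward elimination**: whole term blocks (all spline columns of a
  variable) are tested by likelihood-ratio test against the current
  model; the block with the largest p-value is removed while that
  p-value exceeds the threshold (default 0.3, the relaxed criterion used
  for prognostic models). Ties remove the later-listed candidate.
  Since the elimination rule is "remove if p > threshold", a threshold
  near 1 removes nothing and a threshold near 0 removes everything; a
  pure-noise term (uniform null p-value) is removed in about 70% of
  datasets at 0.3.
* **E-vs-U placement**: a covariate is tried in each part (spline in E,
  linear in U) and placed by AIC = 2k − 2·loglik over all parameters of
  both parts; exact ties go to E.
* **Spline df**: per variable, greedily in declaration order, the df in
  a small ladder (default 1, 2, 3) minimizing AIC is chosen, starting
  from the default of 2 df everywhere; knots are re-placed whenever a
  df changes. df adjustment runs after variable selection.

## Validation

* **Discrimination** is Harrell's concordance over pregnant /
  non-pregnant cycle pairs, ties counted 0.5, computed via midranks
  (exactly the all-pairs count, which the tests verify by O(n²)
  enumeration).
* **Calibration** is the slope and intercept of an IRLS logistic
  regression of outcome on logit(prediction) (statsmodels GLM; an
  independently coded Newton-Raphson solver is the test oracle).
  Constant predictions are rejected — the slope is undefined — so a
  degenerate intercept-only model cannot be "validated" for calibration.
* **Internal validation** is Harrell's optimism bootstrap restricted to
  SET cycles with the binary outcome "≥ 1 sac": refit on each resample
  of cycles, optimism = (performance of the resample model on the
  resample) − (on the original data), averaged and subtracted from the
  apparent metrics. By default replicates keep the model structure and
  frozen knots and refit coefficients only, warm-started at the original
  solution (a relaxed replicate gradient tolerance of 1e-6 keeps B=200
  affordable); re-running the full selection per replicate is available
  through the `refit` hook. Replicate predictions are clipped to
  [1e-12, 1−1e-12] before the calibration fit, because heavily overfit
  replicate models can saturate probabilities to exactly 0/1 in floating
  point; failed replicates are dropped, counted, and more than 20%
  failures is an error.
* **External validation** scores a frozen fit on a new cohort — all
  transfer types by default (`set_only` restricts), outcome "≥ 1 sac" —
  with 95% percentile-bootstrap CIs over resampled validation cycles
  (default 2000 replicates) and an equal-count 10-bin calibration curve.

## Synthetic cohorts

Real per-embryo morphokinetic datasets with transfer outcomes are not
publicly shareable, so `eupred.simulate` generates cohorts with the
structure the analysis assumes; all tests and the acceptance script run
on these. What it emulates, and the defaults:

* **Female age**: truncated normal on [18, 45]; clinic-A-like mean 34.4,
  sd 6.1 (median ≈ 34.3, IQR ≈ 30–39); clinic-B-like mean 35.6, sd 5.4.
* **Morphokinetics**: t2 ~ truncated normal (25.5 ± 3.5 h on [15, 40]);
  the increments t3−t2, t4−t3, t5−t4 are lognormal (medians ≈ 11, 1.2
  and 12 h) — constructive sampling guarantees the stage ordering.
  tPNa/tPNf and t6–t8 are filled in consistently but carry no signal.
* **Transfer policy**: DET only for women aged ≥ 38 or in a third or
  higher cycle. Scenarios sized to the two study cohorts pin the DET
  count exactly (706 cycles / 78 DET; 1064 / 210); other scenarios use a
  DET probability.
* **Outcomes**: drawn from a ground-truth EU model. Truth effects on
  the viability logit are themselves restricted-cubic-spline shaped
  (3 knots), with coefficients chosen so the logit peaks sit at ≈ 10 h
  for t3−t2, ≈ 12.5 h for t5−t4 and ≈ 25 h for t2 — inside the optima
  windows such cohorts show — and a linear age slope of −0.05/year.
  Using spline-shaped (rather than, say, quadratic) truths keeps the
  generating model inside the fitted model class, so "recover every
  coefficient within 3 SE" is a well-posed end-to-end check (the
  recovery fit uses the truth's own knots). The E intercepts (0.3769
  clinic-A-like, 0.2303 clinic-B-like, on the logit scale for a typical
  embryo) were calibrated once so the simulated SET pregnancy rates
  match the ~38.7% / ~37.2% of the emulated cohorts; the U intercept is
  2.2 (receptivity ≈ 0.90).
* **Covariates are sampled independently** (the two intervals do not
  overlap anatomically and no correlation structure is documented);
  annotation error, inter-observer disagreement, embryo-selection-
  before-transfer effects and between-year drifts in culture conditions
  are *not* modelled. Passing tests therefore demonstrate correctness
  of the machinery under the model's own assumptions, not clinical
  performance on real data.

Named scenarios: `clinicA-like`, `clinicB-like`, `null` (no covariate
effects, 600 cycles), `overfit-bait` (150 SET-only cycles, no effects —
for optimism checks), `recovery` (clinic-A-like truth at n = 2000 with
an unconditional 30% DET probability, so the U intercept is well
identified for coefficient-recovery runs).

## Problem sizes in the checked runs

The test suite and acceptance script run parameter recovery over 20
seeds at n = 2000, optimism direction over 20 seeds at B = 200
bootstrap replicates, calibration recovery at n = 50 000, and the
pipeline scenarios at their native 706/1064 cycles — sizes at which each
check's Monte-Carlo error is comfortably below its assertion band.
Stochastic-rate module examples (noise-term elimination, spline-df
selection) use 16–25 replicates at n = 800–2000.

## Known limitations

* The U part supports declared cycle-level covariates structurally, but
  only linear terms, and none of the packaged scenarios exercise them
  beyond the E-vs-U placement check.
* Triplet and higher-order transfers are out of scope (outcomes 0–2).
* Backward elimination automates a "manual" procedure as
  largest-p-first whole-block removal; other orderings a human analyst
  might take are not explored.
* The bootstrap default refits coefficients only; full per-replicate
  re-selection is supported but costs roughly a selection run per
  replicate.
* With no DET cycles (or very few), the U intercept estimate can drift
  to the boundary; results for `u` itself should then not be
  interpreted, though predictions `u·e` remain stable.
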