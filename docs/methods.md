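# Methods

## The prediction problem

Preeclampsia (new-onset hypertension ≥ 140/90 mmHg after 20 weeks' gestation
with proteinuria) is diagnosed in roughly 4–5% of nulliparous pregnancies.
Antenatal care produces a growing longitudinal record per woman — around 11
visits from week 10 with blood pressure, weight, hemoglobin, capillary
glucose, dipstick proteinuria, and symphysis-fundal height from week 24 —
and the clinically useful question is *sequential*: given everything
observed up to a landmark gestational week, what is this woman's risk now,
among women still undiagnosed and undelivered?

`pelandmark` implements a two-stage (landmarking) approximation to a joint
longitudinal–event model: population mean curves, then per-woman departure
features, then a per-outcome generalized linear model. A full shared-random-
effects joint likelihood (random effects common to the longitudinal and
event submodels) is deliberately out of scope; the two-stage version keeps
every step fast, transparent and separately testable, at the cost of
ignoring estimation uncertainty propagated between stages.

## Stage 1 — population mean trajectories

For each continuous marker, all visits of the non-preeclamptic women enter a
linear mixed model: fixed effects are a clamped cubic B-spline in
gestational age (days) with boundary knots at 56 and 300 and interior knots
at weeks 16/24/32 (days 112/168/224); one random intercept per woman;
REML estimation via statsmodels `MixedLM`. Symphysis-fundal height uses a
linear basis on [168, 300] days. The spline reproduces the characteristic
non-monotone shapes (blood pressure and hemoglobin dip in the second
trimester and rise toward term) without committing to a parametric form.

Numerical choices:

- Random intercept only by default. Random slopes are supported in the
  generator but default to zero so the stage-1 model is correctly specified
  for the synthetic data; a real analysis would revisit this.
- Zero-noise data lying exactly in the basis space makes the mixed model
  singular; the fitter detects an OLS residual RMS below 1e-8 and returns
  the exact least-squares coefficients (the interpolation limit).
- Evaluation outside the fitted gestational-age support is allowed but
  warning-tagged; the basis is clamped at its boundary knots.

## Stage 2 — u-scores

At landmark week `w`, only measurements with `ga_days < 7·(w+1)` (strictly
before the end of the completed week) are visible. A woman's residuals from
the stage-1 curve are regressed on an orthogonal quadratic polynomial in
time, centered at the midpoint of her own observed gestational ages and
scaled to weeks; Gram–Schmidt orthogonalization on her own time points makes
the three projections (level, trend per week, curvature per week²)
near-uncorrelated, which stabilizes the downstream logistic fit. The
batched implementation accumulates per-woman moment sums with
`numpy.bincount` and is tested to agree with the per-woman normal-equations
oracle to 1e-10.

Degenerate visit histories shrink toward the population mean rather than
dropping the woman: 2 observations → curvature 0, level/trend from the
exact line; 1 observation → the residual is the level; 0 observations → all
zero. Every at-risk woman therefore gets a feature vector without
imputation.

Raw coefficients are standardized (centered and scaled, z-score style)
against the non-preeclamptic women at risk at the same landmark; scales are
re-estimated per landmark because coefficient dispersion grows with
follow-up. A feature's scale requires ≥ 30 contributing women with enough
observations (≥ 1/2/3 for level/trend/curvature) and dispersion above 1e-8,
otherwise the marker's u-scores are zero-filled and flagged — in practice
this happens to symphysis-fundal height at week 24, where at most one
measurement can exist.

The categorical time-varying markers reduce to "capillary glucose ever
≥ 9 mmol/L" (boundary inclusive) and the maximum dipstick category (0/1/≥2;
0 if never measured) within the landmark window.

## Stage 3 — landmark risk models

The risk set at week `w` excludes women diagnosed before the end of the
week and women already delivered (the latter clause is forced by
landmarking logic even though only the first is usually stated). The same
risk-set rule serves all five outcomes: any preeclampsia; preterm/term
preeclampsia split by delivery before/at 259 days (37 completed weeks); and
the diagnosis-time variants. An aspirin-exclusion flag reruns everything
without aspirin users (~1.1% of women) as a sensitivity analysis.

The design matrix is deterministic: centered maternal age and height, dummy
encoding with the largest printed category as reference (Sweden, living
with partner, non-smoking, no infertility, blood group O) and `missing` as
its own level, 15 u-scores, the glucose flag, two proteinuria dummies — 56
columns in full. Columns constant within a risk set (e.g. a covariate with
prevalence 0) are dropped and recorded in the encoding metadata. Logistic
models are fitted by maximum likelihood; detected separation or
non-convergence triggers a refit with a weak ridge penalty (1e-4 on
standardized columns, intercept unpenalized) and a diagnostics flag —
rare covariates such as SLE can separate at moderate cohort sizes.

## Evaluation

AUC is the Mann–Whitney statistic (ties ½), identical to the trapezoidal
area under the step ROC with tied scores grouped. Its 95% CI uses the
DeLong structural-component variance with a normal approximation, clipped
to [0, 1]; perfect separation yields a zero-width interval, flagged by
construction. Detection rate at 10% FPR uses the most liberal threshold
whose empirical FPR ≤ 0.10 (step function, no interpolation — reproducible
and conservative), with a percentile CI from 2000 case/control-stratified
bootstrap resamples implemented as multinomial reweighting of the sorted
score groups. Evaluation is apparent (in-sample) by default; a holdout
flag splits subjects 50/50 by seed for honest synthetic benchmarking.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis consumes, not
physiology. All defaults are explicit config, calibrated to the printed
descriptives of the motivating nulliparous cohort:

- **Baseline covariates** drawn from the published category frequencies;
  maternal age N(29.33, 5.0) (marginal mean set so the non-preeclamptic
  subgroup mean is 29.3 y), height N(166.6, 6.5).
- **Outcome** via a logistic model on the encoded baseline covariates with
  log-odds roughly matching the published case/control contrasts; the
  intercept is solved numerically (Brent) so the marginal incidence equals
  the 4.4% target regardless of coefficient choices.
- **Event times**: diagnosis from a two-component normal mixture
  (preterm N(238, 14) vs term N(272, 8) days, 30% preterm — the source
  cohort's split is unpublished, so this is a free choice); delivery =
  diagnosis + Gamma(2, 5) days. Non-case delivery N(281, 10), floor 200.
- **Visits**: first visit N(72, 10) clipped to [49, 112] days, then gaps
  N(31, 5) → N(17, 3) → N(10, 2.5) across breaks at days 168/238,
  truncated at delivery; cases get Poisson(1.5) extra visits in the 4 weeks
  before diagnosis. These parameters are calibrated so median visit counts
  are 11 (without) and 12 (with preeclampsia). Visits continue after
  diagnosis until delivery — diagnosed women are removed by the risk-set
  rule, not by the generator.
- **Continuous markers**: cubic mean curves through anchor points with a
  second-trimester minimum for sbp/dbp/hb, linear 1 cm/week symphysis-fundal
  height (≈ ga/7); per-woman random intercepts (SDs 8/6/9/7/1.5 marker
  units) and visit noise (SDs 6/5/1/5/1.5). Diastolic pressure is floored
  at systolic − 5 to keep the recorded pair physiologic under independent
  noise. Optional rounding of blood pressure to the nearest 5 mmHg mimics
  clinical recording practice (off by default).
- **Preeclampsia departure**: with `u = max(0, t − (dx − L))/L` and lead
  time L = 35 days, the departure is
  `level·(1 − e^{−2u}) + trend·u + curvature·u²`, separately controllable
  per component and scaled globally by `departure_scale`. Defaults put most
  signal in curvature, sized so blood pressure reaches the diagnostic range
  (≥ 140/90) around diagnosis — which also makes a curvature-only departure
  detectable in a majority of cases against the control dispersion of
  per-woman quadratic coefficients.
- **Categoricals**: group-specific probabilities of ever-high glucose
  (3.3% / 5.3%) and of maximum dipstick category 1 / ≥2
  (10.5% & 1.3% / 26.0% & 44.4%); case dipstick elevations are placed at or
  after diagnosis − lead time, mimicking gestational proteinuria preceding
  diagnosis.
- Thrombosis history is carried as a covariate with default prevalence 0
  (no published counts to calibrate against); its constant design column is
  dropped automatically.

All randomness flows through one PCG64 generator, so cohorts are
bit-reproducible by seed across platforms.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: measurement error correlated across markers or
visits, informative visit timing beyond the diagnosis-linked extra visits,
missed measurements (every scheduled visit records every applicable
marker), covariate-dependent trajectory shapes, secular trends, and any
causal effect of aspirin. Absolute AUC levels on synthetic cohorts reflect
the configured signal strength, not clinical reality; the meaningful
synthetic results are comparative (gradients across landmarks and signal
magnitudes) and calibration of the descriptives.

## Problem sizes and test design

The test suite runs the full pipeline at 1,200–1,500 women, statistical
recovery checks at 8,000–20,000, and the landmark-gradient property at
20,000 women × 5 seeds with population curves fitted on a 3,000-woman
control subsample (the mean curve is estimated with ample precision there,
and controls are identical across departure-magnitude settings, so fitted
curves are reused within a seed). The acceptance script regenerates the
full 58,899-woman cohort. Coefficient-recovery assertions use a
multiplicity-aware joint criterion (all |z-errors| < 3.5, at most 3 of ~22
beyond 2 SE, strong predictors individually within 2 SE), since ~5% of
coefficients are expected outside 2 SE by chance.

## Known limitations

- Two-stage estimation ignores uncertainty in the population curves and
  u-score scales when fitting the risk models.
- In-sample (apparent) evaluation overstates performance; use `holdout`.
- The u-score quadratic summarises a whole visit history; slowly evolving
  departures far before the landmark are diluted.
- The ridge fallback changes the estimand slightly when triggered; it is
  flagged in the model diagnostics rather than hidden.
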