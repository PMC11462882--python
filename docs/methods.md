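# Methods

This note documents the statistical model, the conventions that required a
decision, the synthetic-data generator, and the numerical choices, in the
package's own terms.

## Estimands and estimation

For each entity `z` (m entities) the target is the standardized restricted
mean time lost to cause `j` within `τ` days: the population average of the
potential outcome had every patient been assigned to `z`. Estimation
proceeds in four stages.

1. **Episodes.** Claims tables are reduced to per-patient triples
   (time, status, entity) with status in {noncompliance, competing,
   censored}; see "Episode conventions" below.
2. **Nonparametric curves.** All-cause survival by the product-limit
   estimator; cause-specific cumulative incidence by Aalen–Johansen,
   with jumps `S(t−)·d_j/n_t`. Both are exact step functions; restricted
   means are exact rectangle integrals, so `RMST + Σ_j RMTL_j = τ` holds
   to float precision for every input.
3. **Pseudo-observations.** Leave-one-out jackknife pseudo-values for the
   RMST and each RMTL, computed *within each entity* (a pooled mode
   exists for sensitivity analysis). Entities need n ≥ 2; entities below
   a configurable floor (default 10) are flagged rather than dropped.
   The fast path exploits the fact that subjects sharing (time, status)
   have identical leave-one-out estimators, downdating the risk table
   once per unique pair; the naive n-refit oracle is retained and the two
   agree to ~1e-13 (both run in extended precision internally because the
   jackknife difference amplifies rounding by a factor n).
4. **Standardization.** IPTW (Hájek form), outcome regression
   (g-computation), and AIPW, all linear in the pseudo-values. Centered
   estimates subtract the unweighted across-entity mean. Standardized
   RMST is reported as `τ − Σ_j RMTL_j`, which makes the decomposition
   exact by construction for every estimator.

### Propensity model

Multinomial logistic regression of entity on the full confounder design,
ridge-penalized (intercepts unpenalized, features standardized to unit
variance internally), penalty chosen by 10-fold entity-stratified
cross-validated multinomial deviance over a log-spaced grid (1e-4..1e4,
17 points). Entities smaller than the fold count reduce the fold count
with a warning. Fitted probabilities below 1e-6 abort with a positivity
error rather than silently truncating; weight truncation is off by
default. Per-entity propensity quantiles are exported as an overlap
diagnostic.

### Outcome model

Per functional, ordinary least squares of the pseudo-values on entity
indicators plus *shared* confounder coefficients. Shared slopes are the
default because per-entity samples can be small (tens of patients);
entity-specific slopes are available behind a flag and are what a fully
saturated specification requires. Rank deficiency falls back to the
minimum-norm solution with a warning (counterfactual predictions are
invariant to the indeterminacy when the collinearity involves the entity
block).

### Design matrix

Intercept; natural cubic spline of age with 4 df (knots at age quantiles;
implemented as the `cr` partition-of-unity basis with one column dropped,
which spans exactly the intercept + 4-df natural-spline space and stays
full-rank next to entity indicators); sex; age-spline × sex interaction;
reference-coded index-year indicators; binary comorbidity/co-medication
flags. Constant columns are dropped with a warning.

### Inference

Patient-level bootstrap (B = 250 by default) keeping the original cohort
size; the whole estimation path — spline knots, propensity fit (CV
re-selection of the penalty by default; a fixed-penalty fast mode
exists), pseudo-values, standardization — is re-run per replicate.
Episode construction is deterministic per patient, so resampling the
per-patient episode rows is equivalent to rebuilding episodes from
resampled claims. Intervals are bias-corrected percentile (BC, not BCa):
`z₀ = Φ⁻¹(#{θ* < θ̂}/B)` with ties counted half, endpoints at the
`Φ(2z₀ ± z_{α/2})` percentiles by type-7 linear interpolation. Bonferroni
divides the family error α across entities; at B = 250 and m ≈ 100 the
required percentiles lie outside the empirical grid of order statistics,
so endpoints clamp to the replicate range and a warning marks them as
extrapolated. Replicates in which an entity vanishes are recorded as
missing for that entity and excluded from its interval, with counts
logged. Degenerate cases (all replicates equal) yield a zero-width
interval; BC endpoints are never silently clipped to bracket the point
estimate.

## Episode conventions

Day 0 is the index discharge; all intervals are half-open `[start, end)`
in integer days; τ = 365; months are days × 12/365 at reporting only.

* **Days supplied** = packages × package size × dose per unit / reference
  daily dose.
* **Supply pooling.** A running stock accrues at each fill and is
  consumed one day per outpatient day; early refills stockpile. Days
  inside a hospital stay consume nothing, and each discharge credits a
  tolerance (default 2 days), so a supply exhaustion can never fall on an
  inpatient day — this operationalizes "cessation cannot occur in
  hospital" without a separate shifting rule.
* **Grace window.** An exhaustion on day *e* becomes a cessation unless
  net-positive coverage is restored by day *e + grace* (default 30).
  Uncovered gap days are borrowed against the rescuing fill, so a fill
  must exceed the accumulated gap to rescue it. A fill restoring positive
  stock during a hospital stay also rescues (otherwise adding a stay
  could shorten an episode).
* **Recorded event time** is the exhaustion day — grace days are not
  days in compliance. The alternative convention (exhaustion + grace) is
  a config switch.
* **Ascertainment.** A cessation is declared only when the entire grace
  window is observed: a terminal event or administrative censoring
  striking inside the window takes precedence (competing events beat
  cessation on ties; censoring loses to any same-day event).
* Non-adherence is absorbing; re-initiation after a confirmed cessation
  is out of scope (that is the medication-possession-ratio estimand).

Sensitivity: narrowing the grace window from 30 to 7 days changes
cohort-level estimates only slightly when fills are approximately
back-to-back; this is asserted qualitatively in the test suite.

## Synthetic-claims generator

The generator emulates the *structure* of linked social-insurance claims;
it makes no attempt at realistic ICD/ATC coding, spatial correlation, or
informative censoring.

* **Confounders** (defaults): age ~ N(68, 14²); female ~ Bern(0.36);
  index year uniform on 2012–2015; ten binary comorbidity/co-medication
  flags with prevalences 0.05–0.45 — a deliberately scaled-down stand-in
  for the hundred-plus confounders of real claims. Effects are specified
  on standardized covariates using theoretical moments, so the ground
  truth does not depend on the sample.
* **Entity assignment**: multinomial logit with linear predictor
  `u_z · s(X)`, where `u_z` is an equispaced loading on [−1, 1] and
  `s(X)` a scalar confounder score — one-dimensional but genuine
  measured confounding.
* **Outcomes**: cessation time exponential with hazard
  `0.0055 · exp(entity effect + βᵀX_std)` per day, competing time
  exponential with constant hazard 0.0011 per day, both rounded up to
  whole days. The baseline hazards were set so the default cohort loses
  roughly half the year to non-adherence and a tenth of patients to
  competing events, matching the magnitudes typical of post-infarction
  statin persistence.
* **Fill stream**: back-to-back 30-day fills whose pooled supply
  exhausts exactly on the latent cessation day, then no further fills;
  no fills are observable after death or censoring. This makes builder
  recovery of the latent day *exact* and separates generator correctness
  from builder correctness. Hospital stays default to rate 0 for the same
  reason; a positive `stay_rate` generates outcome-independent stays to
  exercise the inpatient rules (recovery is then deliberately not exact,
  since stays extend coverage).
* **Censoring**: administrative, uniform on a configurable day range;
  the default (420–1095) leaves every patient observable through
  τ + grace, so ascertainment never interacts with censoring in the
  default study conditions. Early censoring is exercised via config.

### Ground-truth oracle

The standardized estimands are computed by a semi-analytic oracle that is
independent of the claims/episode path: confounders are drawn afresh
(default 5·10⁵ draws), every draw is counterfactually assigned to each
entity, and the conditional restricted means given the hazards are
evaluated *exactly in time* by geometric sums over whole days — including
the grace-window interaction (a cessation on day y counts only if the
competing time exceeds y + grace; otherwise the competing event is
recorded), mirroring the episode builder's convention precisely. Only
the confounder draw contributes Monte-Carlo error, which is reported.
With no confounder→outcome effects the same formulas are closed-form
exact. A brute-force day-mechanism simulation cross-checks the oracle in
the tests.

### What passing tests do and do not show

The generator's confounding is low-dimensional and its hazards
proportional by construction, so parameter-recovery results demonstrate
the estimators' correctness under the stated model, not robustness to the
messiness of real claims (dose switching, re-initiation, coding error,
unmeasured confounding). The bootstrap calibration study uses small
cohorts (n = 500) with two entities; coverage in large-m, small-n_z
regimes will be more optimistic than those results suggest, which is why
small entities are flagged.

## Problem sizes used in the checks

Simulation checks use m = 4 entities with n = 2,000 patients over 200
replicates for estimator bias and double robustness (with true
propensities and oracle conditional-mean outcome designs providing the
"correctly specified" arms), n = 20,000 for single-cohort recovery, and
500 replications × 200 bootstrap resamples at n = 500 for interval
calibration — sizes chosen to keep Monte-Carlo error a fraction of the
effects being measured while the whole suite stays conveniently
runnable on one CPU.

## Known limitations

* The pseudo-value outcome regression is linear in the design; under a
  log-hazard data-generating process a spline-plus-flags design is a
  (good) approximation, and a residual bias of order 1% of the estimand
  can remain for the pure outcome-regression estimator. The doubly
  robust estimator with a correct propensity model removes it.
* The Poisson comparator's intensity can exceed 1 per τ of person-time
  (its complement then goes negative); it is reported unclipped.
* No spatial smoothing, no sandwich variances for risk-factor
  coefficients, no medication-possession-ratio estimand, no map
  rendering — all out of scope.
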