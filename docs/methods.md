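# Methods

This document describes the statistical model behind `clockforge`, the default
parameter choices, and the known limitations of both the estimator and the
synthetic benchmark generator.

## 1. Problem setting

A *biological-age clock* is a regression model that predicts chronological age
from a panel of clinical blood biomarkers, trained only on samples from
healthy subjects. The interesting quantity is not the prediction itself but
the **age acceleration**: the gap between predicted (biological) age and
chronological age. In diseased or high-risk groups this gap is systematically
positive; it also predicts mortality hazard.

Two statistical obstacles dominate this design:

1. **Regression to the mean.** Any conditional-mean estimator trained on a
   bounded age range predicts too old at the young end and too young at the
   old end, producing an age-dependent skew in the acceleration that swamps
   group effects.
2. **Explanation validity.** Feature attributions for "why is this person
   predicted older" are only meaningful against an *age-matched* reference
   population, not the global training mean.

## 2. Pipeline

```
ingest/simulate -> label health -> select panel -> split (age-stratified)
  -> preprocess (trim, impute, scale) -> train MLP -> fit skew corrector
  -> (optional) panel reduction -> Shapley explanations -> group analysis
```

### 2.1 Health labelling

A sample is healthy iff it carries no ICD diagnosis codes and no chronic
medication (ATC codes with configurable chronic prefixes, default the C09
renin-angiotensin agents). Only healthy samples enter training, validation,
and the reference (test) distribution; unhealthy samples are scored but never
fitted on.

### 2.2 Preprocessing

* **Outlier trimming** removes, per biomarker, the top `outlier_fraction`
  (default 0.5%) of measured values; a sample extreme in any marker is dropped
  once, and the per-marker report counts every exceedance. Optionally
  two-sided.
* **Imputation** uses chained equations (scikit-learn `IterativeImputer`,
  ridge conditionals, median initialization) fitted on the training split
  only. Imputed matrices are floored at `impute_floor` (default 0 — lab
  values are non-negative; note the floor applies to the transformed matrix
  as a whole).
* **Scaling** is min–max to [0, 1] on the training range. Apply-time values
  outside the fitted range are *not* clipped; they scale linearly beyond the
  unit interval so that out-of-distribution inputs remain visible.
* **Sex** is encoded 0 (female) / 1 (male); unknown sex rows are dropped with
  a warning.

All fitted state is frozen in a `FittedPreprocessor`; applying it is
deterministic and leakage-free (nothing about validation/test data enters the
fit).

### 2.3 Clock

The regressor is a fully-connected ReLU MLP (default hidden sizes
(1000, 100)) trained with Adam on mini-batch MSE, implemented directly in
NumPy for full determinism. The split is stratified by integer age year
(sparse strata merged) into train/validation/test (default 60/20/20).

**Checkpointing.** `checkpoint="best_val"` restores the weights with the
lowest validation MSE; `checkpoint="last_step"` keeps the final weights.
Best-val selection minimizes MSE, which at equal fit quality prefers a
*shrunken* predictor (slope toward the mean) — exactly the geometry the skew
corrector must then undo, and a multiplicative shrinkage is not an additive
per-age offset. For experiments whose target is acceleration-gap recovery we
therefore train with a fixed step budget and `last_step`; for pure prediction
metrics `best_val` is the default.

### 2.4 Skew correction

Even a well-fit clock exhibits the regression-to-the-mean skew: the OLS slope
of prediction on age is < 1, so acceleration is negatively correlated with
age. The corrector:

1. computes the median raw prediction per integer age year on **training data
   only** (years with fewer than `min_count=10` samples excluded);
2. smooths these medians with kernel ridge regression
   (`alpha=0.001`, additive-χ² kernel) — a near-interpolating fit that
   regularizes only where per-year medians are noisy;
3. defines `offset(a) = smoothed(floor(a) + 0.5) − (floor(a) + 0.5)` and
   corrects `biological_age = raw − offset(age)`.

Two deliberate design points:

* **Bin-center convention.** The per-year medians are medians over samples
  whose ages span `[y, y+1)`; their natural abscissa is the bin center
  `y + 0.5`. Fitting the smoother at integer abscissae instead introduces a
  systematic −0.5 y bias into the corrected ages (the corrector would "think"
  the year-`y` median belongs to age `y` exactly). Both the fit and the
  evaluation therefore use bin centers.
* **Constant offset within a year.** The offset is a function of
  `floor(age)`, not of fractional age. Consequently, within any integer age
  year the correction subtracts one shared constant: prediction *ranks* are
  preserved exactly, the median moves by exactly the offset, and same-age
  group gaps are unchanged (to double-precision rounding of the shared
  subtraction, ≤ a few ulp). A fractional-age offset would trade these exact
  invariants for a marginally smoother correction.

Ages outside the fitted range are clamped to the boundary year and flagged.

**Degenerate-model caveat.** The corrector maps *any* monotone-in-age
prediction profile onto the identity — including a constant predictor, whose
corrected output is simply each sample's age-year center (MAE 0.25 y on
uniform ages). Corrected MAE therefore cannot certify model quality;
correction must follow, never substitute for, predictive signal (see the
uncorrected metrics reported alongside).

### 2.5 Explanations

Shapley attributions are computed by antithetic permutation sampling over the
feature set, with the background expectation taken over an **age-matched
background**: healthy training samples within ±`window` years (default 2) of
the explained sample's age, widened until `min_background` samples are found
(widening is reported). Because the value function telescopes over each
permutation, local accuracy `Σφ + base = prediction` holds to machine
precision by construction, for any number of permutations; more permutations
only reduce the variance of individual φᵢ. For linear models the closed form
`φᵢ = wᵢ(xᵢ − x̄ᵢ)` is used directly. When a corrector is supplied the report
also carries `adjusted_base = base − offset(age)` so attributions can be read
on the corrected scale.

### 2.6 Panel reduction

Reduction to a smaller assay panel proceeds: (i) greedy correlation pruning
(drop the lower-measurement-count member of any pair with |r| above the
threshold), (ii) optional cost-based exclusions, then (iii) repeated
retrain-and-eliminate: retrain the clock on the surviving panel, rank
features by mean |age-matched Shapley attribution| on the validation split,
remove the bottom *k* (schedule, default (5, 5) then 1 at a time) until the
target size. The sex code is ranked but exempt from elimination. The trace
telescopes: each step's surviving panel is exactly the previous minus that
step's removals.

### 2.7 Acceleration analysis

Group accelerations are compared to the healthy test distribution with
two-sided Mann–Whitney U tests (exact enumeration for small groups, asymptotic
with tie correction otherwise), Bonferroni-adjusted across groups, with
bootstrap 95% CIs on group medians. Mortality is analyzed with Cox
proportional-hazards models (lifelines) in three nested adjustment tiers
(acceleration only; + age; + age, sex, BMI), after excluding accidental
deaths and subjects older than 79 at sampling. Decile-stratified survival
uses covariate-adjusted baseline survival curves evaluated at the stratum
means.

## 3. Synthetic benchmark generator

Real cohorts of this kind are proprietary, so all acceptance properties are
checked on generated cohorts with a ground-truth sidecar the pipeline never
reads.

* Each subject carries a latent biological-age offset δ ~ N(0, σ_b²)
  (default σ_b = 5 y). Diseases are exclusive assignments that add a further
  Δ years. Biomarkers respond to **effective age** = age + δ + Δ, so a
  planted Δ is recoverable as a predicted-age displacement by any consistent
  regressor — the central property the acceptance tests rely on.
* Informative markers are pinned at a noise level of 9 age-equivalent years
  each (noise_sd = 9·|slope|): individually weak, jointly a 7-marker panel
  determines effective age to roughly ±3.4 y, matching the error regime of
  real clinical clocks.
* Missingness is block-structured (lab panels drop together) at 22% of cells
  by default.
* Mortality is inversion-sampled from a Gompertz hazard
  `h(t) = r·exp(b·(age+t) + β·δ)` with a flat competing accidental hazard;
  default β = 0.05 per δ-year.
* The longitudinal generator adds per-subject diagnosis years and a linear
  pre-diagnosis latent drift (`drift_rate` y/y over `drift_window` years);
  ICD codes appear only at/after diagnosis.

### Known generator/estimator interactions

These are properties of the design, documented rather than hidden:

* **Boundary attenuation.** A conditional-mean predictor attenuates planted
  offsets within roughly two total standard deviations (σ_b plus
  marker-estimation noise, ≈13 y at defaults) of the training age-range
  boundary — the same geometry the corrector addresses at the population
  level cannot be removed per-sample. Planted-offset recovery is therefore
  assessed with disease ages drawn from the interior (30–60 for a +5 y
  plant, so *effective* ages also stay clear of the 80 y edge).
* **Imputation dilution.** With 22% missing cells imputed from the healthy
  conditional distribution, a planted offset is partially replaced by the
  healthy expectation in imputed cells; the measured sensitivity of the
  default clock to a per-sample offset at fixed age is ≈0.9 rather than 1.0.
  Bootstrap CIs on group medians comfortably cover the planted value at the
  benchmark sizes.

## 4. Reproducibility

Every stochastic stage takes an explicit seed; the pipeline fans a single
global seed out to per-stage seeds by stable hashing (CRC32 of
`"{seed}:{stage}"`). Re-running an identical config reproduces bit-identical
metrics and artifact digests (recorded in the run manifest). The corrector
state depends only on its training inputs and serializes to JSON for
auditing.

## 5. Limitations

* The generator does not calibrate realistic biochemical covariance or
  within-subject autocorrelation beyond the drift model; absolute metric
  values (R², MAE) on synthetic data are not comparable to clinical cohorts.
* The corrector assumes enough per-year training density (`min_count`) for
  stable medians; outside the fitted age range it falls back to boundary
  offsets.
* Permutation Shapley with few permutations gives exact local accuracy but
  noisy per-feature values; ranking-sensitive uses (reduction) average over
  multiple explained samples to compensate.
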