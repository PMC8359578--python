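# Methods

This note records the modelling assumptions, numerical conventions and
design decisions behind `bioage`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort handling

The unit of analysis is one patient at an index ECG. Eligibility mirrors a
cardiology-registry design: patients are removed for structural heart
disease, age < 20 or > 90 years (boundaries inclusive on the retained side),
indeterminate QRS axis (R axis > 180°), paced beats, or atrial/ventricular
tachyarrhythmia. When a patient matches several criteria the removal is
attributed to the **first** matching criterion in that fixed order, so the
per-criterion counts sum exactly to the number removed. Follow-up is capped
at 3 years = 1095.75 days (3 × 365.25, the same day-year used for
patient-year denominators); a death recorded after the cap is re-labelled
alive because all downstream outcome analysis is binary vital status within
the observation window. Exclusion and truncation are independent row-wise
operations, so they commute.

Clinical covariates use the Japanese-coefficient MDRD equation
`eGFR = 194·SCr^−1.004·Age^−0.287 (×0.739 if female)` and
`BMI = weight/height²`. ECG columns follow the `<Parameter>__<Lead>` naming
convention against a packaged catalogue of 438 modelling parameters
(6 not lead-specific, 36 × 12 lead-specific) and 201 excluded ones; unknown
columns in an input file are dropped with a warning rather than silently
modelled. Missing values are not allowed in modelling columns
(complete-case analysis); they are permitted only in the optional
covariates (creatinine, height, weight).

## Parameter selection

Selection is computed separately for men and women. Step 1 keeps parameters
with |Pearson r| ≥ θ₁ = 0.2 against chronological age. The threshold is
applied to |r| deliberately: several ECG amplitudes decline with age and a
signed threshold would discard them even though they carry identical
information. Step 2 examines all unordered pairs among the step-1 survivors;
pairs with |r| ≥ θ₂ = 0.9 are "strong". A parameter is retained iff it has
no strong partner, or its step-1 |r| with age strictly exceeds that of every
strong partner. This implies the post-condition (asserted in tests) that no
retained pair is strongly correlated: in any strong pair at most one member
can outrank the other. Exact ties between partners are broken by keeping the
lexicographically first column name, deterministically, with a log record.
For reporting, the size of the pairwise scan is quoted as ordered pairs,
X(X − 1), the convention used in the source field; the scan itself visits
each unordered pair once.

The per-sex selections must be combined into one list for pooled model
fitting. The default is their **union**. The intersection was considered and
rejected: within a block of near-exchangeable collinear parameters the
per-sex winner is determined by sampling noise, so the intersection of two
independent winners-per-block is close to empty (on synthetic data it
collapsed to a single parameter out of 60), which is a degenerate panel
rather than a stricter one. Per-sex lists (`male`, `female`) and
`intersection` remain available through `sex_mode`.

## PCA biological age

Inputs are standardized per column (mean 0, sd 1, ddof = 1) with the
standardization model stored for later application to new data. The
correlation matrix is eigendecomposed; unrotated components with eigenvalue
≥ 1.0 (inclusive) are retained. Eigenvector sign is mathematically
arbitrary but pre-BA is not sign-free, so each loading vector is oriented to
make its score's regression slope against CA non-negative. Component
weights are `p_i = R²_i/Σ R²_k` with R²_i from the univariate regression of
CA on component-i scores; weights are therefore non-negative and sum to 1.
The calibration constant B is computed as the Pearson correlation of pre-BA
with CA, which equals the standardized regression slope and is numerically
stable. On the training cohort pre-BA has mean exactly 0 and the age term
`(CA − C̄A)(1 − B)` has mean 0, so mean(BA) = mean(CA) to machine precision —
a useful invariant check. Note that the construction scales the *raw*
weighted composite by sd(CA); since the dominant component of a collinear
panel has variance well above 1, BA has a wider spread than CA. This is a
property of the published construction, reproduced as specified, not a bug.

## Klemera–Doubal biological age

Because true biological age is unobservable, the per-biomarker regressions
are of `x_j` on CA (not on BA_E); `k_j`, `q_j`, `s_j`, `r_j` are the OLS
slope, intercept, residual RMSE and Pearson correlation. Conventions:

- `s_j` divides the residual sum of squares by n (population RMSE).
- In `r_char`, `|r_j|` is used so that negatively age-correlated biomarkers
  contribute positively; the sign information remains in `k_j`. A biomarker
  with `s_j = 0` or `|r_j| = 1` is degenerate (it would get infinite weight)
  and raises an error instructing its removal.
- `s²_BA` uses the population (divide-by-n) variance of `BA_E − CA` and is
  written in the canonical form *variance minus noise correction*, the
  correction being `(1 − r²_char)/r²_char · (CA_max − CA_min)²/(12 m)` with
  the CA extremes taken from the fitting cohort. At small n or with a weak
  panel the correction can exceed the variance; `s²_BA` is then floored at
  1e−8 with a warning, which makes BA_EC collapse to CA — the honest limit
  of an uninformative panel.

BA_E is algebraically the weighted-least-squares minimiser over candidate
age t of `Σ_j[(x_j − q_j − k_j t)/s_j]²`, which the tests verify against a
grid/closed-form oracle; BA_EC adds CA as one more pseudo-biomarker with
variance `s²_BA` and is therefore always between BA_E and CA.

## ROC evaluation

Outcomes are binary vital status at the end of truncated follow-up; no
censoring adjustment or time-dependent ROC is attempted, matching the
source design. For the cardiovascular outcome, non-cardiovascular deaths
remain in the control set. AUC is the Mann–Whitney estimator with midrank
ties; DeLong placement values give the variance, the 95% CI (normal
approximation, truncated to [0, 1]), the per-predictor test against
AUC = 0.5, the paired test between two predictors on the same patients, and
the unpaired test (independent variances summed) for one predictor across
two disjoint age strata. All p-values are two-sided. Strata with no events
(or no controls) are reported as not evaluable rather than dropped
silently. A seeded null simulation (two correlated chance predictors,
n = 200, 2000 replicates) checks that the paired test's type-I error at
α = 0.05 is near nominal; bootstrap oracles back the paired and unpaired
variances on small fixtures.

## Synthetic cohort generator

The generator emulates only the statistical structure the pipeline relies
on, not ECG physiology:

- **CA** ~ truncated normal, mean 55.5, sd 15.0 years on [20, 90] —
  registry-scale moments.
- **Latent biological age** = CA + N(0, `latent_noise_sd` = 8 years). The
  8-year spread makes biological-age acceleration material but keeps
  corr(latent, CA) ≈ 0.87, a plausible biomarker regime.
- **Sex**: 53.7% male; sex affects only the anthropometric covariates, so
  per-sex selection results differ only by sampling noise — which is itself
  the regime that motivates the union combination rule above.
- **ECG parameters**: 12 blocks × 5 parameters (60 columns drawn from the
  catalogue). Each block shares a driver `a·u + √(1−a²)·e_b` with
  `a = age_loading = 0.6` on the exactly standardized latent age `u`; each
  parameter is a random affine transform (random sign) of the driver plus
  idiosyncratic noise sized analytically so the expected within-block
  correlation equals `within_block_corr` = 0.95 — the strong-collinearity
  regime the pruning step is designed for. Twelve blocks give the panel
  enough independent age information that the Klemera–Doubal estimate
  recovers the latent age at r ≈ 0.93 (asymptotically
  `0.6/√(0.36 + 0.64/12)` = 0.933) under the default signal strength.
- **Mortality**: exponential hazard, baseline 0.5 per 100 patient-years,
  log-hazard shifted by 0.05 per year of (latent − CA); administrative
  follow-up uniform on (0, 1095.75] days; cause cardiovascular with
  probability 23/55. The exponential model is a deliberate simplification —
  the analysis only requires that biological age carries mortality signal.
- **Determinism**: one named child stream per stage from a master
  `SeedSequence`, so identical seeds give identical tables.

What the generator does **not** emulate: real marginal distributions and
units of ECG parameters, sex-specific aging physiology, non-exponential
hazard shape, covariate-dependent mortality, loss to follow-up, or
missingness. Passing tests therefore demonstrate the correctness and
statistical behaviour of the pipeline under its stated assumptions, not the
clinical performance of ECG age on any real population.

## Problem sizes and numerics

Recovery and distribution checks use n = 5000 patients; null-calibration of
the DeLong test uses 2000 replicates of n = 200; the end-to-end determinism
check runs the full pipeline twice at n = 5000. These sizes give
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the whole suite around a minute. Other conventions: standardization uses
ddof = 1; correlation-matrix eigendecomposition uses a symmetric solver
(`eigh`); model JSON serialises floats at full precision; report renderers
round for display only.

## Known limitations

- Pooled (sex-combined) model fitting is the default; fully sex-stratified
  models are available but the evaluation layer compares one prediction set
  at a time.
- The variance floor on `s²_BA` means BA_EC degrades gracefully to CA for
  weak panels instead of failing; callers who prefer a hard failure should
  inspect the emitted warning.
- The ROC analysis ignores censoring by design; with the 3-year cap and
  near-complete follow-up this matches the source design but would bias
  AUCs on cohorts with heavy early dropout.
- Exclusion flags are consumed as given; the package does not derive them
  from measurements (e.g. it does not compute the R-axis criterion from the
  `R axis` column).
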