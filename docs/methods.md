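# Methods

This note documents the models, the numerical choices, and the synthetic
data behind `mddnet`, in the spirit of the methods documentation of
statsmodels or scanpy: what is computed, under which assumptions, with
which defaults, and what the simulations do and do not establish.

## Connectivity construction (`mddnet.fc`)

Input is a `volumes × regions` BOLD matrix plus six rigid-body motion
parameters per volume. Processing steps and their conventions:

- **Band-pass filter**: first-order Butterworth, pass band 0.01–0.08 Hz
  (the standard resting-state band). Applied forward–backward
  (`scipy.signal.filtfilt`) so no phase lag is introduced; the effective
  magnitude response is the square of the single-pass response (≈ −0.53 dB
  at 0.04 Hz for TR = 2 s).
- **Framewise displacement**: FD[t] = Σ|Δtranslation| + r·Σ|Δrotation|,
  with rotations converted to arc length on a sphere of radius r = 50 mm
  (Power-style; configurable). Whether rotations should be converted to
  millimetres at all is a genuine convention choice; 50 mm is the default
  and is stated here because published descriptions often omit it. FD of
  the first volume is defined as 0, since FD is a backward difference.
- **Scrubbing**: volumes with FD strictly above 0.5 mm are censored;
  participants whose censored fraction exceeds mean + 3 SD (population SD,
  computed over all participants before any exclusion) are dropped.
- **Connectivity**: Fisher-z (atanh) of Pearson correlations over the
  strict lower triangle, row-major `(i, j), i > j`, 0-based — the pair
  convention is recorded in every sidecar file. Correlations of exactly ±1
  are clipped to ±(1 − 1e−7) to keep atanh finite. A region whose signal
  is constant (SD below 1e−12 of its amplitude scale) is an error naming
  the region, not a silent NaN.
- **Nuisance regression** accepts a pre-computed regressor matrix
  (motion parameters, aCompCor components, etc.) and projects it out by
  least squares; extracting such regressors from images is out of scope —
  the pipeline deliberately starts at parcellated time series.

## Synthetic data (`mddnet.synth`)

The generator draws from exactly the generative model the harmonization
estimator assumes: per connection,

    study scan:    const + m[site] + s_hc/s_mdd[site] + d·1{MDD} + ε
    traveler scan: const + m[site] + p[traveler] + ε,   ε ~ N(0, noise_sd²)

with `m`, `s_hc`, `s_mdd` centered across sites and `p` across travelers
(the centering makes the estimator's sum-to-zero constraints hold exactly
in the truth). Defaults, chosen once to mirror the empirical regime of
multi-site FC studies:

| parameter | default | rationale |
|---|---|---|
| `measurement_sd` | 0.2 (Fisher-z) | measurement bias is reported to exceed disorder effects; 2× the disorder scale |
| `sampling_sd` | 0.1 | same order as the disorder effect |
| `disorder_sd` | 0.1 | ≈ 1 noise SD on affected connections |
| `noise_sd` | 0.1 | residual scan noise (γ^(−1/2)) |
| disorder support | 25 connections, 19 negative / 6 positive | the reported count and under-/over-connectivity split of the MDD marker |
| sites / travelers | 4 / 9 | the discovery-cohort design |
| ages | site-specific normals, truncated to [18, 80] | exercises age matching; HC/MDD offsets configurable |

Support magnitudes are floored at 0.25·`disorder_sd` so "support" always
means a non-negligible effect. BDI scores are generated high in patients
and low in controls with 5% missingness (exercising the ComBat covariate
path); medication flags are random in patients.

What the generator does **not** emulate: temporal autocorrelation of BOLD,
motion artifacts, multiplicative site effects on FC, heavy-tailed noise,
or correlation structure *between* connections (connections are
conditionally independent given the effects). Passing recovery tests on
this generator therefore demonstrates correctness of the estimators under
their assumed model, not robustness to real-data violations of it.

The surrogate "true probability of depression" used by the rater
simulation is a two-component Beta mixture (0.65·Beta(2,6) +
0.35·Beta(6,2)), one mode per diagnostic class. The real distribution of
classifier outputs that a published analysis would use here is not
available, so any quantity that depends on the shape of this distribution
— notably the rater variance implied by a given kappa — is reported for
the synthetic mixture only and is not comparable to published values.

## Harmonization (`mddnet.harmonize`)

**Traveling-subject regression.** All connections are fit in one pass:
categorical factors are encoded with sum-to-zero contrasts (level k → eₖ,
last level → −1), giving a reduced full-rank design shared by all
connections, solved by a single rank-revealing `lstsq`. Plain least
squares is used — no regularization by default — and a rank-deficient
design (e.g. travelers missing a site) is a hard error rather than a
silently shrunk fit. Harmonization subtracts **only** the estimated
measurement bias `m̂[site]`; sampling biases and the disorder effect are
never removed, because they carry the population signal the classifier
needs. The subtraction is intentionally not idempotent (applying it twice
subtracts 2m̂).

Two conventions are worth stating because the source descriptions leave
them open: traveler scans enter the regression with the same weight as
study scans, and the estimator is ordinary least squares rather than a
regularized variant.

**ComBat.** Parametric empirical-Bayes location/scale adjustment:
per-connection standardization against a covariate-preserving linear fit,
normal/inverse-gamma shrinkage of per-site means and variances, removal,
and restoration of scale and covariate effects. Implemented in-package
(no Python ComBat implementation is part of the dependency set) and
verified against Bioconductor `sva::ComBat` to ~1e−6 on a fixed fixture.
Missing numeric covariates (BDI) are mean-imputed within site with a
missing-indicator column. The non-parametric variant is not implemented.
Constant connections are passed through untouched.

## Classifier (`mddnet.classify`)

- **Objective**: per-sample-averaged log-loss + λ‖w‖₁, intercept
  unpenalized. λ_max = max_k |(1/n) Σᵢ x_ik (yᵢ − ȳ)| (the KKT bound at
  the all-zero solution); the grid is 25 **linearly** spaced values on
  [0, λ_max] — linear rather than the more conventional log spacing, kept
  as the reference design specifies. At λ ≥ λ_max the exact closed-form
  optimum (w = 0, intercept = log-odds) is returned.
- **Solver**: scikit-learn's liblinear coordinate descent with
  C = 1/(nλ). liblinear penalizes its intercept through the
  augmented-feature trick, so `intercept_scaling = 1e3` is used to make
  that contribution negligible; the test suite verifies the objective
  against an independent FISTA (accelerated proximal-gradient) solver to
  1e−4.
- **Undersampling**: each subsample takes `min(minority, 125)` members
  per class; a seeded random anchor ordering of the minority class is
  greedily paired with nearest-age majority members, and if the mean-age
  gap still exceeds 1.0 year the worst-offending pairs are dropped
  (keeping classes equal) down to at most half the target before erroring.
- **Inner CV**: 10-fold deviance per grid λ; the selected λ is the
  largest whose mean CV error is within one standard error
  (SD over folds / √k) of the minimum — the standard reading of the
  one-SE rule; the raw-SD variant is available via `rule="sd"`.
- **Standardization**: features are z-scored with training-subsample
  statistics before the penalized fit (the reference design is silent on
  this; unstandardized features would make the L1 penalty
  scale-dependent). The scaler is stored with each member.
- **Ensemble**: stratified outer folds; the held-out fold is scored only
  by that fold's own members; external data are scored by all 100.
  Decision threshold: probability strictly greater than 0.5 calls MDD.
  (The rater simulation intentionally uses ≥ 0.5, matching the convention
  stated for that analysis; the inconsistency exists in the source and is
  preserved, documented, rather than silently unified.)

## Evaluation and importance (`mddnet.evaluate`, `mddnet.importance`)

Metrics with zero denominators are reported as missing (NaN), never
clamped. AUC is the rank-based Mann–Whitney statistic with ties counted ½.
Permutation p-values use the plus-one convention (1 + b)/(1 + n_perm), so
they are never zero; with n_perm = 19 the smallest attainable p is 0.05 —
α = 0.05 decisions therefore need n_perm ≥ 19, and the default is 100.
The two-proportion z-test uses the pooled variance without continuity
correction — this is the convention that reproduces the published
medication-use statistics (z = 1.995 prints as 2.00 at the source's
rounding; its p = 0.046 matches exactly).

The importance threshold is the smallest integer count c with
(1 + #{null max ≥ c})/(n_perm + 1) ≤ α, where each null draw retrains the
full ensemble on label-shuffled data and takes the maximum selection count
over all connections — max-statistic FWER control. A threshold of 0 is
never returned (a never-selected connection is not evidence). Effect
sizes are pooled-variance two-sample t statistics signed patients − controls
(negative = under-connectivity); Welch's variant was not used, matching
the two-sample convention of the reference analysis. Cross-cohort
reproducibility correlates the two t-vectors, with a permutation null that
reshuffles labels independently within each cohort.

## Rater simulation (`mddnet.rater`)

Σ is interpreted as a **variance** (noise SD = √Σ), consistent with the
N(0, Σ) notation; this is stated prominently because the notation alone
does not disambiguate. Kappa uses marginal-product expected agreement;
when both raters are constant and identical, kappa is defined as 1.
Inversion is by bisection on Σ with a fresh Monte-Carlo estimate per
iterate (tolerance 0.005 on kappa); an unreachable target reports the
attainable kappa range. The variance decomposition uses sample (n−1)
variances throughout and averages per-participant components across
participants; participants lacking ≥ 2 scans at the designated
"within" site are skipped with a warning.

## Problem sizes in the test suite

The acceptance tests run the full design where it matters and scaled
replicas where many repetitions are needed: harmonization recovery at
4 sites × 200 connections × 600 participants with 9 travelers × 3 scans;
classifier recovery at 500 connections × 600 participants with the full
10 × 10 ensemble (one signal run, one label-permuted run); selection-count
separation over 20 repeats at 100 connections × 200 participants with a
5 × 5 ensemble; null error-control checks (family-wise and type-I) over
20–60 repeats at micro scale (20–30 connections, 60–160 participants,
2–6 member ensembles, n_perm = 19). The micro null checks loosen the
age-matching tolerance to 10 years: at 30 participants per class the
standard error of a mean-age difference (~3 years) makes a 1-year
matching tolerance routinely infeasible, and age structure is irrelevant
to the exchangeability being tested. These sizes are the package's own
test design; all full-size defaults (10 × 10 × 25, n_perm = 100,
n_boot = 1000) remain the library defaults.

## Known limitations

- The pipeline starts at parcellated time series; no image-space
  preprocessing, parcellation, or aCompCor extraction.
- The traveling-subject estimator assumes additive, connection-wise
  independent site effects; multiplicative site effects are only handled
  by the ComBat path.
- The permutation procedures retrain the entire ensemble per draw and are
  therefore expensive at full scale; the defaults (100 permutations)
  match the reference design, not a runtime optimum.
- Published headline results on the restricted clinical cohorts (e.g.
  AUC 0.74, the 25 specific connections, Σ = 0.0149) depend on data this
  package cannot ship; the reconstructions here verify arithmetic
  consistency and procedure behavior, not those empirical values.
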