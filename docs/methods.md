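# Methods

## Normative model and assumptions

Each region × metric series is modelled cross-sectionally by ordinary least
squares as

    qMRI = β₀ + β₁·Age + β₂·Age² + β₃·Sex + β₄ˡ·Edu_low + β₄ʰ·Edu_high + β₅·MoCA + ε,
    ε ~ N(0, σ²) i.i.d.

Assumptions: age effects are smooth and at most quadratic within 18–79 years;
covariate effects are additive and age-invariant; residuals are homoscedastic
across age; subjects are independent (no longitudinal or family structure).
Education enters as two dummies against the medium reference so the two
contrasts are reported separately. Sex is coded female = 1 by default
(configurable). Age is centred at the sample mean internally for numerical
conditioning; all reported coefficients, SEs and covariances are mapped back
to the original years scale through the exact linear reparametrization, so
centring never changes reported estimates (verified to ~1e-7 relative).

### Quadratic gate

The quadratic term is kept only if the likelihood-ratio statistic
`LR = n·log(SSE_linear/SSE_quadratic)` exceeds the χ²(1) critical value at
α = 0.05 (strict inequality: p = α gates the region). This Gaussian-profile
LR form is the default because it matches the stated testing procedure; an
F-test variant with (1, n−p) denominator df is provided for users who prefer
exact small-sample calibration. At n = 293 the χ² form is already
well-calibrated (null rejection ≈ 0.05 in simulation).

### Peak age and its uncertainty

The vertex `Age_peak = −β₁/(2β₂)` is a maximum for β₂ < 0, a minimum for
β₂ > 0. Its default standard error is the propagation formula

    SE_peak = sqrt[(SE_β₁/(2β₂))² + (β₁·SE_β₂/(2β₂²))²]

which omits the β₁–β₂ covariance. The formula is therefore evaluated on the
**centred-age** coefficients: with a roughly symmetric age distribution the
centred β₁ and β₂ are nearly uncorrelated, and the omitted term is
negligible (within ~10% of the full first-order delta method in our
simulations). On the raw age scale the same formula would overstate the SE
several-fold, because raw β₁ and β₂ are almost collinear. The full delta
method including `2·d₁·d₂·cov(β₁,β₂)` is available via
`include_covariance=True` and is parametrization-invariant.

The bootstrap resamples subjects (not residuals) with replacement, refits
the full model per replicate and re-evaluates the vertex. Replicates are
marked invalid when |β₂| falls below a conditioning floor
(`sqrt(machine epsilon) × max(|β₂_full|, tiny)`) or when the vertex lands
outside the observed age span ± 20 years; invalid replicates are excluded
from the SE (SD of valid peaks) and the 2.5/97.5 percentile CI, and their
count is reported. Fewer than B/2 valid replicates attaches an
unstable-peak warning without suppressing the result. The percentile CI (not
BCa) is the default since no bias correction is part of the reference
procedure; gating is decided once on the original fit, not per replicate.
The reference replicate count is B = 10 000; the analysis drivers and the
acceptance experiments use B = 1000, at which the SE and CI endpoints are
stable to well under 0.1 years for these effect sizes.

### Model adequacy (EXPV)

The comparison model replaces the {Age, Age²} basis with a cubic B-spline in
age — interior knots at the 25/50/75th percentiles of the *training* ages of
each fold, boundary knots at the training min/max, first basis column dropped
against the intercept — keeping the covariate columns identical, so only the
age basis differs. Both models share the same 5 folds, stratified by age
decade to stabilise holdout variance. Out-of-sample EXPV per fold is
1 − SSE/SST about the holdout mean. The headline EXPV per model is the
best-performing fold, taken per model independently (the most literal
reading of the procedure); because best-fold selection is optimistic, the
mean across folds and the ratio of means are always co-reported. When the
polynomial's headline EXPV is ≤ 0 the ratio is reported as undefined (NaN)
and flagged. Holdout ages are clamped into the training age range before
spline evaluation, since the B-spline basis is undefined beyond its boundary
knots; with stratified folds this affects at most a handful of extreme-age
subjects per fold.

### Covariation

Pearson correlations use pairwise-complete observations; cells with fewer
than 3 complete pairs are left missing, and a region with no valid partner is
dropped with a warning. Two-sided p-values use the exact t-transform with
n_pairs − 2 df. Benjamini–Hochberg runs within each mode × block family
(intra-cGM, intra-sWM, inter cGM-sWM) by default — the family definition is
configurable (`bh_family="matrix"` pools the whole matrix) and recorded in
the outputs. Correlations are pooled on the Fisher-Z scale,
`tanh(mean(atanh(r)))`, with |r| = 1 clipped at 1 − 1e-12 (warned). The
age-adjusted mode correlates standardized residuals z = e / SD(e) (sample
SD, ddof = 1, so each region's z has mean 0, SD 1 exactly); only regions
passing the quadratic gate enter this mode, and noise-free regions
(R² ≈ 1 or zero residual SD) are flagged degenerate and skipped.

## Synthetic cohort generator

The generator is the fitted model's own data-generating process, so fitting
it back is a closed-loop parameter-recovery test.

* **Demographics** (defaults): n = 293; ages drawn by decade bin with
  weights 46/45/47/52/52/51 over 18–30/31–40/…/71–79, then uniformly within
  the bin (continuous ages avoid discretization artifacts at the vertex);
  P(female) = 0.539; education low/medium/high with probabilities
  36/90/149 normalized; MoCA on 24–30 with pmf (.03,.07,.17,.28,.17,.18,.10),
  giving median 27 and IQR 26–29 — a narrow high range typical of screened
  healthy adults.
* **Trajectories**: per tissue and metric family, true vertex ages are drawn
  Normal(tissue mean, tissue SD) and mean-centred so the realized tissue
  average equals the target exactly — R1-like 39.16/43.28/56.40 y
  (WM bundles/sWM/cGM, SD 2.85/3.71/1.98), R2\*-like 45.06/52.23/60.27 y
  (SD 5.43/2.99/3.45), QSM-like 46.81/48.86/51.54 y (SD 4.27/7.38/6.03) with
  upward-opening (minimum-type) curves in WM bundles and downward-opening
  elsewhere. Vertex values sit in the metric's plausible regional ranges
  (e.g. cGM R1 0.66–0.74 s⁻¹, bundle R1 up to 1.19 s⁻¹, bundle QSM down to
  −21 ppb), with the trajectory amplitude over the age span set per tissue
  (e.g. 0.04–0.06 s⁻¹ for R1).
* **Noise calibration**: σ is solved per region from a target age-signal R²
  (uniform per region in 0.30–0.50 for R1-like, 0.20–0.40 for R2\*-like,
  0.08–0.18 for QSM-like) against the decade-mixture age density evaluated
  on a deterministic grid — matching the reported pattern that R1 models age
  most strongly and QSM weakest. Realized full-model R² runs slightly above
  the target because covariate effects add explained variance.
* **Covariates**: per-region effects are drawn from centred normals scaled
  to σ (sex strongest for R2\*-like at 0.30σ, weakest for R1-like at 0.15σ;
  education ~0.1σ per dummy; MoCA 0.02–0.06σ per point), reproducing the
  qualitative tissue/metric pattern of covariate significance without making
  the exact counts a target. An optional per-subject standard-normal latent
  factor with per-region loadings induces age-independent regional
  covariance.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring regions (regions are conditionally independent given age,
covariates and the single optional latent factor), hemispheric asymmetries,
heteroscedastic or heavy-tailed measurement noise, artefact-driven outliers,
missing data patterns, and any voxel/surface/tractogram structure (generation
starts at the subject × region table). Passing recovery tests therefore
demonstrates correctness of the estimators under the model's own
assumptions, not robustness to real-data violations of them. By default all
regional covariance is age-driven, so age-adjusted correlation matrices are
near zero unless a latent loading is specified.

## Tables and aggregation conventions

Delimited text (CSV, UTF-8, header) for both tables; reading validates
closed vocabularies, key uniqueness (duplicate keys are integrity errors),
MoCA range, and warns (without failing) on ages outside 18–79. Missing
metric values are permitted and propagate as pairwise-complete handling; they
are never imputed. Regional averaging of voxel-level value lists excludes
values whose **magnitude** exceeds 3× the magnitude of the median — the rule
is applied to magnitudes deliberately, because QSM medians are frequently
negative and a signed threshold is ill-defined there — and falls back to the
plain mean if the exclusion would discard everything. Cortical (cGM/sWM)
left/right pairs are averaged into bilateral rows; WM bundles are kept per
hemisphere (left and right tracts age on distinct trajectories); a cortical
region present in one hemisphere only passes through as bilateral with a
warning. Because cGM and sWM share Brodmann labels, all internal pivots key
regions by (tissue, region_id).

## Reporting choices

Tissue-level dispersion of peak ages is reported both as SD across regions
and as SE of the tissue mean, labelled explicitly, since a bare "±" is
ambiguous between the two. Covariate tallies report raw-α counts as the
headline (with BH-adjusted counts alongside); a region counts once for
education if either dummy is significant, and its BH input is the
Bonferroni-combined min(1, 2·min(p_low, p_high)) so each region contributes
one p-value to the family. The gradient verdict demands the strict ordering
mean(WM bundles) < mean(sWM) < mean(cGM) over ungated, in-range peaks and is
marked incomplete if any tissue has none.

## Numerical choices and degenerate inputs

OLS via statsmodels with an explicit rank check (singular designs raise);
constant covariate columns (e.g. single-sex cohorts) are dropped with a
warning before fitting; fewer than 10 complete rows is an error. Constant
responses yield R² = 0 by convention (SST = 0). Spline knot collapse
(degenerate age distributions) raises a dedicated error with guidance.
Bootstrap replicate regressions use a Cholesky/normal-equations solve with an
lstsq fallback on singular resamples. Experiment seeds derive from a master
seed via SHA-256 of (seed, stage, index), keeping every derived seed below
2³¹ and independent across stages.

## Problem sizes

Calibration experiments run at the study's sample size (n = 293): 100
random instances for the OLS oracle, 2000 null and 500 power simulations for
the LRT, 200 simulated regions with B = 1000 bootstrap replicates for peak
recovery and CI coverage, 100 regions for the EXPV ratio, and one full
104-region × 3-metric synthetic run for the tissue gradient. These sizes give
Monte-Carlo error comfortably inside the property tolerances while keeping
the whole acceptance run under a minute.

## Known limitations

* The quadratic vertex is a descriptive landmark, not a biological change
  point; heavily asymmetric trajectories put it near the age-range boundary
  where its SE grows quickly.
* The propagation SE relies on first-order linearization and near-zero
  centred-coefficient covariance; for very weak curvature (|β₂| → 0) both it
  and the bootstrap become unstable — hence the gate and the replicate
  validity rules.
* Best-fold EXPV is optimistic by construction; use the co-reported fold
  means for conservative comparisons.
* No mixed-effects, GAMLSS, exponential-saturation or longitudinal
  modelling; no Fieller-type analytic CI for the vertex; no graph-theoretic
  summaries of the correlation matrices.
* The BH family definition (per block, per matrix) is a modelling choice;
  results near the significance boundary can move between choices, which is
  why the family is configurable and logged.
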