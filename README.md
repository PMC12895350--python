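# qmriage

Regional brain-ageing trajectory analysis for quantitative MRI (qMRI)
metrics — longitudinal relaxation rate R1 (s⁻¹), apparent transverse
relaxation rate R2\* (s⁻¹) and quantitative susceptibility (QSM, ppb) —
measured per subject in cortical grey matter (cGM), superficial white matter
(sWM) and deep white-matter bundles. It is aimed at researchers modelling
normative ageing in cross-sectional adult cohorts who want region-level
turning-point ("peak age") estimates with honest uncertainty, a check that a
quadratic age model is adequate, and raw vs age-adjusted regional covariation.

## The model

Per region of interest (ROI) and metric, an ordinary least-squares normative
model:

```
qMRI_ROI = β₀ + β₁·Age + β₂·Age² + β₃·Sex + β₄·Education + β₅·MoCA + ε
```

with medium education as the reference category (two dummies) and MoCA the
Montreal Cognitive Assessment score. From the quadratic fit:

* **Peak age** — the vertex `Age_peak = −β₁ / (2β₂)`, a maximum when β₂ < 0
  (inverted-U, typical of R1/R2\*) or a minimum when β₂ > 0 (U-shape, typical
  of bundle susceptibility).
* **Propagation SE** — `SE_peak = √[(SE_β₁/(2β₂))² + (β₁·SE_β₂/(2β₂²))²]`,
  evaluated on the centred-age parametrization where the β₁–β₂ covariance is
  negligible; a full first-order delta method including the covariance term
  is available behind a flag.
* **Gate** — peaks are reported only when a likelihood-ratio test,
  `LR = n·log(SSE_linear/SSE_quadratic)` vs χ²(1), rejects the nested linear
  model (p < 0.05).
* **Bootstrap** — subjects resampled with replacement, the model refit and
  the vertex re-evaluated per replicate; SD and 2.5/97.5 percentiles of the
  valid replicates give SE and 95% CI.
* **Adequacy** — out-of-sample explained variance (EXPV = 1 − SSE/SST on the
  holdout) of the polynomial vs a cubic age B-spline (knots at the
  25/50/75th training-age percentiles) under shared 5-fold CV; their ratio
  near 1 means the quadratic is not an oversimplification in this age range.
* **Covariation** — pairwise-complete Pearson matrices across cGM/sWM
  regions on raw values and on standardized model residuals (z-scores),
  Fisher-Z pooled per block, Benjamini–Hochberg corrected.

A synthetic cohort generator emulates the target study design (n = 293,
ages 18–79 with near-uniform decade coverage, ~54% female, tissue-anchored
trajectory libraries) and carries exact ground truth, so every stage is
testable by parameter recovery without any data download.

## Worked example

```python
import pandas as pd
import qmriage as q

cohort = q.generate_cohort(q.CohortSpec(seed=7))          # 293 subjects, ages 18-79
lib = q.default_trajectory_library("R1", n_cgm=1, n_swm=0, n_bundles=0, seed=7)
values = q.generate_region_metrics(cohort, lib, seed=8)

design = q.build_design(cohort)
y = pd.Series(values["value"].to_numpy(), index=values["subject_id"].to_numpy())
fit = q.fit_trajectory(design, y, region_id="BA01", tissue="cGM", metric="R1")
est = q.estimate_peak(fit, design=design, y=y, B=1000, seed=9)

print(f"true peak age : {lib.specs[0].true_peak:.2f} y")
print(f"fit           : R^2 = {fit.r2:.2f}, LRT p = {fit.lrt_p:.2e}")
print(f"estimated peak: {est.peak_age:.2f} y ({est.curvature_sign})")
print(f"uncertainty   : SE_delta = {est.se_delta:.2f} y, SE_boot = {est.se_boot:.2f} y, "
      f"95% CI [{est.ci95_boot[0]:.1f}, {est.ci95_boot[1]:.1f}]")
```

prints

```
true peak age : 56.40 y
fit           : R^2 = 0.50, LRT p = 9.83e-33
estimated peak: 55.93 y (maximum)
uncertainty   : SE_delta = 0.70 y, SE_boot = 0.73 y, 95% CI [54.7, 57.5]
```

The cGM region generated with a true vertex at 56.4 years is recovered within
half a year; the propagation SE and the bootstrap SD agree; the LRT
decisively prefers the quadratic over the linear model.

## Analysis drivers

`analysis/` holds numbered scripts that run the full study on the synthetic
cohort: `01_simulate.py` (data to `scratch/sim/`), `02_fit_trajectories.py`,
`03_peak_ages.py` (bootstrap B = 1000), `04_model_adequacy.py`,
`05_covariation.py`. Each prints its findings and writes small summary
tables under `results/analysis/`. The same stages are available as CLI
subcommands (`qmriage simulate | validate | fit | peaks | evaluate | covary |
gradient | run`) and as a single config-driven pipeline
(`qmriage.run_pipeline`), which also records a reproducibility manifest.

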