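"""Calibration and parameter-recovery experiments for the whole pipeline.

Each function runs a self-contained, seeded simulation study through the
package's public fitting/inference path and returns summary statistics:
estimator oracle agreement, likelihood-ratio-test calibration and power,
peak-age recovery and bootstrap coverage at the study's sample size (n=293),
polynomial-vs-spline explained-variance ratios under quadratic truth, full
tissue-gradient recovery, and the raw-vs-age-adjusted covariation contrast.

These are the quantitative checks behind the test suite and the acceptance
script; problem sizes are arguments so callers can trade precision for time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariation import bh_adjust, compute_zscores, correlation_matrix, fisher_average
from .peaks import estimate_peak, peak_age, peak_age_se
from .pipeline import _stage_seed, run_pipeline
from .reporting import tissue_gradient
from .synthetic import PEAK_AGE_TARGETS, CohortSpec, default_trajectory_library, generate_cohort, generate_region_metrics
from .tables import TISSUES
from .trajectory import build_design, cv_expv, fit_quadratic, fit_trajectory


def peak_identity(seed: int = 0, n_mc: int = 200_000) -> dict:
    """Closed-form vertex and propagation SE at a reference coefficient set.

    The Monte-Carlo column perturbs (b1, b2) = (2, -0.025) with independent
    normal errors (0.1, 0.002) and takes the SD of the implied vertex.
    """
    pk, _ = peak_age(2.0, -0.025)
    se = peak_age_se(2.0, -0.025, 0.1, 0.002)
    rng = np.random.default_rng(seed)
    b1 = 2.0 + rng.normal(0, 0.1, n_mc)
    b2 = -0.025 + rng.normal(0, 0.002, n_mc)
    mc_sd = float((-b1 / (2 * b2)).std())
    return {"peak": float(pk), "se": float(se), "se_mc": mc_sd}


def ols_oracle_error(n_instances: int = 100, seed: int = 0) -> float:
    """Max relative deviation of the OLS fit from a normal-equations solve."""
    cohort = generate_cohort(CohortSpec(seed=_stage_seed(seed, "ols-cohort")))
    design = build_design(cohort)
    X = design.X
    XtX_inv = np.linalg.inv(X.T @ X)
    rng = np.random.default_rng(_stage_seed(seed, "ols-y"))
    worst = 0.0
    for _ in range(n_instances):
        y = rng.standard_normal(design.n)
        oracle = XtX_inv @ (X.T @ y)
        fit = fit_quadratic(design, pd.Series(y, index=design.subject_id))
        rel = np.abs(fit.params_centered.to_numpy() - oracle) / np.maximum(np.abs(oracle), 1e-12)
        worst = max(worst, float(rel.max()))
    return worst


def lrt_calibration(n_null: int = 2000, n_power: int = 500, seed: int = 0) -> dict:
    """Null rejection rate (beta2 = 0 truth) and power under quadratic truth."""
    cohort = generate_cohort(CohortSpec(seed=_stage_seed(seed, "lrt-cohort")))
    design = build_design(cohort)
    rng = np.random.default_rng(_stage_seed(seed, "lrt-noise"))
    age = design.age

    rejections = 0
    for _ in range(n_null):
        y = 0.01 * age + rng.standard_normal(design.n)
        fit = fit_trajectory(design, pd.Series(y, index=design.subject_id))
        rejections += fit.lrt_p < 0.05
    null_rate = rejections / n_null

    lib = default_trajectory_library("R1", n_cgm=1, n_swm=0, n_bundles=0,
                                     seed=_stage_seed(seed, "lrt-lib"), covariates=False)
    s0 = lib.specs[0]
    truth = s0.beta0 + s0.beta1 * age + s0.beta2 * age**2
    decisive = 0
    for _ in range(n_power):
        y = truth + rng.standard_normal(design.n) * s0.sigma
        fit = fit_trajectory(design, pd.Series(y, index=design.subject_id))
        decisive += fit.lrt_p < 1e-6
    return {"null_rejection_rate": null_rate, "power_frac": decisive / n_power}


def peak_recovery(n_regions: int = 200, B: int = 1000, seed: int = 0) -> dict:
    """Peak recovery, bootstrap CI coverage, and delta-vs-bootstrap agreement.

    Each simulated region draws a fresh cohort (n=293) and one region from
    the default R1-like library, cycling through the three tissue classes.
    """
    errors, covered, rel_diff = [], [], []
    for i in range(n_regions):
        tissue = TISSUES[i % 3]
        sizes = {"n_cgm": 0, "n_swm": 0, "n_bundles": 0}
        sizes[{"cGM": "n_cgm", "sWM": "n_swm", "WM_bundle": "n_bundles"}[tissue]] = 1
        cohort = generate_cohort(CohortSpec(seed=_stage_seed(seed, "pr-cohort", i)))
        design = build_design(cohort)
        lib = default_trajectory_library("R1", seed=_stage_seed(seed, "pr-lib", i), **sizes)
        spec = lib.specs[0]
        df = generate_region_metrics(cohort, lib, seed=_stage_seed(seed, "pr-noise", i))
        y = pd.Series(df["value"].to_numpy(), index=df["subject_id"].to_numpy())
        fit = fit_trajectory(design, y, region_id=spec.region_id, tissue=tissue, metric="R1")
        est = estimate_peak(fit, design=design, y=y, B=B, seed=_stage_seed(seed, "pr-boot", i))
        if est.gated or est.peak_age is None:
            # a gated region counts as a miss; keep the denominator honest
            errors.append(np.inf)
            covered.append(False)
            continue
        errors.append(est.peak_age - spec.true_peak)
        covered.append(est.ci95_boot[0] <= spec.true_peak <= est.ci95_boot[1])
        if est.se_delta and est.se_boot is not None:
            rel_diff.append(abs(est.se_boot - est.se_delta) / est.se_delta)
    errors = np.asarray(errors)
    finite = errors[np.isfinite(errors)]
    return {
        "within_5y_rate": float((np.abs(errors) < 5.0).mean()),
        "mean_bias_years": float(finite.mean()),
        "ci_coverage": float(np.mean(covered)),
        "delta_boot_median_rel_diff": float(np.median(rel_diff)) if rel_diff else float("nan"),
        "n_regions": n_regions,
    }


def expv_ratio_experiment(n_regions: int = 100, seed: int = 0) -> dict:
    """Mean spline/polynomial EXPV ratio under quadratic truth."""
    cohort = generate_cohort(CohortSpec(seed=_stage_seed(seed, "expv-cohort")))
    design = build_design(cohort)
    ratios = []
    for i in range(n_regions):
        lib = default_trajectory_library("R1", n_cgm=1, n_swm=0, n_bundles=0,
                                         seed=_stage_seed(seed, "expv-lib", i))
        df = generate_region_metrics(cohort, lib, seed=_stage_seed(seed, "expv-noise", i))
        y = pd.Series(df["value"].to_numpy(), index=df["subject_id"].to_numpy())
        ratios.append(cv_expv(design, y, seed=_stage_seed(seed, "expv-cv", i)).ratio)
    ratios = np.asarray(ratios)
    return {"ratio_mean": float(np.nanmean(ratios)), "n_regions": n_regions}


def gradient_recovery(seed: int = 0, out_dir=None, metrics=("R1", "R2star", "QSM")) -> dict:
    """Full synthetic run: tissue ordering and mean-peak recovery per metric."""
    import tempfile

    cfg = {
        "simulate": {"n_subjects": 293, "metrics": list(metrics),
                     "n_cgm": 41, "n_swm": 41, "n_bundles": 22},
        "alpha": 0.05,
        "bootstrap": 0,
        "cv_folds": 5,
        "seed": seed,
    }
    if out_dir is None:
        with tempfile.TemporaryDirectory() as td:
            res = run_pipeline(cfg, td)
            return _summarize_gradient(res, metrics)
    res = run_pipeline(cfg, out_dir)
    return _summarize_gradient(res, metrics)


def _summarize_gradient(res, metrics) -> dict:
    out = {}
    for m_i, metric in enumerate(metrics):
        truth = res["truth"][m_i].true_peaks()
        true_means = truth.groupby("tissue")["true_peak"].mean()
        grad, verdict = res["gradient"][metric]
        errs = {}
        means = {}
        for _, row in grad.iterrows():
            if row["n_regions_ungated"]:
                means[row["tissue"]] = row["mean_peak"]
                errs[row["tissue"]] = row["mean_peak"] - true_means[row["tissue"]]
        out[metric] = {
            "ordered": verdict["ordered"],
            "tissue_means": means,
            "tissue_mean_errors": errs,
            "max_abs_error": max(abs(v) for v in errs.values()) if errs else float("nan"),
        }
        if metric == "QSM":
            peaks = res["peaks"][metric]
            bundles = peaks[(peaks["tissue"] == "WM_bundle") & (~peaks["gated"].astype(bool))]
            out[metric]["bundle_minimum_frac"] = float(
                (bundles["curvature_sign"] == "minimum").mean()
            ) if len(bundles) else float("nan")
    return out


def covariation_direction(n_regions: int = 8, seed: int = 0) -> dict:
    """Raw-vs-age-adjusted intra-block correlation drop, plus oracle checks.

    Regions share the age trajectory (age-driven common signal) and a weak
    age-independent latent factor; adjusting for the fitted model should
    reduce the mean intra-block correlation.
    """
    from .synthetic import TrajectoryLibrary, TrajectorySpec

    cohort = generate_cohort(CohortSpec(seed=_stage_seed(seed, "cov-cohort")))
    design = build_design(cohort)
    specs = [
        TrajectorySpec(
            region_id=f"BA{i + 1:02d}", tissue="cGM", metric="R1",
            beta0=1.0, beta1=0.02, beta2=-0.00025, sigma=0.012, latent_loading=0.004,
        )
        for i in range(n_regions)
    ]
    df = generate_region_metrics(cohort, TrajectoryLibrary(specs), seed=_stage_seed(seed, "cov-noise"))
    wide = df.pivot_table(index="subject_id", columns=["tissue", "region_id"], values="value")
    fits = [
        fit_trajectory(design, wide[(t, r)], region_id=r, tissue=t, metric="R1")
        for t, r in wide.columns
    ]
    flat = wide.copy()
    flat.columns = [f"{t}:{r}" for t, r in wide.columns]
    tissues = {c: "cGM" for c in flat.columns}
    raw = correlation_matrix(flat, tissues, mode="raw")
    zs = compute_zscores(fits)
    zs["label"] = zs["tissue"] + ":" + zs["region_id"]
    zw = zs.pivot_table(index="subject_id", columns="label", values="z")
    zres = correlation_matrix(zw, tissues, mode="z")
    raw_mean = fisher_average(raw.pairs["r"].dropna().to_numpy())
    z_mean = fisher_average(zres.pairs["r"].dropna().to_numpy())

    # exact-oracle checks for the two pooling/correction primitives
    rng = np.random.default_rng(_stage_seed(seed, "cov-oracle"))
    p = rng.uniform(size=1000)
    m = len(p)
    order = np.argsort(p)
    adj_oracle = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj_oracle[idx] = running
    bh_err = float(np.abs(bh_adjust(p) - adj_oracle).max())
    rs = rng.uniform(-0.95, 0.95, size=200)
    fisher_err = abs(fisher_average(rs) - np.tanh(np.mean(np.arctanh(rs))))
    return {
        "raw_intra_mean_r": float(raw_mean),
        "z_intra_mean_r": float(z_mean),
        "raw_minus_z": float(raw_mean - z_mean),
        "bh_oracle_max_abs_diff": bh_err,
        "fisher_oracle_abs_diff": float(fisher_err),
    }
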