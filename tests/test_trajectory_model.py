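"""Normative-model fitting: design construction, OLS, LRT, spline comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qmriage as q
from qmriage.trajectory import (
    InsufficientDataError,
    KnotCollapseError,
    fit_bspline,
)


class TestBuildDesign:
    def test_reference_coding_of_education(self):
        cohort = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(12)],
                "age": np.linspace(20, 70, 12),
                "sex": ["female", "male"] * 6,
                "education": ["low", "medium", "high"] * 4,
                "moca": [26, 27] * 6,
            }
        )
        d = q.build_design(cohort, center_age=False)
        i_low = d.columns.index("edu_low")
        i_high = d.columns.index("edu_high")
        np.testing.assert_array_equal(d.X[:3, i_low], [1, 0, 0])
        np.testing.assert_array_equal(d.X[:3, i_high], [0, 0, 1])
        # never both dummies set
        assert not np.any((d.X[:, i_low] == 1) & (d.X[:, i_high] == 1))

    def test_age_squared_column(self):
        cohort = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(12)],
                "age": [40.0] * 6 + list(np.linspace(20, 70, 6)),
                "sex": ["female", "male"] * 6,
                "education": ["low", "medium", "high"] * 4,
                "moca": [26, 27] * 6,
            }
        )
        d = q.build_design(cohort, center_age=False)
        assert d.X[0, d.columns.index("age2")] == pytest.approx(1600.0)

    def test_constant_sex_column_dropped_with_warning(self, tiny_cohort):
        males = tiny_cohort.copy()
        males["sex"] = "male"
        with pytest.warns(UserWarning, match="constant covariate"):
            d = q.build_design(males)
        assert "sex" not in d.columns
        assert "sex" in d.dropped_columns
        # fit proceeds on the reduced design
        rng = np.random.default_rng(0)
        y = pd.Series(rng.standard_normal(len(males)), index=males["subject_id"].to_numpy())
        fit = q.fit_quadratic(d, y)
        assert "beta_sex" not in fit.params.index

    def test_missing_covariates_excluded_and_recorded(self, tiny_cohort):
        holes = tiny_cohort.copy()
        holes.loc[0, "moca"] = np.nan
        d = q.build_design(holes)
        assert d.n == len(holes) - 1
        assert holes.loc[0, "subject_id"] in d.dropped_subjects

    def test_too_few_complete_rows(self, tiny_cohort):
        with pytest.raises(InsufficientDataError):
            q.build_design(tiny_cohort.iloc[:5])


class TestFitQuadratic:
    def test_matches_normal_equations_oracle(self, design293):
        """OLS coefficients equal the brute-force (X'X)^-1 X'y solve."""
        rng = np.random.default_rng(99)
        X = design293.X
        XtX_inv = np.linalg.inv(X.T @ X)
        for _ in range(20):
            y = rng.standard_normal(design293.n)
            beta_oracle = XtX_inv @ (X.T @ y)
            fit = q.fit_quadratic(design293, pd.Series(y, index=design293.subject_id))
            np.testing.assert_allclose(
                fit.params_centered.to_numpy(), beta_oracle, rtol=1e-8, atol=1e-12
            )

    def test_constant_response(self, design293):
        y = pd.Series(np.full(design293.n, 3.0), index=design293.subject_id)
        fit = q.fit_quadratic(design293, y)
        assert fit.params["beta1"] == pytest.approx(0.0, abs=1e-10)
        assert fit.params["beta2"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_decentred_coefficients_independent_of_centring(self, cohort293, strong_region):
        _, y = strong_region
        fit_c = q.fit_quadratic(q.build_design(cohort293, center_age=True), y)
        fit_r = q.fit_quadratic(q.build_design(cohort293, center_age=False), y)
        for name in fit_c.params.index:
            assert fit_c.params[name] == pytest.approx(fit_r.params[name], rel=1e-7, abs=1e-12)
            assert fit_c.se[name] == pytest.approx(fit_r.se[name], rel=1e-6, abs=1e-12)

    def test_coefficient_ci_coverage(self, design293):
        """True beta1/beta2 inside +/-1.96 SE in ~95% of simulations."""
        X = design293.X
        n, p = X.shape
        pinv = np.linalg.pinv(X)
        unit_cov = np.linalg.inv(X.T @ X)
        c = design293.age_center
        # truth on the centred scale
        beta_true = np.zeros(p)
        i1, i2 = design293.columns.index("age"), design293.columns.index("age2")
        beta_true[i1], beta_true[i2] = 0.004, -2.5e-5
        rng = np.random.default_rng(7)
        nsim = 1000
        Y = (X @ beta_true)[:, None] + 0.02 * rng.standard_normal((n, nsim))
        B = pinv @ Y
        resid = Y - X @ B
        sigma2 = (resid**2).sum(axis=0) / (n - p)
        cover = np.zeros(2)
        for j, i in enumerate((i1, i2)):
            se = np.sqrt(unit_cov[i, i] * sigma2)
            cover[j] = (np.abs(B[i] - beta_true[i]) <= 1.96 * se).mean()
        assert (cover >= 0.93).all() and (cover <= 0.97).all()


class TestLRT:
    def test_identical_sse_gives_zero_statistic(self, design293):
        """Response built so both nested fits leave identical residuals."""
        rng = np.random.default_rng(4)
        X = design293.X
        Xl = design293.without_quadratic().X
        H = X @ np.linalg.pinv(X)
        Hl = Xl @ np.linalg.pinv(Xl)
        z = rng.standard_normal(design293.n)
        w = rng.standard_normal(Xl.shape[1])
        y = (z - H @ z) + Xl @ w  # residual part orthogonal to both models
        yv = pd.Series(y, index=design293.subject_id)
        stat, p = q.lrt_quadratic(q.fit_linear(design293, yv), q.fit_quadratic(design293, yv))
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_statistic_nonnegative_and_r2_monotone(self, design293):
        rng = np.random.default_rng(5)
        for _ in range(10):
            y = pd.Series(rng.standard_normal(design293.n), index=design293.subject_id)
            fl, fq = q.fit_linear(design293, y), q.fit_quadratic(design293, y)
            stat, p = q.lrt_quadratic(fl, fq)
            assert stat >= 0
            assert 0 <= p <= 1
            assert fq.r2 >= fl.r2 - 1e-12

    def test_strong_quadratic_truth_decisively_rejected(self, design293, strong_region):
        _, y = strong_region
        fit = q.fit_trajectory(design293, y)
        assert fit.lrt_p < 1e-6

    def test_mismatched_fits_rejected(self, design293, strong_region):
        _, y = strong_region
        fq = q.fit_quadratic(design293, y)
        fl = q.fit_linear(design293.take(np.arange(200)), y)
        with pytest.raises(ValueError, match="nested"):
            q.lrt_quadratic(fl, fq)

    def test_null_rejection_rate_calibrated(self, design293):
        """With beta2=0 truth the LRT rejects at close to its nominal level."""
        X = design293.X
        Xl = design293.without_quadratic().X
        n = design293.n
        H = X @ np.linalg.pinv(X)
        Hl = Xl @ np.linalg.pinv(Xl)
        rng = np.random.default_rng(13)
        nsim = 500
        Y = 0.01 * design293.age[:, None] + rng.standard_normal((n, nsim))
        sse = ((Y - H @ Y) ** 2).sum(axis=0)
        ssel = ((Y - Hl @ Y) ** 2).sum(axis=0)
        pvals = stats.chi2.sf(n * np.log(ssel / sse), df=1)
        rate = (pvals < 0.05).mean()
        assert 0.03 <= rate <= 0.08

    def test_f_variant_agrees_in_direction(self, design293, strong_region):
        _, y = strong_region
        fl, fq = q.fit_linear(design293, y), q.fit_quadratic(design293, y)
        f, pf = q.ftest_quadratic(fl, fq)
        assert f > 0 and pf < 1e-6


class TestBSpline:
    def test_quadratic_lies_in_spline_space(self, design293):
        age = design293.age
        y = 1 + 0.02 * age - 0.00025 * age**2
        bs = fit_bspline(np.ones((len(age), 1)), age, y)
        np.testing.assert_allclose(bs.fitted, y, atol=1e-6)

    def test_default_knots_are_age_quantiles(self, design293):
        age = design293.age
        y = np.zeros_like(age)
        bs = fit_bspline(np.ones((len(age), 1)), age, y)
        interior = bs.knots[4:-4]
        np.testing.assert_allclose(interior, np.percentile(age, [25, 50, 75]))

    def test_in_sample_sse_never_above_quadratic(self, design293):
        rng = np.random.default_rng(21)
        X_cov, _ = design293.covariate_columns()
        for _ in range(5):
            y = pd.Series(rng.standard_normal(design293.n), index=design293.subject_id)
            fq = q.fit_quadratic(design293, y)
            bs = fit_bspline(X_cov, design293.age, y.to_numpy())
            assert bs.ssr <= fq.ssr + 1e-8

    def test_too_few_rows(self):
        with pytest.raises(InsufficientDataError):
            fit_bspline(np.ones((5, 1)), np.linspace(20, 60, 5), np.zeros(5))

    def test_degenerate_ages_raise_knot_collapse(self):
        age = np.full(30, 50.0)
        with pytest.raises(KnotCollapseError):
            fit_bspline(np.ones((30, 1)), age, np.zeros(30))


class TestCVEXPV:
    def test_same_seed_same_folds_and_scores(self, design293, strong_region):
        _, y = strong_region
        a = q.cv_expv(design293, y, seed=3)
        b = q.cv_expv(design293, y, seed=3)
        assert a.per_fold_pr == b.per_fold_pr
        assert a.per_fold_bspline == b.per_fold_bspline
        assert a.ratio == b.ratio

    def test_quadratic_truth_ratio_near_one(self, design293, cohort293):
        ratios = []
        for s in range(10):
            lib = q.default_trajectory_library("R1", n_cgm=1, n_swm=0, n_bundles=0, seed=70 + s)
            df = q.generate_region_metrics(cohort293, lib, seed=80 + s)
            y = pd.Series(df["value"].to_numpy(), index=df["subject_id"].to_numpy())
            ratios.append(q.cv_expv(design293, y, seed=s).ratio)
        assert 0.85 <= np.mean(ratios) <= 1.15

    def test_pure_noise_mean_expv_nonpositive(self, design293):
        """Out-of-sample EXPV on pure noise is <= 0 in expectation."""
        rng = np.random.default_rng(2)
        means = []
        for s in range(10):
            y = pd.Series(rng.standard_normal(design293.n), index=design293.subject_id)
            means.append(q.cv_expv(design293, y, seed=s).expv_pr_mean)
        assert np.mean(means) < 0

    def test_undefined_ratio_flagged(self, design293):
        """When the polynomial's best-fold EXPV <= 0 the ratio is NaN + flag."""
        rng = np.random.default_rng(14)
        found = False
        for s in range(30):
            y = pd.Series(rng.standard_normal(design293.n), index=design293.subject_id)
            c = q.cv_expv(design293, y, seed=s)
            if c.expv_pr <= 0:
                assert c.undefined and np.isnan(c.ratio)
                found = True
                break
        assert found, "no pure-noise draw with non-positive best-fold EXPV"

    def test_too_few_rows(self, design293):
        small = design293.take(np.arange(20))
        with pytest.raises(InsufficientDataError):
            q.cv_expv(small, pd.Series(np.zeros(20), index=small.subject_id), k=5)
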