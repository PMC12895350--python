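"""Quadratic normative age model per region, with spline adequacy check.

The normative model per region of interest is an ordinary least-squares fit::

    qMRI = b0 + b1*Age + b2*Age^2 + b3*Sex + b4l*Edu_low + b4h*Edu_high + b5*MoCA

with medium education as the reference category. Age is centred at the sample
mean internally for conditioning and de-centred on output, so reported
coefficients (and their SEs and covariance) are always on the original years
scale. The quadratic term is gated by a likelihood-ratio test against the
nested linear model, ``LR = n * log(SSE_linear / SSE_quadratic)`` compared to
chi-square with 1 df (Gaussian likelihood with the residual variance profiled
out); an F-test variant is available.

Model adequacy is assessed by comparing the polynomial against a cubic
B-spline in age (interior knots at the 25th/50th/75th percentiles of the
training ages, same covariate columns) under a shared, age-decade-stratified
5-fold cross-validation, scoring out-of-sample explained variance
EXPV = 1 - SSE_holdout / SST_holdout. The headline EXPV per model is the
best-performing fold (taken per model independently); the mean across folds
is co-reported because best-fold selection is optimistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import BSpline
from sklearn.model_selection import StratifiedKFold

COEF_NAMES = ("beta0", "beta1", "beta2", "beta_sex", "beta_edu_low", "beta_edu_high", "beta_moca")
_COLUMN_TO_COEF = {
    "const": "beta0",
    "age": "beta1",
    "age2": "beta2",
    "sex": "beta_sex",
    "edu_low": "beta_edu_low",
    "edu_high": "beta_edu_high",
    "moca": "beta_moca",
}


class InsufficientDataError(ValueError):
    """Too few complete rows to fit the model."""


class SingularFitError(ValueError):
    """Design is rank-deficient after constant-column drops."""


@dataclass
class DesignMatrix:
    """Covariate design for the normative model, rows aligned to subjects."""

    X: np.ndarray
    columns: list
    subject_id: np.ndarray
    age: np.ndarray  # original years
    age_center: float
    dropped_subjects: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def take(self, idx) -> "DesignMatrix":
        idx = np.asarray(idx)
        return DesignMatrix(
            X=self.X[idx],
            columns=list(self.columns),
            subject_id=self.subject_id[idx],
            age=self.age[idx],
            age_center=self.age_center,
            dropped_subjects=list(self.dropped_subjects),
            dropped_columns=list(self.dropped_columns),
        )

    def without_quadratic(self) -> "DesignMatrix":
        keep = [i for i, c in enumerate(self.columns) if c != "age2"]
        return DesignMatrix(
            X=self.X[:, keep],
            columns=[self.columns[i] for i in keep],
            subject_id=self.subject_id,
            age=self.age,
            age_center=self.age_center,
            dropped_subjects=list(self.dropped_subjects),
            dropped_columns=list(self.dropped_columns),
        )

    def covariate_columns(self) -> "tuple[np.ndarray, list]":
        """Non-age columns (including intercept), for the spline comparison."""
        keep = [i for i, c in enumerate(self.columns) if c not in ("age", "age2")]
        return self.X[:, keep], [self.columns[i] for i in keep]


def build_design(
    cohort: pd.DataFrame,
    center_age: bool = True,
    female_value: float = 1.0,
) -> DesignMatrix:
    """Build the normative-model design from a validated cohort table.

    Rows with any missing covariate are excluded and recorded. Covariate
    columns that are constant in the complete rows (e.g. an all-male cohort)
    are dropped with a warning.
    """
    needed = ["age", "sex", "education", "moca"]
    complete = cohort[needed].notna().all(axis=1)
    dropped = cohort.loc[~complete, "subject_id"].tolist()
    sub = cohort.loc[complete]
    if len(sub) < 10:
        raise InsufficientDataError(
            f"only {len(sub)} complete rows (need >= 10); dropped {len(dropped)}"
        )

    age = sub["age"].to_numpy(dtype=float)
    center = float(age.mean()) if center_age else 0.0
    age_c = age - center
    sex = np.where(sub["sex"].to_numpy() == "female", female_value, 1.0 - female_value)
    edu = sub["education"].to_numpy()
    cols = {
        "const": np.ones(len(sub)),
        "age": age_c,
        "age2": age_c**2,
        "sex": sex,
        "edu_low": (edu == "low").astype(float),
        "edu_high": (edu == "high").astype(float),
        "moca": sub["moca"].to_numpy(dtype=float),
    }
    dropped_cols = []
    for name in ("sex", "edu_low", "edu_high", "moca"):
        if np.ptp(cols[name]) == 0:
            dropped_cols.append(name)
            del cols[name]
    if dropped_cols:
        warnings.warn(
            f"constant covariate column(s) dropped from design: {dropped_cols}",
            stacklevel=2,
        )
    X = np.column_stack(list(cols.values()))
    return DesignMatrix(
        X=X,
        columns=list(cols.keys()),
        subject_id=sub["subject_id"].to_numpy(),
        age=age,
        age_center=center,
        dropped_subjects=dropped,
        dropped_columns=dropped_cols,
    )


@dataclass
class TrajectoryFit:
    """OLS fit of the normative model for one region x metric.

    Coefficients, SEs and the coefficient covariance are reported on the
    original age scale regardless of internal centring.
    """

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    params_centered: pd.Series  # age terms on the internal centred-age scale
    cov_centered: pd.DataFrame
    residuals: pd.Series  # indexed by subject_id
    sigma: float  # residual SD, ddof = n - p
    resid_sd: float  # sample SD of residuals, ddof = 1
    r2: float
    n_used: int
    ssr: float
    age_range: tuple
    age_center: float
    region_id: str | None = None
    tissue: str | None = None
    metric: str | None = None
    lrt_statistic: float | None = None
    lrt_p: float | None = None

    @property
    def beta1(self) -> float:
        return float(self.params["beta1"])

    @property
    def beta2(self) -> float:
        return float(self.params["beta2"])


def _decentering_transform(columns, center: float) -> np.ndarray:
    """Linear map from centred-age coefficients to original-scale ones.

    With a = age - c: b0' + b1'a + b2'a^2 equals
    (b0' - b1'c + b2'c^2) + (b1' - 2c b2') age + b2' age^2.
    """
    k = len(columns)
    T = np.eye(k)
    idx = {c: i for i, c in enumerate(columns)}
    if center != 0.0 and "age" in idx:
        i0, i1 = idx["const"], idx["age"]
        T[i0, i1] = -center
        if "age2" in idx:
            i2 = idx["age2"]
            T[i0, i2] = center**2
            T[i1, i2] = -2.0 * center
    return T


def _ols_fit(design: DesignMatrix, y: np.ndarray, meta: dict | None = None) -> TrajectoryFit:
    X = design.X
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"n_used={n} must exceed number of columns p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise SingularFitError("design matrix is rank-deficient")
    res = sm.OLS(y, X).fit()

    T = _decentering_transform(design.columns, design.age_center)
    params = T @ res.params
    cov = T @ res.cov_params() @ T.T
    se = np.sqrt(np.diag(cov))
    df_resid = n - p
    tvals = np.divide(params, se, out=np.zeros_like(params), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    names = [_COLUMN_TO_COEF[c] for c in design.columns]
    resid = np.asarray(res.resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(res.ssr) / sst if sst > 0 else 0.0
    cov_c = np.asarray(res.cov_params())
    fit = TrajectoryFit(
        params=pd.Series(params, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        params_centered=pd.Series(np.asarray(res.params), index=names),
        cov_centered=pd.DataFrame(cov_c, index=names, columns=names),
        residuals=pd.Series(resid, index=design.subject_id),
        sigma=float(np.sqrt(res.ssr / df_resid)) if df_resid > 0 else 0.0,
        resid_sd=float(np.std(resid, ddof=1)) if n > 1 else 0.0,
        r2=max(0.0, min(1.0, r2)),
        n_used=n,
        ssr=float(res.ssr),
        age_range=(float(design.age.min()), float(design.age.max())),
        age_center=design.age_center,
        **(meta or {}),
    )
    return fit


def _align_y(design: DesignMatrix, y) -> "tuple[DesignMatrix, np.ndarray]":
    """Align a response to the design rows and drop rows with missing y."""
    if isinstance(y, pd.Series):
        y = y.reindex(design.subject_id).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if y.shape[0] != design.n:
            raise ValueError("y length does not match design rows; pass a Series keyed by subject_id")
    ok = np.isfinite(y)
    if not ok.all():
        design = design.take(np.where(ok)[0])
        y = y[ok]
    return design, y


def fit_quadratic(design: DesignMatrix, y, **meta) -> TrajectoryFit:
    """Fit the full quadratic normative model by OLS."""
    design, y = _align_y(design, y)
    return _ols_fit(design, y, meta)


def fit_linear(design: DesignMatrix, y, **meta) -> TrajectoryFit:
    """Fit the nested model with the quadratic age term removed."""
    design, y = _align_y(design, y)
    return _ols_fit(design.without_quadratic(), y, meta)


def lrt_quadratic(fit_linear: TrajectoryFit, fit_quadratic: TrajectoryFit) -> "tuple[float, float]":
    """Likelihood-ratio test of the quadratic term (chi-square, 1 df).

    Gaussian likelihood with sigma profiled out in both models:
    LR = n * log(SSE_linear / SSE_quadratic).
    """
    if fit_linear.n_used != fit_quadratic.n_used:
        raise ValueError("fits are not nested on identical rows (different n_used)")
    n = fit_quadratic.n_used
    if fit_quadratic.ssr <= 0:
        return float("inf"), 0.0
    stat = max(0.0, n * float(np.log(fit_linear.ssr / fit_quadratic.ssr)))
    p = float(stats.chi2.sf(stat, df=1)) if np.isfinite(stat) else 0.0
    return stat, p


def ftest_quadratic(fit_linear: TrajectoryFit, fit_quadratic: TrajectoryFit) -> "tuple[float, float]":
    """F-test variant of the quadratic-term comparison (1, n-p df)."""
    if fit_linear.n_used != fit_quadratic.n_used:
        raise ValueError("fits are not nested on identical rows (different n_used)")
    n = fit_quadratic.n_used
    p_full = len(fit_quadratic.params)
    df2 = n - p_full
    num = fit_linear.ssr - fit_quadratic.ssr
    if fit_quadratic.ssr <= 0:
        return float("inf"), 0.0
    f = max(0.0, num / (fit_quadratic.ssr / df2))
    return f, float(stats.f.sf(f, 1, df2))


def fit_trajectory(design: DesignMatrix, y, **meta) -> TrajectoryFit:
    """Quadratic fit plus the nested-linear LRT, in one call."""
    design, y = _align_y(design, y)
    fq = _ols_fit(design, y, meta)
    fl = _ols_fit(design.without_quadratic(), y, None)
    fq.lrt_statistic, fq.lrt_p = lrt_quadratic(fl, fq)
    return fq


# --- cubic B-spline comparison model -------------------------------------

class KnotCollapseError(ValueError):
    """Age quantiles coincide; spline knots collapse.

    Spread the age distribution or supply explicit knots.
    """


@dataclass
class BSplineAgeFit:
    """Cubic age B-spline plus covariates, least-squares fit."""

    coefs: np.ndarray
    knots: np.ndarray  # full augmented knot vector
    boundary: tuple
    covariate_columns: list
    fitted: np.ndarray
    ssr: float

    def basis(self, age: np.ndarray) -> np.ndarray:
        age = np.clip(np.asarray(age, dtype=float), *self.boundary)
        B = BSpline.design_matrix(age, self.knots, 3).toarray()
        return B[:, 1:]  # first column dropped against the intercept

    def predict(self, age: np.ndarray, X_cov: np.ndarray) -> np.ndarray:
        Z = np.column_stack([X_cov, self.basis(age)])
        return Z @ self.coefs


def fit_bspline(X_cov: np.ndarray, age: np.ndarray, y: np.ndarray, knots=None) -> BSplineAgeFit:
    """Fit the cubic B-spline comparison model.

    Interior knots default to the 25th/50th/75th percentiles of the supplied
    (training) ages; boundary knots at the training age min/max. Covariate
    columns are passed through unchanged, so the model differs from the
    quadratic one only in its age basis.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(age) < 20:
        raise InsufficientDataError("B-spline comparison requires >= 20 complete rows")
    if knots is None:
        knots = np.percentile(age, [25, 50, 75])
    knots = np.asarray(knots, dtype=float)
    lo, hi = float(age.min()), float(age.max())
    if len(np.unique(np.concatenate([[lo], knots, [hi]]))) != len(knots) + 2:
        raise KnotCollapseError(
            f"degenerate age distribution: knots {knots} collide with boundaries ({lo}, {hi})"
        )
    t = np.concatenate([[lo] * 4, knots, [hi] * 4])
    B = BSpline.design_matrix(age, t, 3).toarray()[:, 1:]
    Z = np.column_stack([X_cov, B])
    coefs, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    fitted = Z @ coefs
    return BSplineAgeFit(
        coefs=coefs,
        knots=t,
        boundary=(lo, hi),
        covariate_columns=[],
        fitted=fitted,
        ssr=float(np.sum((y - fitted) ** 2)),
    )


@dataclass
class EXPVComparison:
    """Shared-fold CV comparison of the quadratic and B-spline age models."""

    expv_pr: float  # best fold
    expv_bspline: float  # best fold
    ratio: float  # bspline / pr on best folds; NaN when undefined
    per_fold_pr: list
    per_fold_bspline: list
    expv_pr_mean: float
    expv_bspline_mean: float
    ratio_of_means: float
    seed: int
    undefined: bool = False


def _decade_labels(age: np.ndarray) -> np.ndarray:
    edges = np.array([18.0, 31.0, 41.0, 51.0, 61.0, 71.0, np.inf])
    return np.searchsorted(edges, age, side="right")


def cv_expv(design: DesignMatrix, y, k: int = 5, seed: int = 0) -> EXPVComparison:
    """Out-of-sample EXPV for polynomial vs B-spline under shared folds.

    Folds are stratified by age decade (stabilises the holdout SST) and are
    identical for both models. Per fold, EXPV = 1 - SSE/SST on the holdout.
    When the polynomial's best-fold EXPV is <= 0 the ratio is undefined
    (reported NaN, flagged).
    """
    design, yv = _align_y(design, y)
    n = design.n
    if n < 5 * k:
        raise InsufficientDataError(f"n_used={n} < 5*k={5 * k}")
    strata = _decade_labels(design.age)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    X = design.X
    X_cov, _ = design.covariate_columns()

    pr_scores, bs_scores = [], []
    for train, test in skf.split(X, strata):
        # polynomial: least-squares on the full design
        beta, _, _, _ = np.linalg.lstsq(X[train], yv[train], rcond=None)
        pred_pr = X[test] @ beta
        # spline: knots from the training ages of this fold
        bs = fit_bspline(X_cov[train], design.age[train], yv[train])
        pred_bs = bs.predict(design.age[test], X_cov[test])

        yt = yv[test]
        sst = float(np.sum((yt - yt.mean()) ** 2))
        if sst <= 0:
            pr_scores.append(np.nan)
            bs_scores.append(np.nan)
            continue
        pr_scores.append(1.0 - float(np.sum((yt - pred_pr) ** 2)) / sst)
        bs_scores.append(1.0 - float(np.sum((yt - pred_bs) ** 2)) / sst)

    best_pr = float(np.nanmax(pr_scores))
    best_bs = float(np.nanmax(bs_scores))
    mean_pr = float(np.nanmean(pr_scores))
    mean_bs = float(np.nanmean(bs_scores))
    undefined = best_pr <= 0
    ratio = float("nan") if undefined else best_bs / best_pr
    ratio_means = float("nan") if mean_pr <= 0 else mean_bs / mean_pr
    return EXPVComparison(
        expv_pr=best_pr,
        expv_bspline=best_bs,
        ratio=ratio,
        per_fold_pr=pr_scores,
        per_fold_bspline=bs_scores,
        expv_pr_mean=mean_pr,
        expv_bspline_mean=mean_bs,
        ratio_of_means=ratio_means,
        seed=seed,
        undefined=undefined,
    )
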