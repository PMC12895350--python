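"""Peak-age (turning point) inference for quadratic age trajectories.

The vertex of the fitted quadratic, ``Age_peak = -b1 / (2*b2)``, marks the age
at which an inverted-U trajectory (b2 < 0) peaks, or a U-shaped trajectory
(b2 > 0, typical of white-matter-bundle susceptibility) bottoms out.

Its standard error follows first-order error propagation as commonly printed::

    SE_peak = sqrt[ (SE_b1 / (2 b2))^2 + (b1 * SE_b2 / (2 b2^2))^2 ]

This form omits the b1-b2 covariance cross-term, so it is evaluated on the
centred-age parametrization the model is actually fit on: for a roughly
symmetric age distribution the centred b1 and b2 are nearly uncorrelated and
the omitted term is negligible, whereas on the raw age scale it would inflate
the SE several-fold. ``include_covariance=True`` gives the full first-order
delta method (adds 2 * d1 * d2 * cov(b1, b2) with d1 = -1/(2 b2),
d2 = b1/(2 b2^2)), which is parametrization-invariant.

Robustness is quantified by a subject-level bootstrap: subjects are resampled
with replacement, the full normative model refit per replicate, and the vertex
re-evaluated. Replicates with a near-zero quadratic coefficient or a vertex
far outside the observed age span (beyond +/-20 years) are counted invalid and
excluded from the SE and the 2.5/97.5 percentile interval; all exclusions are
reported.

Peaks are only reported for regions whose quadratic term survives the
likelihood-ratio gate (p < alpha, strict); the gate is evaluated on the
original fit, not per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import DesignMatrix, TrajectoryFit, _align_y, _decentering_transform


class UndefinedPeakError(ValueError):
    """The quadratic coefficient is zero; the vertex does not exist."""


def peak_age(beta1: float, beta2: float) -> "tuple[float, str]":
    """Vertex of the quadratic: (-b1/(2 b2), 'maximum' if b2 < 0 else 'minimum')."""
    if beta2 == 0:
        raise UndefinedPeakError("peak age undefined: quadratic coefficient is zero")
    return -beta1 / (2.0 * beta2), ("maximum" if beta2 < 0 else "minimum")


def peak_age_se(
    beta1: float,
    beta2: float,
    se1: float,
    se2: float,
    cov12: float = 0.0,
    include_covariance: bool = False,
) -> float:
    """Error-propagation SE of the peak age (years).

    Default is the printed propagation formula (no covariance term); set
    ``include_covariance=True`` for the full first-order delta method using
    ``cov12 = cov(b1, b2)``.
    """
    if beta2 == 0:
        raise UndefinedPeakError("peak-age SE undefined: quadratic coefficient is zero")
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    d1 = -1.0 / (2.0 * beta2)
    d2 = beta1 / (2.0 * beta2**2)
    var = (d1 * se1) ** 2 + (d2 * se2) ** 2
    if include_covariance:
        var += 2.0 * d1 * d2 * cov12
    return float(np.sqrt(max(var, 0.0)))


def gate_peak(fit: TrajectoryFit, alpha: float = 0.05) -> bool:
    """True when the quadratic term fails its LRT (p >= alpha, strict gate)."""
    if fit.lrt_p is None:
        raise ValueError("fit carries no LRT p-value; fit with fit_trajectory()")
    return bool(fit.lrt_p >= alpha)


@dataclass
class BootstrapPeakResult:
    se_boot: float
    ci95_boot: tuple
    n_boot_valid: int
    n_boot: int
    peaks: np.ndarray  # valid replicate peaks
    unstable: bool  # fewer than half the replicates valid


@dataclass
class PeakAgeEstimate:
    """Peak age with delta-method and bootstrap uncertainty, plus gating."""

    region_id: str | None
    tissue: str | None
    metric: str | None
    peak_age: float | None
    curvature_sign: str | None
    se_delta: float | None
    se_boot: float | None
    ci95_boot: tuple | None
    n_boot_valid: int | None
    gated: bool
    in_range: bool | None


def bootstrap_peak(
    design: DesignMatrix,
    y,
    B: int = 10_000,
    seed: int = 0,
    window_pad: float = 20.0,
) -> BootstrapPeakResult:
    """Subject-level bootstrap of the peak age; deterministic given seed."""
    if B < 100:
        raise ValueError("B must be >= 100")
    design, yv = _align_y(design, y)
    X = design.X
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    T = _decentering_transform(design.columns, design.age_center)
    i_age = design.columns.index("age")
    i_age2 = design.columns.index("age2")

    # full-sample fit sets the conditioning floor on |b2|
    beta_full, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    b2_full = (T @ beta_full)[i_age2]
    floor = np.sqrt(np.finfo(float).eps) * max(abs(b2_full), np.finfo(float).tiny)

    lo = design.age.min() - window_pad
    hi = design.age.max() + window_pad

    peaks = np.empty(B)
    valid = np.zeros(B, dtype=bool)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        yb = yv[idx]
        G = Xb.T @ Xb
        try:
            beta = np.linalg.solve(G, Xb.T @ yb)
        except np.linalg.LinAlgError:
            beta, _, _, _ = np.linalg.lstsq(Xb, yb, rcond=None)
        bo = T @ beta
        b1, b2 = bo[i_age], bo[i_age2]
        if abs(b2) <= floor:
            continue
        pk = -b1 / (2.0 * b2)
        if lo <= pk <= hi:
            peaks[b] = pk
            valid[b] = True

    valid_peaks = peaks[valid]
    n_valid = int(valid.sum())
    unstable = n_valid < 0.5 * B
    if unstable:
        warnings.warn(
            f"bootstrap peak unstable: only {n_valid}/{B} valid replicates", stacklevel=2
        )
    if n_valid == 0:
        return BootstrapPeakResult(float("nan"), (float("nan"), float("nan")), 0, B, valid_peaks, True)
    se = float(np.std(valid_peaks, ddof=1)) if n_valid > 1 else 0.0
    ci = tuple(np.percentile(valid_peaks, [2.5, 97.5]))
    return BootstrapPeakResult(se, (float(ci[0]), float(ci[1])), n_valid, B, valid_peaks, unstable)


def estimate_peak(
    fit: TrajectoryFit,
    design: DesignMatrix | None = None,
    y=None,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    include_covariance: bool = False,
) -> PeakAgeEstimate:
    """Assemble the full peak-age record for one fitted region.

    Gated regions (LRT p >= alpha) carry no peak fields. The bootstrap is run
    only when ``design`` and ``y`` are supplied.
    """
    gated = gate_peak(fit, alpha)
    meta = dict(region_id=fit.region_id, tissue=fit.tissue, metric=fit.metric)
    if gated:
        return PeakAgeEstimate(
            **meta,
            peak_age=None,
            curvature_sign=None,
            se_delta=None,
            se_boot=None,
            ci95_boot=None,
            n_boot_valid=None,
            gated=True,
            in_range=None,
        )
    pk, sign = peak_age(fit.beta1, fit.beta2)
    # evaluate the propagation formula on the fitted (centred-age) coefficients,
    # where the b1-b2 covariance is near zero and the printed form is accurate
    b1c = float(fit.params_centered["beta1"])
    b2c = float(fit.params_centered["beta2"])
    se_d = peak_age_se(
        b1c,
        b2c,
        float(np.sqrt(fit.cov_centered.loc["beta1", "beta1"])),
        float(np.sqrt(fit.cov_centered.loc["beta2", "beta2"])),
        cov12=float(fit.cov_centered.loc["beta1", "beta2"]),
        include_covariance=include_covariance,
    )
    se_b = ci = n_valid = None
    if design is not None and y is not None:
        boot = bootstrap_peak(design, y, B=B, seed=seed)
        se_b, ci, n_valid = boot.se_boot, boot.ci95_boot, boot.n_boot_valid
    in_range = bool(fit.age_range[0] <= pk <= fit.age_range[1])
    return PeakAgeEstimate(
        **meta,
        peak_age=float(pk),
        curvature_sign=sign,
        se_delta=se_d,
        se_boot=se_b,
        ci95_boot=ci,
        n_boot_valid=n_valid,
        gated=False,
        in_range=in_range,
    )


def peaks_to_frame(estimates) -> pd.DataFrame:
    """Long-format peak table (one row per region), ready for delimited output."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "region_id": e.region_id,
                "tissue": e.tissue,
                "metric": e.metric,
                "peak_age": e.peak_age,
                "curvature_sign": e.curvature_sign,
                "se_delta": e.se_delta,
                "se_boot": e.se_boot,
                "ci95_low": None if e.ci95_boot is None else e.ci95_boot[0],
                "ci95_high": None if e.ci95_boot is None else e.ci95_boot[1],
                "n_boot_valid": e.n_boot_valid,
                "gated": e.gated,
                "in_range": e.in_range,
            }
        )
    return pd.DataFrame(rows)
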