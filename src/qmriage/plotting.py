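"""Minimal figures: per-region trajectory panels and correlation heatmaps."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_region_trajectory(fit, cohort, y, boot_peaks=None, ax=None):
    """Scatter + fitted quadratic age curve, with an optional bootstrap CI band.

    The curve shows the age trend at the covariate means; the shaded band, when
    bootstrap replicate peaks are supplied, marks the 95% interval of the peak
    age location.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    age = cohort["age"].to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    ax.scatter(age, yv, s=8, alpha=0.4, color="steelblue")

    grid = np.linspace(np.nanmin(age), np.nanmax(age), 200)
    p = fit.params
    curve = p["beta0"] + p["beta1"] * grid + p["beta2"] * grid**2
    offset = float(np.nanmean(yv - (p["beta0"] + p["beta1"] * age + p["beta2"] * age**2)))
    ax.plot(grid, curve + offset, color="crimson", lw=1.5)
    if boot_peaks is not None and len(boot_peaks):
        lo, hi = np.percentile(boot_peaks, [2.5, 97.5])
        ax.axvspan(lo, hi, alpha=0.15, color="crimson")
    ax.set_xlabel("age (years)")
    ax.set_ylabel(f"{fit.metric or 'value'}")
    ax.set_title(f"{fit.region_id or ''} {fit.tissue or ''}".strip())
    return ax


def plot_correlation_heatmap(result, ax=None, cmap="RdBu_r"):
    """Square heatmap of a CovariationResult's correlation matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mat = result.square("r")
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap=cmap)
    ax.set_xticks(range(len(mat.columns)))
    ax.set_xticklabels(mat.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(mat.index)))
    ax.set_yticklabels(mat.index, fontsize=5)
    ax.set_title(f"Pearson r ({result.mode})")
    plt.colorbar(im, ax=ax, fraction=0.046)
    return ax
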