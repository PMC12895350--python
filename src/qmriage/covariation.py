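"""Regional covariation: raw and age-adjusted Pearson correlation structure.

Two complementary correlation analyses over cortical grey matter and
superficial white matter regions:

* **raw mode** — Pearson correlations of the regional metric values
  themselves. Regions sharing an age trajectory correlate strongly, so this
  view mixes joint ageing with any age-independent coupling.
* **z mode** — correlations of per-region standardized residuals from the
  quadratic normative model (age, age^2, sex, education, cognition removed),
  exposing covariance independent of ageing. Only regions whose quadratic
  fit survived the likelihood-ratio gate enter this mode.

Correlations use pairwise-complete observations (cells with fewer than three
complete pairs are left missing); two-sided p-values come from the exact
t-transform with n_pairs - 2 degrees of freedom. Multiplicity is controlled by
Benjamini-Hochberg within each mode x block family by default (blocks:
intra-cGM, intra-sWM, inter cGM-sWM); the family definition is configurable.
Correlation coefficients are pooled on the Fisher-Z scale,
tanh(mean(atanh(r))).
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def compute_zscores(fits) -> pd.DataFrame:
    """Standardized residual scores, one row per subject x region.

    z = residual / sample SD of residuals, per region x metric; regions with
    zero residual SD are flagged degenerate and excluded (with a warning).
    Subjects dropped from a region's fit simply have no row for that region.
    """
    frames = []
    for fit in fits:
        if fit.resid_sd == 0 or fit.r2 >= 1.0 - 1e-12:
            warnings.warn(
                f"region {fit.region_id}: zero residual SD, z-scores undefined; skipped",
                stacklevel=2,
            )
            continue
        z = fit.residuals / fit.resid_sd
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": z.index,
                    "region_id": fit.region_id,
                    "tissue": fit.tissue,
                    "metric": fit.metric,
                    "z": z.to_numpy(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["subject_id", "region_id", "tissue", "metric", "z"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class CovariationResult:
    """Pairwise Pearson structure with BH-adjusted p-values."""

    pairs: pd.DataFrame  # region_i, region_j, block, r, p, p_adj, n_pairs
    mode: str  # {raw, z}
    regions: list = field(default_factory=list)
    tissues: dict = field(default_factory=dict)

    def square(self, column: str = "r") -> pd.DataFrame:
        mat = pd.DataFrame(np.eye(len(self.regions)) if column == "r" else np.zeros((len(self.regions),) * 2),
                           index=self.regions, columns=self.regions)
        for _, row in self.pairs.iterrows():
            mat.loc[row["region_i"], row["region_j"]] = row[column]
            mat.loc[row["region_j"], row["region_i"]] = row[column]
        return mat

    def block_mean_r(self, block: str) -> float:
        rs = self.pairs.loc[self.pairs["block"] == block, "r"].dropna()
        return fisher_average(rs.to_numpy()) if len(rs) else float("nan")


def _block_label(t1: str, t2: str) -> str:
    if t1 == t2:
        return f"{t1}-{t1}"
    return "-".join(sorted((t1, t2)))


def correlation_matrix(
    values: pd.DataFrame,
    tissues: dict,
    mode: str = "raw",
    min_pairs: int = 3,
    bh_family: str = "block",
) -> CovariationResult:
    """Pairwise-complete Pearson correlations across regions.

    Parameters
    ----------
    values : wide table, subjects x regions (NaN = missing).
    tissues : region_id -> tissue label, used for block structure.
    mode : 'raw' for metric values, 'z' for age-adjusted residual scores
        (a label carried through to the output).
    min_pairs : cells with fewer complete pairs are left missing.
    bh_family : 'block' adjusts within each (mode, block) family,
        'matrix' across the whole matrix.
    """
    if mode not in ("raw", "z"):
        raise ValueError(f"mode must be 'raw' or 'z', got {mode!r}")
    regions = list(values.columns)
    # drop regions that cannot form a single valid pair
    notna = values.notna().to_numpy(dtype=float)
    pair_counts = notna.T @ notna
    usable = pair_counts >= min_pairs
    np.fill_diagonal(usable, True)
    isolated = [r for i, r in enumerate(regions) if not usable[i].sum() > 1]
    if isolated:
        warnings.warn(
            f"{len(isolated)} region(s) with < {min_pairs} complete pairs against all others "
            f"excluded: {isolated[:5]}",
            stacklevel=2,
        )
        values = values.drop(columns=isolated)
        regions = list(values.columns)
        notna = values.notna().to_numpy(dtype=float)
        pair_counts = notna.T @ notna

    r = values.corr(method="pearson", min_periods=min_pairs).to_numpy()
    n = pair_counts

    rows = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            rij = r[i, j]
            nij = int(n[i, j])
            if nij < min_pairs or not np.isfinite(rij):
                p = np.nan
            else:
                df = nij - 2
                rr = min(max(rij, -1.0), 1.0)
                if abs(rr) >= 1.0:
                    p = 0.0
                else:
                    t = rr * np.sqrt(df / (1.0 - rr * rr))
                    p = 2.0 * stats.t.sf(abs(t), df)
            rows.append(
                {
                    "region_i": regions[i],
                    "region_j": regions[j],
                    "block": _block_label(tissues.get(regions[i], "?"), tissues.get(regions[j], "?")),
                    "r": rij if np.isfinite(rij) else np.nan,
                    "p": p,
                    "n_pairs": nij,
                }
            )
    pairs = pd.DataFrame(rows)
    pairs["p_adj"] = np.nan
    families = pairs["block"] if bh_family == "block" else pd.Series("all", index=pairs.index)
    for _, idx in pairs.groupby(families).groups.items():
        sub = pairs.loc[idx, "p"]
        ok = sub.notna()
        if ok.any():
            pairs.loc[sub.index[ok], "p_adj"] = bh_adjust(sub[ok].to_numpy())
    return CovariationResult(pairs=pairs, mode=mode, regions=regions, tissues=dict(tissues))


def fisher_average(rs) -> float:
    """Pool correlation coefficients on the Fisher-Z scale: tanh(mean(atanh(r)))."""
    rs = np.asarray(rs, dtype=float)
    if np.any(np.abs(rs) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    if np.any(np.abs(rs) == 1):
        warnings.warn("|r| = 1 clipped to 1 - 1e-12 before Fisher transform", stacklevel=2)
        rs = np.clip(rs, -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
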