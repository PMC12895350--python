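"""Tissue-level summaries: the peak-age gradient and covariate tallies.

The central descriptive claim of the analysis is an ordering of mean peak
ages across tissue classes — deep white-matter bundles turn earliest,
superficial white matter next, cortical grey matter last (WM < sWM < cGM).
:func:`tissue_gradient` computes per-tissue means over the ungated, in-range
peaks and reports whether that ordering holds, together with pairwise
differences. Dispersion across regions is reported both as SD and as SE,
labelled explicitly, because a bare "+/-" is ambiguous between the two.

:func:`covariate_summary` tallies, per covariate and tissue, how many
regional models carry a significant coefficient (t-test on the coefficient),
as counts like "12/41". Raw-alpha counts are the default headline, with
BH-adjusted counts alongside. Education counts a region once if either of
its two dummies (low or high vs the medium reference) is significant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariation import bh_adjust

TISSUE_ORDER = ("WM_bundle", "sWM", "cGM")


def tissue_gradient(peaks: pd.DataFrame) -> "tuple[pd.DataFrame, dict]":
    """Per-tissue peak-age summaries plus the ordering verdict.

    Parameters
    ----------
    peaks : long peak table (as from :func:`qmriage.peaks.peaks_to_frame`),
        one row per region with ``peak_age``, ``gated``, ``in_range``.

    Returns
    -------
    (summary, verdict) : summary has one row per tissue (n_regions_ungated,
        mean_peak, sd_peak, se_peak, regions); verdict reports whether
        mean(WM_bundle) < mean(sWM) < mean(cGM) and the pairwise differences,
        and is marked incomplete when any tissue has no usable peak.
    """
    in_ok = peaks["in_range"].map(lambda v: bool(v) if pd.notna(v) else False)
    usable = peaks[(~peaks["gated"].astype(bool)) & in_ok]
    rows = []
    means = {}
    for tissue in TISSUE_ORDER:
        grp = usable[usable["tissue"] == tissue]["peak_age"].dropna()
        if len(grp) == 0:
            rows.append(
                {"tissue": tissue, "n_regions_ungated": 0, "mean_peak": np.nan,
                 "sd_peak": np.nan, "se_peak": np.nan, "regions": ""}
            )
            continue
        sd = float(grp.std(ddof=1)) if len(grp) > 1 else 0.0
        means[tissue] = float(grp.mean())
        rows.append(
            {
                "tissue": tissue,
                "n_regions_ungated": int(len(grp)),
                "mean_peak": float(grp.mean()),
                "sd_peak": sd,
                "se_peak": sd / np.sqrt(len(grp)),
                "regions": ";".join(usable.loc[grp.index, "region_id"].astype(str)),
            }
        )
    summary = pd.DataFrame(rows)
    incomplete = len(means) < len(TISSUE_ORDER)
    diffs = {}
    for a, b in (("WM_bundle", "sWM"), ("sWM", "cGM"), ("WM_bundle", "cGM")):
        if a in means and b in means:
            diffs[f"{b}-{a}"] = means[b] - means[a]
    ordered = (
        not incomplete
        and means["WM_bundle"] < means["sWM"] < means["cGM"]
    )
    verdict = {"ordered": bool(ordered), "incomplete": incomplete, "pairwise_differences": diffs}
    return summary, verdict


_COVARIATE_COEFS = {
    "sex": ("beta_sex",),
    "moca": ("beta_moca",),
    "education": ("beta_edu_low", "beta_edu_high"),
}


def covariate_summary(fits, alpha: float = 0.05) -> pd.DataFrame:
    """Counts of regions with significant covariate coefficients, per tissue.

    A region counts for education if either dummy is significant; the
    BH-adjusted count uses a per-region education p of min(1, 2*min(p_low,
    p_high)) so each region contributes one p-value to the family.
    """
    records = []
    for covariate, coefs in _COVARIATE_COEFS.items():
        per_tissue = {}
        for fit in fits:
            ps = [float(fit.pvalues[c]) for c in coefs if c in fit.pvalues.index]
            if not ps:
                continue
            p_region = min(1.0, len(ps) * min(ps)) if len(ps) > 1 else ps[0]
            raw_sig = any(p < alpha for p in ps)
            per_tissue.setdefault(fit.tissue, []).append((p_region, raw_sig))
        for tissue, entries in per_tissue.items():
            p_adj = bh_adjust([p for p, _ in entries])
            records.append(
                {
                    "covariate": covariate,
                    "tissue": tissue,
                    "metric": fits[0].metric if fits else None,
                    "n_regions": len(entries),
                    "n_significant_raw": int(sum(sig for _, sig in entries)),
                    "n_significant_bh": int((p_adj < alpha).sum()),
                }
            )
    return pd.DataFrame(records)
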