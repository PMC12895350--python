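"""Subject and region-metric tables: schema, validation, IO and aggregation.

Two delimited-text (CSV, UTF-8, header row) tables drive the whole analysis:

* the **cohort table** — one row per participant with ``subject_id``, ``age``
  (years, continuous), ``sex`` (female/male), ``education`` (ISCED low /
  medium / high) and ``moca`` (Montreal Cognitive Assessment, 0-30);
* the **region-metric table** — one row per subject x region x metric x
  hemisphere with the tissue class (cortical grey matter ``cGM``, superficial
  white matter ``sWM``, or deep white-matter bundle ``WM_bundle``) and the
  quantitative-MRI value (R1 and R2* in 1/s, QSM in ppb). Values may be
  missing; missingness propagates as pairwise-complete handling downstream and
  is never imputed.

Aggregation conventions implemented here:

* :func:`robust_regional_mean` — regional averaging that excludes values whose
  magnitude exceeds three times the magnitude of the median (guarding against
  vessel artefacts / segmentation errors in voxel-level value lists). The rule
  is applied to magnitudes because QSM regional medians are frequently
  negative (e.g. -21 ppb) and a signed threshold is ill-defined there.
* :func:`bilateralize` — cortical (cGM, sWM) left/right pairs averaged into
  ``hemisphere='bilateral'`` rows; WM bundles keep their per-hemisphere rows
  because left and right tracts age on distinct trajectories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("cGM", "sWM", "WM_bundle")
METRICS = ("R1", "R2star", "QSM")
HEMISPHERES = ("left", "right", "bilateral")
SEXES = ("female", "male")
EDUCATION_LEVELS = ("low", "medium", "high")

#: Brodmann-area parcels used for cGM and sWM (41 labels).
DEFAULT_BA_REGIONS = tuple(
    f"BA{n:02d}"
    for n in (*range(1, 12), *range(17, 43), 44, 45, 46, 47)
)

#: Deep white-matter bundle codes: forceps minor/major plus ten bilateral
#: tracts kept separate per hemisphere (22 labels).
_BILATERAL_TRACTS = ("ARC", "pARC", "ATR", "CGC", "CST", "IFO", "ILF", "SLF", "VOF", "UNC")
DEFAULT_BUNDLE_REGIONS = ("FA", "FP") + tuple(
    f"{t}_{h}" for t in _BILATERAL_TRACTS for h in ("L", "R")
)

COHORT_COLUMNS = ("subject_id", "age", "sex", "education", "moca")
METRIC_COLUMNS = ("subject_id", "region_id", "tissue", "metric", "hemisphere", "value")

STUDY_AGE_RANGE = (18.0, 79.0)
MOCA_RANGE = (0, 30)


class SchemaError(ValueError):
    """A mandatory column is missing or a closed-vocabulary label is unknown."""


class IntegrityError(ValueError):
    """Duplicate keys or other cross-row inconsistencies."""


@dataclass
class ValidationReport:
    """Summary of checks applied while reading a table."""

    n_rows: int = 0
    missing_per_column: dict = field(default_factory=dict)
    out_of_range: dict = field(default_factory=dict)
    duplicate_keys: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"rows: {self.n_rows}"]
        for col, k in self.missing_per_column.items():
            lines.append(f"missing[{col}]: {k}")
        for col, k in self.out_of_range.items():
            lines.append(f"out_of_range[{col}]: {k}")
        if self.duplicate_keys:
            lines.append(f"duplicate_keys: {len(self.duplicate_keys)}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing mandatory column(s): {', '.join(missing)}")


def validate_cohort(df: pd.DataFrame) -> ValidationReport:
    """Validate a cohort table in place; raises on hard errors, warns otherwise."""
    _require_columns(df, COHORT_COLUMNS, "cohort")
    report = ValidationReport(n_rows=len(df))
    report.missing_per_column = {c: int(df[c].isna().sum()) for c in COHORT_COLUMNS}

    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        report.duplicate_keys = dup.tolist()
        raise IntegrityError(f"duplicate subject_id values: {sorted(set(dup))}")

    bad_sex = ~df["sex"].isin(SEXES) & df["sex"].notna()
    if bad_sex.any():
        raise SchemaError(f"unknown sex labels: {sorted(df.loc[bad_sex, 'sex'].unique())}")
    bad_edu = ~df["education"].isin(EDUCATION_LEVELS) & df["education"].notna()
    if bad_edu.any():
        raise SchemaError(
            f"unknown education labels: {sorted(df.loc[bad_edu, 'education'].unique())}"
        )

    lo, hi = STUDY_AGE_RANGE
    outside = ((df["age"] < lo) | (df["age"] > hi)) & df["age"].notna()
    report.out_of_range["age"] = int(outside.sum())
    if outside.any():
        msg = f"{int(outside.sum())} subject(s) outside the {lo:.0f}-{hi:.0f} y study age range"
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)

    moca_bad = ((df["moca"] < MOCA_RANGE[0]) | (df["moca"] > MOCA_RANGE[1])) & df["moca"].notna()
    report.out_of_range["moca"] = int(moca_bad.sum())
    if moca_bad.any():
        msg = f"{int(moca_bad.sum())} MoCA score(s) outside {MOCA_RANGE}"
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return report


def validate_region_metrics(df: pd.DataFrame) -> ValidationReport:
    _require_columns(df, METRIC_COLUMNS, "region-metric")
    report = ValidationReport(n_rows=len(df))
    report.missing_per_column = {c: int(df[c].isna().sum()) for c in METRIC_COLUMNS}

    key = ["subject_id", "region_id", "tissue", "metric", "hemisphere"]
    dup_mask = df.duplicated(subset=key, keep=False)
    if dup_mask.any():
        dup_keys = df.loc[df.duplicated(subset=key), key].apply(tuple, axis=1).tolist()
        report.duplicate_keys = dup_keys
        raise IntegrityError(f"duplicate (subject, region, tissue, metric, hemisphere) keys: {dup_keys[:5]}")

    for col, vocab in (("tissue", TISSUES), ("metric", METRICS), ("hemisphere", HEMISPHERES)):
        bad = ~df[col].isin(vocab) & df[col].notna()
        if bad.any():
            raise SchemaError(f"unknown {col} labels: {sorted(df.loc[bad, col].unique())}")
    return report


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table; ValidationReport in ``df.attrs``."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    report = validate_cohort(df)
    df.attrs["validation"] = report
    return df


def read_region_metrics(path) -> pd.DataFrame:
    """Read and validate a region-metric table; ValidationReport in ``df.attrs``."""
    df = pd.read_csv(path, dtype={"subject_id": str, "region_id": str})
    report = validate_region_metrics(df)
    df.attrs["validation"] = report
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in df.columns])


def write_region_metrics(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in df.columns])


def robust_regional_mean(values) -> float:
    """Mean after excluding values whose magnitude exceeds 3x the median magnitude.

    Falls back to the plain mean when the exclusion would discard every value
    (e.g. a median of exactly zero with all values nonzero).
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("robust_regional_mean requires at least one finite value")
    threshold = 3.0 * abs(np.median(arr))
    keep = np.abs(arr) <= threshold
    if not keep.any():
        logger.info("outlier rule would exclude all %d values; returning plain mean", arr.size)
        return float(arr.mean())
    n_excluded = int(arr.size - keep.sum())
    if n_excluded:
        logger.info("outlier rule excluded %d of %d values", n_excluded, arr.size)
    return float(arr[keep].mean())


def bilateralize(table: pd.DataFrame) -> pd.DataFrame:
    """Average cortical (cGM/sWM) left-right pairs into bilateral rows.

    WM-bundle rows pass through unchanged. A cortical region present in only
    one hemisphere is passed through relabelled bilateral, with a warning.
    Idempotent: a table with only bilateral rows is returned unchanged.
    """
    cortical = table["tissue"].isin(("cGM", "sWM"))
    lateral = table["hemisphere"].isin(("left", "right"))
    todo = table[cortical & lateral]
    keep = table[~(cortical & lateral)]
    if todo.empty:
        return table.copy()

    merged_rows = []
    key = ["subject_id", "region_id", "tissue", "metric"]
    for group_key, grp in todo.groupby(key, sort=False):
        hemis = set(grp["hemisphere"])
        if hemis != {"left", "right"}:
            msg = f"cortical region {group_key} present only in {sorted(hemis)}; passing through as bilateral"
            warnings.warn(msg, stacklevel=2)
        row = grp.iloc[0].copy()
        row["hemisphere"] = "bilateral"
        row["value"] = grp["value"].mean()
        merged_rows.append(row)
    merged = pd.DataFrame(merged_rows)
    out = pd.concat([keep, merged], ignore_index=True)
    return out.reset_index(drop=True)
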