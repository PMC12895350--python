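"""Shared paths and loaders for the numbered analysis drivers.

The drivers run in order: 01 writes the simulated study-scale dataset under
``scratch/sim`` (bulky, regenerable), later steps read it back and deposit
small summary tables under ``results/analysis``.
"""

from pathlib import Path

import qmriage as q

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "sim"
OUT_DIR = ROOT / "results" / "analysis"

METRICS = ("R1", "R2star", "QSM")
SEED = 7


def load_dataset():
    cohort = q.read_cohort(SIM_DIR / "cohort.csv")
    metrics = q.read_region_metrics(SIM_DIR / "region_metrics.csv")
    return cohort, metrics


def fit_all(cohort, metrics):
    """Fit the quadratic normative model for every region x metric."""
    design = q.build_design(cohort)
    out = {}
    for metric in sorted(metrics["metric"].unique()):
        sub = metrics[metrics["metric"] == metric]
        wide = sub.pivot_table(index="subject_id", columns=["tissue", "region_id"], values="value")
        fits = [
            q.fit_trajectory(design, wide[(t, r)], region_id=r, tissue=t, metric=metric)
            for t, r in sorted(wide.columns)
        ]
        out[metric] = (fits, design, wide)
    return out
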