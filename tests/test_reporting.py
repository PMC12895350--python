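"""Tissue gradient, covariate tallies, and end-to-end pipeline behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest

import qmriage as q


def _peaks_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["region_id", "tissue", "metric", "peak_age", "gated", "in_range"],
    )


class TestTissueGradient:
    def test_degenerate_equal_peaks(self):
        rows = [(f"BA{i}", "cGM", "R1", 56.4, False, True) for i in range(5)]
        rows += [(f"BA{i}", "sWM", "R1", 43.0, False, True) for i in range(3)]
        rows += [("FA", "WM_bundle", "R1", 39.0, False, True)]
        summary, verdict = q.tissue_gradient(_peaks_frame(rows))
        cgm = summary[summary["tissue"] == "cGM"].iloc[0]
        assert cgm["mean_peak"] == pytest.approx(56.4)
        assert cgm["sd_peak"] == 0.0
        assert verdict["ordered"] is True

    def test_gated_and_out_of_range_peaks_excluded(self):
        rows = [
            ("BA1", "cGM", "R1", 56.0, False, True),
            ("BA2", "cGM", "R1", 200.0, False, False),  # out of range
            ("BA3", "cGM", "R1", None, True, None),  # gated
            ("FA", "WM_bundle", "R1", 39.0, False, True),
            ("BA1", "sWM", "R1", 43.0, False, True),
        ]
        summary, _ = q.tissue_gradient(_peaks_frame(rows))
        assert summary[summary["tissue"] == "cGM"].iloc[0]["n_regions_ungated"] == 1

    def test_missing_tissue_marks_incomplete(self):
        rows = [("BA1", "cGM", "R1", 56.0, False, True)]
        summary, verdict = q.tissue_gradient(_peaks_frame(rows))
        assert verdict["incomplete"] is True
        assert not verdict["ordered"]
        assert summary[summary["tissue"] == "sWM"].iloc[0]["n_regions_ungated"] == 0

    def test_shuffled_labels_break_ordering(self, cohort293, design293):
        """Permuting tissue labels across regions destroys the gradient."""
        rng = np.random.default_rng(17)
        peaks = {"WM_bundle": 39.16, "sWM": 43.28, "cGM": 56.40}
        rows = []
        for tissue, mean in peaks.items():
            for i in range(10):
                rows.append((f"{tissue}{i}", tissue, "R1", rng.normal(mean, 2.0), False, True))
        frame = _peaks_frame(rows)
        _, verdict = q.tissue_gradient(frame)
        assert verdict["ordered"] is True
        shuffled = frame.copy()
        shuffled["tissue"] = rng.permutation(shuffled["tissue"].to_numpy())
        _, verdict_shuffled = q.tissue_gradient(shuffled)
        assert verdict_shuffled["ordered"] is False


class TestCovariateSummary:
    def _fits(self, cohort, design, sex_effect, n_regions=12, seed=0):
        specs = []
        for i in range(n_regions):
            specs.append(
                q.TrajectorySpec(
                    region_id=f"BA{i + 1:02d}", tissue="cGM", metric="R1",
                    beta0=1.0, beta1=0.02, beta2=-0.00025, sigma=0.01,
                    beta_sex=sex_effect,
                )
            )
        df = q.generate_region_metrics(cohort, q.TrajectoryLibrary(specs), seed=seed)
        wide = df.pivot_table(index="subject_id", columns=["tissue", "region_id"], values="value")
        return [
            q.fit_trajectory(design, wide[(t, r)], region_id=r, tissue=t, metric="R1")
            for t, r in wide.columns
        ]

    def test_saturated_sex_effect_counts_all_regions(self, cohort293, design293):
        fits = self._fits(cohort293, design293, sex_effect=0.05)
        summary = q.covariate_summary(fits)
        row = summary.query("covariate == 'sex'").iloc[0]
        assert row["n_significant_raw"] == row["n_regions"] == 12

    def test_null_sex_effect_rare(self, cohort293, design293):
        fits = self._fits(cohort293, design293, sex_effect=0.0, seed=1)
        summary = q.covariate_summary(fits)
        row = summary.query("covariate == 'sex'").iloc[0]
        assert row["n_significant_raw"] <= 4  # ~alpha * 12 expected

    def test_education_counts_region_once_for_either_dummy(self, cohort293, design293):
        specs = [
            q.TrajectorySpec(
                region_id="BA01", tissue="cGM", metric="R1",
                beta0=1.0, beta1=0.02, beta2=-0.00025, sigma=0.01,
                beta_edu_low=0.08, beta_edu_high=0.0,
            )
        ]
        df = q.generate_region_metrics(cohort293, q.TrajectoryLibrary(specs), seed=2)
        wide = df.pivot_table(index="subject_id", columns=["tissue", "region_id"], values="value")
        fits = [
            q.fit_trajectory(design293, wide[(t, r)], region_id=r, tissue=t, metric="R1")
            for t, r in wide.columns
        ]
        row = q.covariate_summary(fits).query("covariate == 'education'").iloc[0]
        assert row["n_significant_raw"] == 1
        assert row["n_regions"] == 1


class TestPipeline:
    CFG = dict(
        simulate=dict(n_subjects=120, metrics=["R1"], n_cgm=3, n_swm=3, n_bundles=2),
        alpha=0.05,
        bootstrap=150,
        cv_folds=5,
        seed=9,
    )

    def test_end_to_end_determinism(self, tmp_path):
        """Two runs from the same config produce byte-identical tables."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q.run_pipeline(dict(self.CFG), tmp_path / "a")
            q.run_pipeline(dict(self.CFG), tmp_path / "b")
        for f in sorted((tmp_path / "a").glob("*.csv")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_outputs_complete_and_traceable(self, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = q.run_pipeline(dict(self.CFG), tmp_path / "run")
        out = tmp_path / "run"
        for name in (
            "cohort.csv", "region_metrics.csv", "fits_R1.csv", "peaks_R1.csv",
            "expv_R1.csv", "gradient_R1.csv", "covariates_R1.csv",
            "covariation_R1_raw.csv", "manifest.json", "summary.txt",
        ):
            assert (out / name).exists(), name
        # summary numbers come from the gradient table
        grad = pd.read_csv(out / "gradient_R1.csv")
        summary_text = (out / "summary.txt").read_text()
        for _, row in grad.iterrows():
            if row["n_regions_ungated"]:
                assert f"{row['mean_peak']:.2f}" in summary_text
        assert "truth" in res

    def test_metric_subset_respected(self, tmp_path):
        cfg = dict(self.CFG)
        cfg["simulate"] = dict(cfg["simulate"], metrics=["R1"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q.run_pipeline(cfg, tmp_path / "r1only")
        assert not list((tmp_path / "r1only").glob("*QSM*"))

    def test_loading_external_tables(self, tmp_path):
        """The pipeline also runs from externally supplied delimited tables."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q.run_pipeline(dict(self.CFG), tmp_path / "sim")
        cfg = dict(
            inputs=dict(
                cohort=str(tmp_path / "sim" / "cohort.csv"),
                metrics=str(tmp_path / "sim" / "region_metrics.csv"),
            ),
            alpha=0.05,
            bootstrap=0,
            cv_folds=5,
            seed=9,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = q.run_pipeline(cfg, tmp_path / "ext")
        assert (tmp_path / "ext" / "fits_R1.csv").exists()
        assert res["manifest"]["input_checksums"]


class TestPlotting:
    def test_trajectory_and_heatmap_render(self, cohort293, design293, strong_region, tmp_path):
        import matplotlib.pyplot as plt
        import numpy as np

        from qmriage.plotting import plot_correlation_heatmap, plot_region_trajectory

        spec, y = strong_region
        fit = q.fit_trajectory(design293, y, region_id=spec.region_id, tissue="cGM", metric="R1")
        ax = plot_region_trajectory(fit, cohort293, y, boot_peaks=np.array([55.0, 56.0, 57.0]))
        ax.figure.savefig(tmp_path / "traj.png", dpi=50)
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        res = q.correlation_matrix(vals, {c: "cGM" for c in vals.columns})
        ax2 = plot_correlation_heatmap(res)
        ax2.figure.savefig(tmp_path / "heat.png", dpi=50)
        plt.close("all")
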