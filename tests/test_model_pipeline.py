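"""Model/Results surface, end-to-end pipeline runs and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from perfterr.cli import main as cli_main
from perfterr.errors import ValidationError
from perfterr.model import ArterialContributionModel
from perfterr.phantom import CohortConfig, PhantomConfig
from perfterr.pipeline import RunConfig, cohort_config_from_yaml, run_pipeline

SMALL_GRID = (24, 16, 32)


@pytest.fixture(scope="module")
def fitted_results():
    cc = CohortConfig(phantom=PhantomConfig(grid_shape=SMALL_GRID))
    model = ArterialContributionModel.from_simulation(cc, seed=31)
    return model.fit()


class TestModel:
    def test_report_table_shape_and_pvalues(self, fitted_results):
        table = fitted_results.table
        assert len(table) == 15
        assert table["p_value"].between(0, 1).all()

    def test_summary_text_contains_all_cells(self, fitted_results):
        text = fitted_results.summary()
        for cell in ("Full trochanteric region", "GT anterior", "Subtrochanteric (ST)"):
            assert cell in text

    def test_table_pvalues_match_stats_recomputation(self, fitted_results):
        from perfterr.stats import compare_regions

        recomputed = compare_regions(fitted_results.estimates)
        for (region, sub), r in recomputed.items():
            sub_key = "" if sub is None else sub
            row = fitted_results.table[
                (fitted_results.table["region"] == region)
                & (fitted_results.table["subregion"] == sub_key)
            ]
            assert float(row["p_value"].iloc[0]) == r.p_value

    def test_recovery_without_truth_rejected(self, small_cohort_config):
        from perfterr.phantom import generate_cohort

        dataset, _ = generate_cohort(small_cohort_config, 5)
        model = ArterialContributionModel(dataset.specimens)
        res = model.fit(tests=False)
        with pytest.raises(ValidationError, match="truth"):
            res.recovery()

    def test_monotone_in_configured_fraction_noise_free(self):
        """Raising the true MFCA fraction never lowers the estimate."""
        from perfterr.phantom import (
            ExperimentAssignment,
            TerritoryTruth,
            build_specimen_phantom,
        )

        ph = PhantomConfig(grid_shape=SMALL_GRID, noise_sd=0.0)
        prev = -1.0
        for frac in np.linspace(0.0, 1.0, 9):
            spec = build_specimen_phantom(
                ph, TerritoryTruth.uniform(frac), ExperimentAssignment("left", "MFCA"),
                seed=1, specimen_id="S1",
            )
            from perfterr.contribution import specimen_contribution
            from perfterr.enhancement import specimen_enhancements

            cells = specimen_enhancements(spec)
            est = specimen_contribution(
                cells["experimental"][("FULL", None)],
                cells["control"][("FULL", None)],
                "MFCA",
            )
            assert est.mfca_pct >= prev
            prev = est.mfca_pct

    def test_plot_returns_axes(self, fitted_results):
        import matplotlib

        matplotlib.use("Agg")
        ax = fitted_results.plot_contributions()
        assert len(ax.patches) == 15
        ax.figure.clf()


class TestPipeline:
    def _config(self, out, seed=9, **kw):
        cc = CohortConfig(phantom=PhantomConfig(grid_shape=SMALL_GRID))
        return RunConfig(mode="simulate", out_dir=str(out), seed=seed, cohort=cc, **kw)

    def test_simulate_writes_report_bundle(self, tmp_path):
        run_pipeline(self._config(tmp_path / "run", write_volumes=False))
        out = tmp_path / "run"
        for name in (
            "enhancements.csv", "contributions.csv", "summary.csv",
            "summary.txt", "run.json", "truth_table.csv", "recovery.csv",
        ):
            assert (out / name).exists(), name
        assert len(pd.read_csv(out / "summary.csv")) == 15

    def test_same_seed_identical_summaries(self, tmp_path):
        run_pipeline(self._config(tmp_path / "a", write_volumes=False))
        run_pipeline(self._config(tmp_path / "b", write_volumes=False))
        assert (tmp_path / "a/summary.csv").read_bytes() == (
            tmp_path / "b/summary.csv"
        ).read_bytes()

    def test_analyze_mode_matches_simulate_at_stored_precision(self, tmp_path):
        """Re-analyzing the written phantom volumes reproduces the simulate-mode
        numbers to the float32 storage precision."""
        res_sim = run_pipeline(self._config(tmp_path / "sim", write_volumes=True))
        manifests = sorted((tmp_path / "sim" / "data").glob("S*_manifest.json"))
        assert len(manifests) == 10
        cfg = RunConfig(
            mode="analyze", out_dir=str(tmp_path / "re"), manifests=[str(p) for p in manifests]
        )
        res_re = run_pipeline(cfg)
        sim = res_sim.estimates_frame.sort_values(["specimen_id", "region", "subregion"])
        re_ = res_re.estimates_frame.sort_values(["specimen_id", "region", "subregion"])
        np.testing.assert_allclose(
            re_["mfca_pct"].to_numpy(), sim["mfca_pct"].to_numpy(), atol=1e-3
        )

    def test_noise_free_recovery_is_exact(self, tmp_path):
        cc = CohortConfig(
            n_specimens=4,
            within_region_jitter_sd=0.0,
            phantom=PhantomConfig(grid_shape=SMALL_GRID, noise_sd=0.0),
        )
        cfg = RunConfig(
            mode="simulate", out_dir=str(tmp_path / "nf"), seed=2, cohort=cc,
            write_volumes=False,
        )
        res = run_pipeline(cfg)
        assert res.recovery().mae < 1e-6

    def test_truth_table_id_mismatch_rejected(self, fitted_results):
        from perfterr.pipeline import truth_comparison

        bad = fitted_results.model.truth_table.copy()
        bad["specimen_id"] = bad["specimen_id"].str.replace("S0", "X0")
        with pytest.raises(ValidationError, match="specimen ids"):
            truth_comparison(fitted_results, bad)

    def test_yaml_round_trip(self, tmp_path):
        yaml_text = """
n_specimens: 4
allocation: bernoulli
within_region_jitter_sd: 0.02
phantom:
  grid_shape: [24, 16, 32]
  noise_sd: 3.0
"""
        path = tmp_path / "cohort.yaml"
        path.write_text(yaml_text)
        cc = cohort_config_from_yaml(path)
        assert cc.n_specimens == 4
        assert cc.phantom.noise_sd == 3.0

    def test_yaml_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("n_specimens: 4\nnoise: 2\n")
        with pytest.raises(ValidationError, match="unknown"):
            cohort_config_from_yaml(path)


class TestCli:
    def test_simulate_subcommand(self, tmp_path):
        config = tmp_path / "cohort.yaml"
        config.write_text(
            "n_specimens: 4\nphantom:\n  grid_shape: [24, 16, 32]\n"
        )
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "simulate", "--config", str(config), "--seed", "3",
                "--out", str(tmp_path / "out"), "--no-volumes",
            ],
        )
        assert result.exit_code == 0, result.output
        assert "Full trochanteric region" in result.output
        assert (tmp_path / "out" / "summary.csv").exists()

    def test_report_subcommand_roundtrip(self, tmp_path, fitted_results):
        contrib = tmp_path / "contributions.csv"
        fitted_results.estimates_frame.to_csv(contrib, index=False)
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["report", str(contrib), "--out", str(tmp_path / "rep")]
        )
        assert result.exit_code == 0, result.output
        table = pd.read_csv(tmp_path / "rep" / "summary.csv")
        assert len(table) == 15
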