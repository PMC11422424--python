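"""Model/results facade, file I/O round trips, pipeline runner and CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from ematraj import EmaTrajectoryModel, PipelineConfig
from ematraj.cli import main as cli_main
from ematraj.config import derive_seed
from ematraj.io import read_ema_csv, write_ema_csv
from ematraj.pipeline import run_pipeline
from ematraj.simulate import CohortSpec, TrajectoryModelParams


@pytest.fixture(scope="module")
def fitted(small_cohort):
    records, cohort, schedules = small_cohort
    cfg = PipelineConfig(
        seed=11, windows=(2,), n_resamples=40, n_trees=20,
        k_range=tuple(range(2, 6)),
    )
    model = EmaTrajectoryModel(records, schedules=schedules, config=cfg)
    return model.fit(), cohort


class TestModelFit:
    def test_selects_two_clusters_on_separated_cohort(self, fitted):
        results, _ = fitted
        assert results.selected_k == 2

    def test_recovers_latent_class(self, fitted):
        results, cohort = fitted
        truth = cohort.set_index("participant_id")["latent_class"]
        assert results.adjusted_rand(truth) >= 0.9

    def test_summary_mentions_clusters_and_stability(self, fitted):
        results, _ = fitted
        text = results.summary()
        assert "cluster sizes" in text
        assert "hierarchical" in text and "kmeans" in text

    def test_labels_cover_all_retained_participants(self, fitted):
        results, _ = fitted
        labels = results.labels_
        assert labels.notna().all()
        assert set(labels) == set(range(1, results.primary_solution.k + 1))
        assert len(labels) == results.composite.shape[0]

    def test_composite_within_likert_range(self, fitted):
        results, _ = fitted
        vals = results.composite.to_numpy()
        assert ((vals >= 1.0) & (vals <= 7.0)).all()

    def test_characterization_detects_planted_gap(self, fitted):
        results, _ = fitted
        table = results.characterize()
        row = table[table["variable"] == "mean_rating"].iloc[0]
        assert row["p_fdr"] < 0.05

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            EmaTrajectoryModel(pd.DataFrame({"participant_id": []}))


class TestSeedDerivation:
    def test_stage_seeds_stable_and_distinct(self):
        seeds = {s: derive_seed(123, s) for s in
                 ("simulate", "impute", "cluster", "stability")}
        assert seeds == {s: derive_seed(123, s) for s in seeds}
        assert len(set(seeds.values())) == len(seeds)
        assert all(0 <= v < 2**31 for v in seeds.values())

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            derive_seed(1, "teleport")


class TestEmaCsv:
    def test_round_trip_identity(self, small_cohort, tmp_path):
        records, _, _ = small_cohort
        path = tmp_path / "records.csv"
        write_ema_csv(records, str(path))
        back = read_ema_csv(str(path))
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), records.reset_index(drop=True),
            check_dtype=False,
        )

    def test_rating_out_of_range_cites_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "participant_id,study,group,day,time,item,rating\n"
            "P1,studyA,HC,1,09:00,voices,3\n"
            "P1,studyA,HC,1,10:00,voices,8\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_ema_csv(str(path))

    def test_empty_rating_parsed_as_missing(self, tmp_path):
        path = tmp_path / "missing.csv"
        path.write_text(
            "participant_id,study,group,day,time,item,rating\n"
            "P1,studyA,HC,1,09:00,voices,\n"
        )
        df = read_ema_csv(str(path))
        assert df["rating"].isna().all()

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "head.csv"
        path.write_text("pid,day\n1,2\n")
        with pytest.raises(ValueError, match="malformed header"):
            read_ema_csv(str(path))


class TestRunPipeline:
    @pytest.fixture(scope="class")
    def artifacts(self, tmp_path_factory):
        cfg = PipelineConfig(
            seed=21, windows=(2,), n_resamples=30, n_trees=15,
            k_range=tuple(range(2, 5)),
        )
        out = tmp_path_factory.mktemp("run")
        spec = CohortSpec(n_hc=8, n_re=4, n_pd=12, seed=0)
        run_pipeline(cfg, str(out), cohort_spec=spec,
                     trajectory_params=TrajectoryModelParams(missing_rate=0.25))
        return out, cfg

    def test_expected_artifacts_present(self, artifacts):
        out, _ = artifacts
        for name in (
            "records.csv", "cohort.csv", "composite_trajectories.csv",
            "distances_w2.csv", "ward_tree_w2.csv", "stability_w2.csv",
            "cluster_assignments.csv", "primary_labels.csv",
            "imputation_report.csv", "cluster_characterization.csv",
            "manifest.json", "summary.txt",
        ):
            assert (out / name).exists(), name

    def test_manifest_records_config_and_seeds(self, artifacts):
        out, cfg = artifacts
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["config_hash"] == cfg.config_hash()
        assert manifest["stage_seeds"]["impute"] == cfg.seed_for("impute")

    def test_rerun_identical_manifest(self, artifacts, tmp_path):
        out, cfg = artifacts
        out2 = tmp_path / "rerun"
        spec = CohortSpec(n_hc=8, n_re=4, n_pd=12, seed=0)
        run_pipeline(cfg, str(out2), cohort_spec=spec,
                     trajectory_params=TrajectoryModelParams(missing_rate=0.25))
        m1 = json.loads((out / "manifest.json").read_text())
        m2 = json.loads((out2 / "manifest.json").read_text())
        assert m1 == m2
        assert (out / "primary_labels.csv").read_text() == (
            out2 / "primary_labels.csv"
        ).read_text()

    def test_empty_input_fails_with_stage_error(self, tmp_path):
        bad = tmp_path / "empty.csv"
        bad.write_text("participant_id,study,group,day,time,item,rating\n")
        cfg = PipelineConfig(input_csv=str(bad))
        with pytest.raises(RuntimeError, match="stage"):
            run_pipeline(cfg, str(tmp_path / "out"))


class TestCli:
    def test_simulate_verb_writes_csv(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["simulate", "--out", str(tmp_path), "--n-hc", "3", "--n-re", "2",
             "--n-pd", "3", "--seed", "1"],
        )
        assert res.exit_code == 0, res.output
        assert (tmp_path / "records.csv").exists()
        df = read_ema_csv(str(tmp_path / "records.csv"))
        assert df["participant_id"].nunique() == 8

    def test_distances_verb(self, tmp_path):
        comp = pd.DataFrame(
            np.random.default_rng(0).uniform(1, 7, size=(5, 42)),
            index=[f"P{i}" for i in range(5)],
        )
        comp_path = tmp_path / "comp.csv"
        comp.to_csv(comp_path)
        out = tmp_path / "dist.csv"
        res = CliRunner().invoke(
            cli_main,
            ["distances", "--input", str(comp_path), "--out", str(out),
             "--window", "2"],
        )
        assert res.exit_code == 0, res.output
        D = pd.read_csv(out, index_col=0)
        assert D.shape == (5, 5)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(seed=5, windows=(2, 8), n_resamples=77)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(str(path))
        back = PipelineConfig.from_yaml(str(path))
        assert back == cfg
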