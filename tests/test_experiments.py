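"""Experiment harness: report shapes, determinism, CLI round-trip."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import glottiswt as g
from glottiswt.cli import main as cli_main
from glottiswt.errors import ConfigError
from glottiswt.experiments import CohortConfig, ExperimentConfig, report_to_frame, run_experiment

FAST = dict(n_per_class=5, duration_s=1.0)


def _fast_config(**kw):
    defaults = dict(
        mode="detection",
        cohorts=[CohortConfig(**FAST)],
        cv_k=5,
        seed=3,
        iaif_method="lpc",
    )
    defaults.update(kw)
    return ExperimentConfig(**defaults)


class TestConfig:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(mode="bogus")

    def test_cross_dataset_needs_two_cohorts(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(mode="cross_dataset", cohorts=[CohortConfig()])

    def test_top_k_bounded_by_dimension(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(feature_subset="top_k:99")

    def test_yaml_roundtrip(self, tmp_path):
        cfg_path = tmp_path / "exp.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "mode": "detection",
                    "cohorts": [dict(kind="binary", n_per_class=5, duration_s=1.0)],
                    "cv_k": 5,
                    "seed": 9,
                }
            )
        )
        cfg = ExperimentConfig.from_yaml(cfg_path)
        assert cfg.mode == "detection"
        assert cfg.cohorts[0].n_per_class == 5
        assert cfg.seed == 9


@pytest.fixture(scope="module")
def detection_report():
    return run_experiment(_fast_config())


class TestRunExperiment:

    def test_detection_report_shape(self, detection_report):
        # 2 classifiers x 2 feature conditions, 5 metrics each
        results = detection_report["results"]
        assert set(results) == {
            "sgd|all",
            "sgd|top_k:3",
            "svm_rbf|all",
            "svm_rbf|top_k:3",
        }
        for block in results.values():
            assert {"auc", "ca_pct", "f1", "ppv_pct", "recall_pct"} <= set(block)

    def test_ranking_attached(self, detection_report):
        assert len(detection_report["ranking"]) == 56
        assert detection_report["ranking"][0]["rank"] == 1

    def test_provenance_recorded(self, detection_report):
        prov = detection_report["provenance"]
        assert prov["wavelet"] == "haar"
        assert prov["levels"] == 4
        assert prov["iaif_method"] == "lpc"

    def test_determinism_bit_identical_reports(self):
        a = json.dumps(run_experiment(_fast_config()), sort_keys=True)
        b = json.dumps(run_experiment(_fast_config()), sort_keys=True)
        assert a == b

    def test_common3_uses_exactly_three_features(self):
        report = run_experiment(_fast_config(feature_subset="common3"))
        assert set(report["results"]) == {"sgd|common3", "svm_rbf|common3"}

    def test_report_frame_flattening(self, detection_report):
        frame = report_to_frame(detection_report)
        assert len(frame) == 4
        assert {"condition", "auc", "ca_pct"} <= set(frame.columns)

    def test_cross_dataset_matrix_shape(self):
        cfg = _fast_config(
            mode="cross_dataset",
            cohorts=[
                CohortConfig(formant_scale_range=(0.9, 1.0), **FAST),
                CohortConfig(formant_scale_range=(1.0, 1.1), **FAST),
            ],
            classifiers=["sgd"],
        )
        report = run_experiment(cfg)
        assert set(report["results"]["sgd"]) == {"train0->test1", "train1->test0"}


class TestSweeps:
    TINY = dict(n_per_class=3, duration_s=1.0)

    def test_level_sweep_rows(self):
        cfg = _fast_config(mode="sweep_levels", classifiers=["sgd"],
                           cohorts=[CohortConfig(**self.TINY)], cv_k=3)
        report = run_experiment(cfg)
        assert set(report["results"]) == {f"sgd|J={j}" for j in range(1, 6)}

    def test_wavelet_sweep_covers_family(self):
        cfg = _fast_config(mode="sweep_wavelets", classifiers=["sgd"],
                           cohorts=[CohortConfig(**self.TINY)], cv_k=3)
        report = run_experiment(cfg)
        expected = {"sgd|haar"} | {f"sgd|db{k}" for k in range(2, 13)}
        assert set(report["results"]) == expected


class TestCli:
    def test_synth_features_rank_run_pipeline(self, tmp_path):
        runner = CliRunner()
        cohort_yaml = tmp_path / "cohort.yaml"
        cohort_yaml.write_text(
            yaml.safe_dump(
                {
                    "fs_hz": 22050,
                    "classes": [
                        {"name": "healthy", "count": 3, "duration_s": 1.0},
                        {"name": "polyp-like", "count": 3, "duration_s": 1.0},
                    ],
                }
            )
        )
        out_dir = tmp_path / "cohort"
        r = runner.invoke(cli_main, ["synth", "--spec", str(cohort_yaml), "--out", str(out_dir), "--seed", "5"])
        assert r.exit_code == 0, r.output
        assert (out_dir / "manifest.csv").exists()
        assert len(list(out_dir.glob("*.wav"))) == 6

        feats_csv = tmp_path / "feats.csv"
        r = runner.invoke(
            cli_main,
            ["features", "--in", str(out_dir), "--out", str(feats_csv), "--iaif-method", "lpc"],
        )
        assert r.exit_code == 0, r.output

        r = runner.invoke(cli_main, ["rank", "--feats", str(feats_csv)])
        assert r.exit_code == 0, r.output
        assert "parameter" in r.output

    def test_run_command_writes_report(self, tmp_path):
        runner = CliRunner()
        exp_yaml = tmp_path / "exp.yaml"
        exp_yaml.write_text(
            yaml.safe_dump(
                {
                    "mode": "detection",
                    "cohorts": [dict(kind="binary", n_per_class=5, duration_s=1.0)],
                    "cv_k": 5,
                    "seed": 1,
                    "iaif_method": "lpc",
                    "classifiers": ["sgd"],
                }
            )
        )
        out_json = tmp_path / "report.json"
        r = runner.invoke(cli_main, ["run", "--config", str(exp_yaml), "--out", str(out_json)])
        assert r.exit_code == 0, r.output
        report = json.loads(out_json.read_text())
        assert report["mode"] == "detection"
        assert out_json.with_suffix(".csv").exists()

    def test_config_error_exits_2(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump({"mode": "bogus"}))
        r = runner.invoke(cli_main, ["run", "--config", str(bad), "--out", str(tmp_path / "x.json")])
        assert r.exit_code == 2
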