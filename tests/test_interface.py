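"""Configuration loading, file round-trips and the command line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from edslung import ann, config, io, pipeline, synthdata
from edslung.cli import cli
from edslung.errors import ConfigurationError, DataValidationError


class TestConfig:
    def test_defaults_validate_cleanly(self):
        cfg = config.load_config(None)
        assert cfg.preclassification.threshold == 50.0
        assert cfg.ann.k == 10
        cfg.fuzzy.to_rule_base()  # default rule base is internally consistent

    def test_empty_file_yields_defaults(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        assert config.load_config(p) == config.EdsConfig()

    def test_out_of_range_threshold_names_location(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("preclassification:\n  threshold: 150\n")
        with pytest.raises(ConfigurationError, match="threshold"):
            config.load_config(p)

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("unknown_section:\n  a: 1\n")
        with pytest.raises(ConfigurationError, match="unknown_section"):
            config.load_config(p)

    def test_invalid_fuzzy_rule_reference_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text(
            "fuzzy:\n  rules:\n    - when: {reversibility: enormous}\n      then: asthma\n"
        )
        with pytest.raises(ConfigurationError, match="enormous"):
            config.load_config(p)

    def test_overridden_factor_table_propagates(self, tmp_path):
        p = tmp_path / "ok.yaml"
        p.write_text(
            "preclassification:\n"
            "  factors:\n"
            "    asthma: [1, 1, 1, 1, 1, 1, 1]\n"
            "    copd: [1, 2, 3, 4, 5, 6, 7]\n"
            "  asthma_inverted_questions: []\n"
        )
        table = config.load_config(p).preclassification.to_table()
        assert table.copd == (1, 2, 3, 4, 5, 6, 7)
        assert table.asthma_inverted_questions == frozenset()


class TestCohortIO:
    def test_round_trip_preserves_records(self, tmp_path, tiny_cohort):
        p = tmp_path / "cohort.csv"
        io.write_cohort(tiny_cohort, p)
        back = io.read_cohort(p)
        assert len(back) == len(tiny_cohort)
        for a, b in zip(tiny_cohort, back):
            assert a.id == b.id
            assert a.answers == b.answers
            assert a.true_label == b.true_label
            assert a.spirometry.vc == pytest.approx(b.spirometry.vc)
            assert a.bronchial_test.fev1_change_percent == pytest.approx(
                b.bronchial_test.fev1_change_percent
            )

    def test_bad_answer_value_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,q1,q2,q3,q4,q5,q6,q7\na,0,0,0,0,0,0,0\nb,0,3,0,0,0,0,0\n")
        with pytest.raises(DataValidationError, match="row 3"):
            io.read_cohort(p)

    def test_missing_required_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,q1,q2\na,0,0\n")
        with pytest.raises(DataValidationError, match="q3"):
            io.read_cohort(p)

    def test_empty_file_with_header_is_empty_cohort(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("id,q1,q2,q3,q4,q5,q6,q7\n")
        assert io.read_cohort(p) == []

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("id,q1,q2,q3,q4,q5,q6,q7\na,0,0,0,0,0,0,0\na,0,0,0,0,0,0,0\n")
        with pytest.raises(DataValidationError, match="duplicate"):
            io.read_cohort(p)


class TestModelIO:
    def _model(self, tiny_cohort):
        return pipeline.train_model(
            tiny_cohort, hidden_size=4, k=3, seed=2,
            settings=ann.LmaSettings(max_iter=30), restarts=1,
        )

    def test_round_trip_is_bit_exact(self, tmp_path, tiny_cohort):
        model = self._model(tiny_cohort)
        p = tmp_path / "model.json"
        io.save_model(model, p)
        back = io.load_model(p)
        assert np.array_equal(back.weights.flatten(), model.weights.flatten())
        assert back.bounds == model.bounds
        x = np.full(5, 0.3)
        assert ann.forward(back.weights, x).outputs == pytest.approx(
            ann.forward(model.weights, x).outputs
        )

    def test_truncated_file_is_load_error(self, tmp_path, tiny_cohort):
        model = self._model(tiny_cohort)
        p = tmp_path / "model.json"
        io.save_model(model, p)
        p.write_text(p.read_text()[:40])
        with pytest.raises(DataValidationError):
            io.load_model(p)

    def test_model_without_bounds_refused(self, tmp_path, tiny_cohort):
        model = self._model(tiny_cohort)
        p = tmp_path / "model.json"
        io.save_model(model, p)
        doc = json.loads(p.read_text())
        doc["bounds"] = {}
        p.write_text(json.dumps(doc))
        with pytest.raises(DataValidationError, match="bounds"):
            io.load_model(p)

    def test_schema_version_mismatch_refused(self, tmp_path, tiny_cohort):
        model = self._model(tiny_cohort)
        p = tmp_path / "model.json"
        io.save_model(model, p)
        doc = json.loads(p.read_text())
        doc["schema_version"] = "99"
        p.write_text(json.dumps(doc))
        with pytest.raises(DataValidationError, match="version"):
            io.load_model(p)


class TestCliEndToEnd:
    def test_simulate_train_classify_evaluate(self, tmp_path):
        runner = CliRunner()
        cohort = tmp_path / "cohort.csv"
        model = tmp_path / "model.json"
        decisions = tmp_path / "decisions.csv"
        report = tmp_path / "report.json"
        cfg = tmp_path / "eds.yaml"
        cfg.write_text("ann:\n  restarts: 1\n  lma:\n    max_iter: 40\n")

        r = runner.invoke(cli, ["simulate", "--profile", "realistic", "--n", "60",
                                "--seed", "11", "--out", str(cohort)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli, ["train", "--data", str(cohort), "--config", str(cfg),
                                "--hidden-size", "6", "--out", str(model)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli, ["triage", "--data", str(cohort)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli, ["classify", "--data", str(cohort), "--model", str(model),
                                "--out", str(decisions)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli, ["evaluate", "--decisions", str(decisions),
                                "--truth", str(cohort), "--out", str(report)])
        assert r.exit_code == 0, r.output
        doc = json.loads(report.read_text())
        assert set(doc["confusion"]) == {"tp", "fn", "fp", "tn"}
        assert sum(doc["confusion"].values()) == 60
        assert doc["metrics"]["accuracy"] is not None

    def test_usage_error_exit_code_1(self):
        import subprocess, sys
        r = subprocess.run(
            [sys.executable, "-m", "edslung.cli", "simulate", "--profile", "bogus",
             "--out", "x.csv"],
            capture_output=True, text=True,
        )
        assert r.returncode == 1

    def test_data_validation_exit_code_2(self, tmp_path):
        import subprocess, sys
        bad = tmp_path / "bad.csv"
        bad.write_text("id,q1,q2,q3,q4,q5,q6,q7\na,0,9,0,0,0,0,0\n")
        r = subprocess.run(
            [sys.executable, "-m", "edslung.cli", "triage", "--data", str(bad)],
            capture_output=True, text=True,
        )
        assert r.returncode == 2
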