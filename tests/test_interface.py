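"""File formats, configuration, the end-to-end pipeline, and the CLI."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from bvpredict import (
    CoupleRecord,
    RunConfig,
    ValidationError,
    analyze,
    generate_cohort,
    read_count_table,
    read_metadata,
    run_pipeline,
    write_count_table,
    write_metadata,
)
from bvpredict.cli import cli
from bvpredict.io import read_auc_vector, write_auc_vector
from tests.conftest import make_count_table


class TestCountTableIO:
    def test_round_trip(self, tmp_path, small_table):
        path = tmp_path / "counts.tsv"
        write_count_table(small_table, path)
        back = read_count_table(path, site="meatal")
        pd.testing.assert_frame_equal(back.counts, small_table.counts, check_names=False)

    def test_comma_separated_also_accepted(self, tmp_path, small_table):
        path = tmp_path / "counts.csv"
        write_count_table(small_table, path, sep=",")
        back = read_count_table(path)
        pd.testing.assert_frame_equal(back.counts, small_table.counts, check_names=False)

    def test_non_integer_cell_error_names_the_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\ttaxA\ttaxB\nS1\t3\t12.5\n")
        with pytest.raises(ValidationError, match=r"12\.5.*'S1'.*'taxB'"):
            read_count_table(path)

    def test_header_only_file_reports_no_samples(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("sample_id\ttaxA\ttaxB\n")
        with pytest.raises(ValidationError, match="no samples"):
            read_count_table(path)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("sample_id\ttaxA\nS1\t3\nS1\t4\n")
        with pytest.raises(ValidationError, match="duplicate sample ids"):
            read_count_table(path)


class TestMetadataIO:
    def test_round_trip_preserves_missing_visits(self, tmp_path):
        records = [
            CoupleRecord("C01", True, {0: 3, 1: 2, 6: 7}),
            CoupleRecord("C02", False, {0: 0}),
        ]
        path = tmp_path / "meta.tsv"
        write_metadata(records, path)
        back = read_metadata(path)
        assert [r.nugent_by_visit for r in back] == [r.nugent_by_visit for r in records]
        assert [r.circumcised for r in back] == [True, False]

    def test_blank_followup_means_visit_absent(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text(
            "couple_id\tcircumcised\tnugent_m0\tnugent_m1\tnugent_m6\tnugent_m12\n"
            "C01\t1\t3\t\t5\t\n"
        )
        (record,) = read_metadata(path)
        assert record.nugent_by_visit == {0: 3, 6: 5}

    def test_score_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("couple_id\tcircumcised\tnugent_m0\nC01\t1\t11\n")
        with pytest.raises(ValidationError):
            read_metadata(path)

    def test_missing_baseline_column_rejected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("couple_id\tcircumcised\nC01\t1\n")
        with pytest.raises(ValidationError, match="nugent_m0"):
            read_metadata(path)


def test_auc_vector_round_trip(tmp_path):
    path = tmp_path / "auc.txt"
    values = np.array([0.81, 0.905, 0.77])
    write_auc_vector(values, path, hash_value="abc123")
    assert "# config: abc123" in path.read_text()
    np.testing.assert_allclose(read_auc_vector(path), values)


class TestRunConfig:
    def test_defaults_and_seed_propagation(self):
        config = RunConfig.from_dict({"seed": 10})
        assert config.preprocess.seed == 11
        assert config.resample.seed == 12
        assert config.cv.base_seed == 13

    def test_explicit_stage_seed_wins(self):
        config = RunConfig.from_dict({"seed": 10, "resample": {"seed": 99}})
        assert config.resample.seed == 99

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValidationError, match="unknown config keys"):
            RunConfig.from_dict({"n_bootstrap": 5})

    def test_paper_scale_raises_repeats(self):
        config = RunConfig.from_dict({"paper_scale": True})
        assert config.cv.n_repeats == 1000


TINY_RUN = {
    "seed": 6,
    "simulate": {"n_couples": 40, "n_taxa": 10, "effect_taxa": {1: 2.0, 3: 2.0}},
    "preprocess": {"min_fraction": 0.0},
    "resample": {"k_neighbors": 3},
    "cv": {"n_folds": 4, "n_repeats": 2},
    "compute_importance": False,
}


@pytest.fixture()
def tiny_inputs(tmp_path):
    config = RunConfig.from_dict(dict(TINY_RUN, out_dir=str(tmp_path / "out")))
    table, records = generate_cohort(config.simulate)
    counts = tmp_path / "counts.tsv"
    meta = tmp_path / "metadata.tsv"
    write_count_table(table, counts)
    write_metadata(records, meta)
    return config, counts, meta, tmp_path


class TestRunPipeline:
    def test_two_identical_runs_write_identical_numeric_outputs(self, tiny_inputs):
        from dataclasses import replace

        config, counts, meta, tmp_path = tiny_inputs
        outputs = {}
        for run in ("a", "b"):
            cfg = replace(
                config,
                counts_path=str(counts),
                metadata_path=str(meta),
                out_dir=str(tmp_path / run),
            )
            run_pipeline(cfg)
            text = (tmp_path / run / "performance_summary.tsv").read_text()
            # drop the config-hash comment: the two configs differ in out_dir only
            outputs[run] = [l for l in text.splitlines() if not l.startswith("#")]
        assert outputs["a"] == outputs["b"]

    def test_manifest_records_config_dims_and_performance(self, tiny_inputs):
        from dataclasses import replace

        config, counts, meta, tmp_path = tiny_inputs
        cfg = replace(config, counts_path=str(counts), metadata_path=str(meta))
        result = run_pipeline(cfg)
        manifest = json.loads((Path(cfg.out_dir) / "manifest.json").read_text())
        assert manifest["config_hash"] == cfg.hash
        assert manifest["stage_dims"]["n_retained"] == len(result.labels)
        assert 0 <= manifest["performance"]["voting"]["auc"] <= 1
        assert "scikit-learn" in manifest["versions"]
        # every output table carries the config hash
        summary_text = (Path(cfg.out_dir) / "performance_summary.tsv").read_text()
        assert summary_text.rstrip().endswith(f"# config: {cfg.hash}")

    def test_missing_input_path_rejected(self):
        cfg = RunConfig.from_dict(
            {"counts_path": "nope.tsv", "metadata_path": "nope2.tsv"}
        )
        with pytest.raises(ValidationError, match="does not exist"):
            run_pipeline(cfg)


class TestStrictNormalization:
    def test_strict_mode_defers_minmax_and_still_evaluates(self):
        config = RunConfig.from_dict(
            dict(
                TINY_RUN,
                preprocess={"min_fraction": 0.0, "strict_normalization": True},
                resample={"k_neighbors": 3, "mode": "within_fold"},
            )
        )
        table, records = generate_cohort(config.simulate)
        result = analyze(table, records, config)
        # feature matrix holds raw CLR coordinates (unbounded), not [0, 1]
        taxa_values = result.features.values.drop(columns=["Circumcised"]).to_numpy()
        assert taxa_values.min() < 0
        assert 0 <= result.summary.voting_auc <= 1

    def test_strict_mode_requires_within_fold_resampling(self):
        config = RunConfig.from_dict(
            dict(
                TINY_RUN,
                preprocess={"min_fraction": 0.0, "strict_normalization": True},
                resample={"k_neighbors": 3, "mode": "pre_cv"},
            )
        )
        table, records = generate_cohort(config.simulate)
        with pytest.raises(ValidationError, match="within_fold"):
            analyze(table, records, config)


def test_sensitivity_mode_drops_exactly_the_intermediate_baselines():
    config = RunConfig.from_dict(dict(TINY_RUN))
    table, records = generate_cohort(config.simulate)
    from bvpredict import build_cohort

    _, _, retained_main = build_cohort(records, table, False)
    _, _, retained_sens = build_cohort(records, table, True)
    n_intermediate = sum(
        1 for r in retained_main if 4 <= r.nugent_by_visit[0] <= 6
    )
    assert len(retained_main) - len(retained_sens) == n_intermediate


class TestCli:
    def test_simulate_then_run_all(self, tmp_path):
        config_path = tmp_path / "run.yaml"
        config_path.write_text(yaml.safe_dump(dict(TINY_RUN, out_dir=str(tmp_path / "out"))))
        runner = CliRunner()
        result = runner.invoke(cli, ["simulate", "-c", str(config_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "counts.tsv").exists()

        run_result = runner.invoke(cli, ["run-all", "-c", str(config_path)])
        assert run_result.exit_code == 0, run_result.output
        assert (tmp_path / "out" / "performance_summary.tsv").exists()
        assert "voting" in run_result.output

    def test_compare_subcommand(self, tmp_path):
        rng = np.random.default_rng(0)
        a, b = tmp_path / "a.txt", tmp_path / "b.txt"
        write_auc_vector(rng.uniform(0.85, 0.9, 40), a)
        write_auc_vector(rng.uniform(0.7, 0.75, 40), b)
        runner = CliRunner()
        result = runner.invoke(cli, ["compare", str(a), str(b), "--n-permutations", "200"])
        assert result.exit_code == 0, result.output
        assert "p = 0.004975" in result.output

    def test_validation_error_exits_with_code_two(self, tmp_path):
        import subprocess, sys

        config_path = tmp_path / "bad.yaml"
        config_path.write_text("unknown_key: 1\n")
        proc = subprocess.run(
            [sys.executable, "-m", "bvpredict.cli", "cohort", "-c", str(config_path)],
            capture_output=True,
            text=True,
        )
        assert proc.returncode == 2
        assert "validation error" in proc.stderr
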