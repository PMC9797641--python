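import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from changevec import (RunConfig, ScenarioSpec, analyze, pair_design,
                       run_pipeline, simulate_count_tables, taxon_level_sweep)
from changevec.cli import main as cli_main
from changevec.io import read_distance_matrix, write_feature_table
from changevec.ordination import bray_curtis


@pytest.fixture(scope="module")
def scenario():
    spec = ScenarioSpec(pairs_per_system=4, n_per_group=20,
                        parallelism_mode="parallel", seed=21)
    return simulate_count_tables(spec)


@pytest.fixture
def scenario_files(scenario, tmp_path):
    table, tax, meta = scenario
    write_feature_table(table, tmp_path / "table.tsv")
    with open(tmp_path / "taxonomy.tsv", "w") as fh:
        fh.write("Feature ID\tTaxon\n")
        for fid, ranks in tax.lineages.items():
            fh.write(f"{fid}\t{'; '.join(ranks)}\n")
    meta.data.to_csv(tmp_path / "metadata.tsv", sep="\t")
    with open(tmp_path / "design.tsv", "w") as fh:
        fh.write("#kind: pair\nvector_id\tfrom_group\tto_group\n")
        for e in pair_design(4).entries:
            fh.write(f"{e.vector_id}\t{e.from_group}\t{e.to_group}\n")
    return tmp_path


class TestRunPipeline:
    def test_parallel_scenario_all_tests_reject(self, scenario_files):
        config = RunConfig(feature_table=str(scenario_files / "table.tsv"),
                           metadata=str(scenario_files / "metadata.tsv"),
                           design=str(scenario_files / "design.tsv"),
                           output_dir=str(scenario_files / "out"),
                           methods=("t", "wilcoxon", "mc", "rayleigh"),
                           iterations=5000, seed=22)
        result = run_pipeline(config)
        assert all(t.p_value < 0.05 for t in result.tests)
        for name in ("distance_matrix.tsv", "ordination.tsv", "vectors.tsv",
                     "angles.tsv", "tests.tsv", "manifest.json"):
            assert (scenario_files / "out" / name).exists()

    def test_precomputed_matrix_path_equivalence(self, scenario, scenario_files):
        table, _, _ = scenario
        dm_path = scenario_files / "dm.tsv"
        from changevec.io import write_distance_matrix
        write_distance_matrix(bray_curtis(table), dm_path)
        base = dict(metadata=str(scenario_files / "metadata.tsv"),
                    design=str(scenario_files / "design.tsv"),
                    methods=("t",))
        r1 = run_pipeline(RunConfig(
            feature_table=str(scenario_files / "table.tsv"),
            output_dir=str(scenario_files / "o1"), **base))
        r2 = run_pipeline(RunConfig(
            distance_matrix=str(dm_path), metric="precomputed",
            output_dir=str(scenario_files / "o2"), **base))
        pd.testing.assert_frame_equal(r1.angles, r2.angles)

    def test_missing_design_fails_before_compute(self, scenario_files):
        config = RunConfig(feature_table=str(scenario_files / "table.tsv"),
                           metadata=str(scenario_files / "metadata.tsv"),
                           design=str(scenario_files / "nonexistent.tsv"),
                           output_dir=str(scenario_files / "out2"),
                           methods=("t",))
        with pytest.raises(FileNotFoundError):
            run_pipeline(config)
        assert not (scenario_files / "out2").exists()

    def test_mc_without_seed_rejected(self, scenario_files):
        config = RunConfig(feature_table=str(scenario_files / "table.tsv"),
                           metadata=str(scenario_files / "metadata.tsv"),
                           design=str(scenario_files / "design.tsv"),
                           methods=("mc",), seed=None)
        with pytest.raises(ValueError, match="seed"):
            config.validate()

    def test_rerun_reproduces_outputs_bit_for_bit(self, scenario_files):
        base = dict(feature_table=str(scenario_files / "table.tsv"),
                    metadata=str(scenario_files / "metadata.tsv"),
                    design=str(scenario_files / "design.tsv"),
                    methods=("t", "mc"), iterations=2000, seed=33,
                    rarefaction_depth=8000)
        run_pipeline(RunConfig(output_dir=str(scenario_files / "r1"), **base))
        run_pipeline(RunConfig(output_dir=str(scenario_files / "r2"), **base))
        for name in ("distance_matrix.tsv", "ordination.tsv", "angles.tsv",
                     "tests.tsv"):
            a = (scenario_files / "r1" / name).read_bytes()
            b = (scenario_files / "r2" / name).read_bytes()
            assert a == b

    def test_manifest_suffices_to_reexecute(self, scenario_files):
        config = RunConfig(feature_table=str(scenario_files / "table.tsv"),
                           metadata=str(scenario_files / "metadata.tsv"),
                           design=str(scenario_files / "design.tsv"),
                           output_dir=str(scenario_files / "m1"),
                           methods=("t",))
        r1 = run_pipeline(config)
        stored = json.loads(
            (scenario_files / "m1" / "manifest.json").read_text())["config"]
        stored["output_dir"] = str(scenario_files / "m2")
        stored["methods"] = tuple(stored["methods"])
        r2 = run_pipeline(RunConfig(**stored))
        pd.testing.assert_frame_equal(r1.angles, r2.angles)


class TestTaxonLevelSweep:
    def test_distinct_lineages_species_equals_unconllapsed(self, scenario):
        table, tax, meta = scenario
        sweep = taxon_level_sweep(table, tax, meta, pair_design(4),
                                  levels=("species",))
        base = analyze(table=table, metadata=meta, design=pair_design(4),
                       methods=())
        np.testing.assert_allclose(
            sweep.theta_deg.to_numpy(), base.angles.theta_deg.to_numpy(),
            atol=1e-9)

    def test_cross_level_angles_positively_correlated(self):
        from changevec import spearman
        spec = ScenarioSpec(pairs_per_system=5, n_per_group=20,
                            parallelism_mode="parallel", seed=21)
        table, tax, meta = simulate_count_tables(spec)
        sweep = taxon_level_sweep(table, tax, meta, pair_design(5))
        piv = sweep.pivot_table(index=["vector_id_1", "vector_id_2"],
                                columns="level", values="theta_deg")
        rho = spearman(piv["phylum"], piv["species"]).statistic \
            if len(piv) >= 3 else np.corrcoef(piv["phylum"], piv["species"])[0, 1]
        assert rho > 0

    def test_degenerate_level_skipped(self, small_table, metadata):
        from changevec import TaxonomyMap
        tax = TaxonomyMap({f: ("Bacteria", "P", f"C{f}")
                           for f in small_table.feature_ids})
        design = pair_design(0)
        # phylum level collapses to a single feature -> skipped; with no
        # analyzable level at all the sweep raises
        with pytest.raises(ValueError, match="no taxonomic level"):
            taxon_level_sweep(small_table, tax, metadata,
                              design, levels=("phylum",))


class TestCLI:
    def test_stagewise_subcommands_chain(self, scenario_files, tmp_path):
        runner = CliRunner()
        dm = tmp_path / "dm.tsv"
        r = runner.invoke(cli_main, ["distance", "--table",
                                     str(scenario_files / "table.tsv"),
                                     "--out", str(dm)])
        assert r.exit_code == 0, r.output
        ordf = tmp_path / "ord.tsv"
        r = runner.invoke(cli_main, ["pcoa", "--distance-matrix", str(dm),
                                     "--out", str(ordf)])
        assert r.exit_code == 0, r.output
        ang = tmp_path / "angles.tsv"
        vec = tmp_path / "vectors.tsv"
        r = runner.invoke(cli_main, ["vectors", "--ordination", str(ordf),
                                     "--metadata",
                                     str(scenario_files / "metadata.tsv"),
                                     "--design",
                                     str(scenario_files / "design.tsv"),
                                     "--out", str(ang),
                                     "--vectors-out", str(vec)])
        assert r.exit_code == 0, r.output
        out = tmp_path / "tests.tsv"
        r = runner.invoke(cli_main, ["test", "--angles", str(ang),
                                     "--vectors", str(vec), "--method", "all",
                                     "--iterations", "2000", "--seed", "1",
                                     "--out", str(out)])
        assert r.exit_code == 0, r.output
        summary = pd.read_csv(out, sep="\t")
        assert set(summary["method"]) == {"t_vs_90", "wilcoxon_vs_90",
                                          "monte_carlo", "rayleigh"}

    def test_simulate_subcommand_writes_artifacts(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(cli_main, ["simulate", "--out-dir", str(out),
                                     "--pairs", "2", "--n-per-group", "5",
                                     "--n-features", "50", "--depth", "2000",
                                     "--seed", "3"])
        assert r.exit_code == 0, r.output
        for name in ("feature_table.tsv", "taxonomy.tsv", "metadata.tsv",
                     "design.tsv", "ground_truth.tsv"):
            assert (out / name).exists()

    def test_run_subcommand_with_yaml_config(self, scenario_files, tmp_path):
        import yaml
        cfg = {"feature_table": str(scenario_files / "table.tsv"),
               "metadata": str(scenario_files / "metadata.tsv"),
               "design": str(scenario_files / "design.tsv"),
               "output_dir": str(tmp_path / "run_out"),
               "methods": ["t", "rayleigh"]}
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        runner = CliRunner()
        r = runner.invoke(cli_main, ["run", "--config", str(cfg_path)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "run_out" / "tests.tsv").exists()

    def test_compare_subcommand_restrict_filter(self, tmp_path):
        runner = CliRunner()
        pd.DataFrame({"theta_deg": [80.0, 95.0, 40.0]}).to_csv(
            tmp_path / "a.tsv", sep="\t", index=False)
        pd.DataFrame({"theta_deg": [85.0, 70.0, 30.0]}).to_csv(
            tmp_path / "b.tsv", sep="\t", index=False)
        r = runner.invoke(cli_main, ["compare", "--angles-a",
                                     str(tmp_path / "a.tsv"), "--angles-b",
                                     str(tmp_path / "b.tsv"),
                                     "--restrict-below-90"])
        assert r.exit_code == 0, r.output
        assert "n = 2" in r.output

    def test_run_missing_input_reports_config_error(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["run", "--table", "missing.tsv",
                                     "--metadata", "m.tsv", "--design",
                                     "d.tsv", "--out-dir", str(tmp_path)])
        assert r.exit_code == 1
        assert "error" in r.output.lower() or r.exception
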