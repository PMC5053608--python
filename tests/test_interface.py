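"""File formats, the end-to-end pipeline, and the CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from fisherset import (AnalysisConfig, match_sets, read_expression_matrix,
                       read_gmt, run_analysis)
from fisherset.cli import main as cli_main

from conftest import make_matrix


# ---------------------------------------------------------------------------
# synthetic fixture files
# ---------------------------------------------------------------------------

@pytest.fixture
def dataset(tmp_path):
    """Two-set synthetic experiment: SHIFTED's genes are differentially
    expressed between the groups, NULLSET's are not."""
    rng = np.random.default_rng(123)
    n1 = n2 = 12
    genes_a = [f"A{i}" for i in range(8)]
    genes_b = [f"B{i}" for i in range(8)]
    values = rng.standard_normal((16, n1 + n2))
    values[:8, n1:] += 1.2  # shift the A genes in group 2
    samples = [f"s{j}" for j in range(n1 + n2)]
    df = pd.DataFrame(values, index=genes_a + genes_b, columns=samples)
    expr = tmp_path / "expr.tsv"
    df.to_csv(expr, sep="\t")
    labels = tmp_path / "labels.tsv"
    labels.write_text("".join(
        f"{s}\t{'case' if j < n1 else 'control'}\n"
        for j, s in enumerate(samples)))
    gmt = tmp_path / "sets.gmt"
    gmt.write_text(
        "SHIFTED\tdiff expressed\t" + "\t".join(genes_a + ["MISSING1"]) + "\n"
        "NULLSET\tbackground\t" + "\t".join(genes_b) + "\n")
    return expr, labels, gmt


class TestGmt:
    def test_basic_line(self, tmp_path):
        f = tmp_path / "a.gmt"
        f.write_text("SET1\tdesc\tG1\tG2\n")
        coll = read_gmt(f)
        assert len(coll) == 1
        assert coll.get("SET1").gene_ids == ["G1", "G2"]

    def test_duplicate_genes_deduplicated_with_warning(self, tmp_path, caplog):
        f = tmp_path / "a.gmt"
        f.write_text("SET1\tdesc\tG1\tG1\n")
        with caplog.at_level("WARNING"):
            coll = read_gmt(f)
        assert coll.get("SET1").gene_ids == ["G1"]
        assert "duplicate" in caplog.text

    def test_short_line_errors_with_line_number(self, tmp_path):
        f = tmp_path / "a.gmt"
        f.write_text("SET1\tdesc\tG1\nBAD\tonlydesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(f)

    def test_duplicate_set_name_errors(self, tmp_path):
        f = tmp_path / "a.gmt"
        f.write_text("SET1\td\tG1\tG2\nSET1\td\tG3\tG4\n")
        with pytest.raises(ValueError, match="duplicate set name"):
            read_gmt(f)


class TestMatching:
    def test_absent_genes_dropped_and_counted(self, small_mat, tmp_path):
        f = tmp_path / "a.gmt"
        f.write_text("S\td\tg0\tg1\tg2\tnope1\tnope2\n")
        matched = match_sets(read_gmt(f), small_mat)
        s = matched.get("S")
        assert s.gene_ids == ["g0", "g1", "g2"]
        assert s.n_total == 5  # "3 of 5 found"

    def test_all_present_is_identity(self, small_mat, tmp_path):
        f = tmp_path / "a.gmt"
        f.write_text("S\td\tg0\tg1\n")
        assert match_sets(read_gmt(f), small_mat).get("S").gene_ids == ["g0", "g1"]

    def test_too_few_genes_skipped(self, small_mat, tmp_path, caplog):
        f = tmp_path / "a.gmt"
        f.write_text("S\td\tabsent1\tabsent2\nOK\td\tg0\tg1\n")
        with caplog.at_level("WARNING"):
            matched = match_sets(read_gmt(f), small_mat)
        assert matched.skipped == ["S"]
        assert len(matched) == 1

    def test_matching_is_case_sensitive(self, small_mat, tmp_path):
        f = tmp_path / "a.gmt"
        f.write_text("S\td\tG0\tG1\tg0\tg1\n")
        assert match_sets(read_gmt(f), small_mat).get("S").gene_ids == ["g0", "g1"]


class TestExpressionReader:
    def test_roundtrip(self, dataset):
        expr, labels, _ = dataset
        mat = read_expression_matrix(expr, labels)
        assert mat.n_genes == 16
        assert mat.groups == ("case", "control")
        assert mat.n1 == mat.n2 == 12

    def test_duplicate_gene_rows_keep_first(self, tmp_path, caplog):
        expr = tmp_path / "e.tsv"
        expr.write_text("gene\ts1\ts2\ts3\ts4\n"
                        "G1\t1\t2\t3\t4\nG1\t9\t9\t9\t9\nG2\t0\t1\t0\t1\n")
        labels = tmp_path / "l.tsv"
        labels.write_text("s1\ta\ns2\ta\ns3\tb\ns4\tb\n")
        with caplog.at_level("WARNING"):
            mat = read_expression_matrix(expr, labels)
        assert mat.n_genes == 2
        assert mat.values[0, 0] == 1.0

    def test_unlabelled_sample_errors(self, tmp_path):
        expr = tmp_path / "e.tsv"
        expr.write_text("gene\ts1\ts2\ts3\ts4\nG1\t1\t2\t3\t4\n")
        labels = tmp_path / "l.tsv"
        labels.write_text("s1\ta\ns2\ta\ns3\tb\n")
        with pytest.raises(ValueError, match="without labels"):
            read_expression_matrix(expr, labels)


class TestPipeline:
    def test_shifted_set_ranks_first(self, dataset, tmp_path):
        expr, labels, gmt = dataset
        cfg = AnalysisConfig(B=200, seed=1, p_min=0.01, extrapolate=False)
        res = run_analysis(expr, labels, gmt, cfg)
        assert list(res.columns) == [
            "set", "K", "genes_found", "F", "p_min", "p_perm", "count_ge",
            "p_uncorr", "p_extrapolated", "p_reported", "bh_retained"]
        a = res.set_index("set")
        assert a.loc["SHIFTED", "p_reported"] < a.loc["NULLSET", "p_reported"]
        assert a.loc["SHIFTED", "genes_found"] == 8
        assert a.loc["SHIFTED", "K"] == 9  # one gene absent from the matrix

    def test_rerun_is_byte_identical(self, dataset, tmp_path):
        expr, labels, gmt = dataset
        cfg = AnalysisConfig(B=100, seed=7)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_analysis(expr, labels, gmt, cfg, out_dir=out1)
        run_analysis(expr, labels, gmt, cfg, out_dir=out2)
        assert (out1 / "results.tsv").read_bytes() == \
               (out2 / "results.tsv").read_bytes()

    def test_extrapolation_path_beats_budget_floor(self, dataset):
        """A set far beyond the permutation resolution gets the power-law
        extrapolated p, which is below 1/(B+1)."""
        expr, labels, gmt = dataset
        B = 2000
        cfg = AnalysisConfig(B=B, seed=3, p_min=0.0, extrapolate=True)
        res = run_analysis(expr, labels, gmt, cfg).set_index("set")
        row = res.loc["SHIFTED"]
        assert row["count_ge"] == 0
        assert np.isfinite(row["p_extrapolated"])
        assert row["p_reported"] == row["p_extrapolated"] < 1 / (B + 1)

    def test_dependency_output_written(self, dataset, tmp_path):
        expr, labels, gmt = dataset
        cfg = AnalysisConfig(B=100, seed=2, dependency_output=True)
        out = tmp_path / "dep"
        run_analysis(expr, labels, gmt, cfg, out_dir=out)
        dep = pd.read_csv(out / "dependency_NULLSET.tsv", sep="\t", index_col=0)
        assert dep.shape == (8, 8)


class TestCli:
    def test_analyze_subcommand(self, dataset, tmp_path):
        expr, labels, gmt = dataset
        out = tmp_path / "cli_out"
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "analyze", str(expr), str(labels), str(gmt),
            "--out-dir", str(out), "-B", "100", "--seed", "5"])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(out / "results.tsv", sep="\t")
        assert {"set", "F", "p_perm", "bh_retained"} <= set(table.columns)

    def test_thresholds_subcommand(self, tmp_path):
        out = tmp_path / "t2.tsv"
        res = CliRunner().invoke(cli_main, ["thresholds", "--table", "dominant",
                                            "--out", str(out)])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(out, sep="\t", index_col=0)
        assert table.shape == (4, 5)

    def test_simulate_type1_subcommand(self, tmp_path):
        out = tmp_path / "t1.tsv"
        res = CliRunner().invoke(cli_main, [
            "simulate-type1", "--replicates", "30", "-B", "49",
            "--seed", "3", "--out", str(out)])
        assert res.exit_code == 0, res.output
        table = pd.read_csv(out, sep="\t", index_col=0)
        assert "fraction_significant" in table.columns

    def test_cli_outputs_stable_across_runs(self, tmp_path):
        args = ["simulate-type1", "--replicates", "20", "-B", "19",
                "--seed", "4"]
        o1, o2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        CliRunner().invoke(cli_main, args + ["--out", str(o1)])
        CliRunner().invoke(cli_main, args + ["--out", str(o2)])
        assert o1.read_bytes() == o2.read_bytes()
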