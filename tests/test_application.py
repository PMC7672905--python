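"""Tests for I/O alignment, standardization, gene screening and the pipeline."""

import json

import numpy as np
import pandas as pd
import pytest

from lcn2g.application import load_and_align, run_pipeline, screen_genes, standardize


class TestLoadAndAlign:
    def test_inner_join_drops_unshared_samples(self, csv_pair):
        X, E = load_and_align(*csv_pair)
        assert X.shape[0] == 5
        assert list(E.columns) == list(X.index)

    def test_transposed_expression_auto_detected(self, csv_pair, tmp_path):
        nutrient_file, expression_file = csv_pair
        E = pd.read_csv(expression_file, index_col=0).T  # samples x genes
        t_file = tmp_path / "expr_t.csv"
        E.to_csv(t_file)
        X1, E1 = load_and_align(nutrient_file, expression_file)
        X2, E2 = load_and_align(nutrient_file, t_file)
        pd.testing.assert_frame_equal(E1, E2)

    def test_missing_values_drop_sample(self, csv_pair, tmp_path):
        nutrient_file, expression_file = csv_pair
        X = pd.read_csv(nutrient_file, index_col=0).astype(object)
        X.loc["S2", "carb"] = "NA"
        na_file = tmp_path / "nutrients_na.csv"
        X.to_csv(na_file)
        Xa, Ea = load_and_align(na_file, expression_file)
        assert "S2" not in Xa.index
        assert Xa.shape[0] == 4

    def test_no_overlap_raises(self, csv_pair, tmp_path):
        nutrient_file, expression_file = csv_pair
        X = pd.read_csv(nutrient_file, index_col=0)
        X.index = [f"Z{i}" for i in range(len(X))]
        bad = tmp_path / "bad.csv"
        X.to_csv(bad)
        with pytest.raises(ValueError, match="overlap"):
            load_and_align(bad, expression_file)

    def test_non_numeric_cell_named_in_error(self, csv_pair, tmp_path):
        nutrient_file, expression_file = csv_pair
        X = pd.read_csv(nutrient_file, index_col=0).astype(object)
        X.loc["S3", "fat"] = "oops"
        bad = tmp_path / "badcell.csv"
        X.to_csv(bad)
        with pytest.raises(ValueError, match="S3.*fat"):
            load_and_align(bad, expression_file)


class TestStandardize:
    def test_hand_example_sample_sd(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = standardize(X)
        np.testing.assert_allclose(out["a"].values, [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, rng):
        X = pd.DataFrame(rng.uniform(10, 500, size=(40, 3)), columns=list("abc"))
        out = standardize(X)
        assert np.all(np.abs(out.mean()) < 1e-10)
        np.testing.assert_allclose(out.std(ddof=1), 1.0)

    def test_idempotent(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["u", "v"])
        once = standardize(X)
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize(X)


def test_ranking_invariant_to_column_rescaling(rng):
    """z-scoring first makes the LC ranking immune to per-column affine
    rescaling of the raw nutrient units."""
    from lcn2g.search import lc_opt_exhaustive

    X = pd.DataFrame(rng.standard_normal((40, 4)), columns=list("abcd"))
    G = rng.standard_normal(40)
    scaled = X * np.array([1000.0, 0.01, 3.0, 42.0]) + np.array([5, -2, 0, 100])
    r1 = lc_opt_exhaustive(standardize(X).values, G, k=2)
    r2 = lc_opt_exhaustive(standardize(scaled).values, G, k=2)
    assert [r.combination for r in r1] == [r.combination for r in r2]


class TestScreenGenes:
    @pytest.fixture
    def panel(self, rng):
        """12 genes: 3 follow the single-peak model on a nutrient pair, 9 noise."""
        n = 100
        X = pd.DataFrame(
            rng.standard_normal((n, 5)),
            columns=[f"N{i}" for i in range(5)],
            index=[f"S{i}" for i in range(n)],
        )
        genes = {}
        for g in range(3):
            genes[f"sig{g}"] = (
                np.exp(-(X["N0"] ** 2 + X["N1"] ** 2)) + 0.1 * rng.standard_normal(n)
            )
        for g in range(9):
            genes[f"noise{g}"] = rng.standard_normal(n)
        E = pd.DataFrame(genes).T
        E.columns = X.index
        return X, E

    def test_signal_genes_kept(self, panel):
        X, E = panel
        res = screen_genes(X, E, k=2, B=200, alpha=0.05, seed=0)
        kept = set(res.kept_genes)
        assert {"sig0", "sig1", "sig2"} <= kept
        assert res.n_combinations == 10  # C(5,2)

    def test_alpha_one_keeps_all_non_degenerate(self, panel):
        X, E = panel
        res = screen_genes(X, E, k=2, B=20, alpha=1.0, seed=0)
        assert res.table["kept"].all()

    def test_degenerate_gene_dropped_not_fatal(self, panel):
        X, E = panel
        E.loc["flat"] = 1.0
        res = screen_genes(X, E, k=2, B=20, alpha=0.05, seed=0)
        row = res.table.set_index("gene").loc["flat"]
        assert not row["kept"] and "degenerate" in row["note"]


class TestPipeline:
    @pytest.fixture
    def sim_files(self, tmp_path):
        from lcn2g.simulation import SimulationConfig, simulate_dataset

        ds = simulate_dataset(SimulationConfig(model=1, n=100, d=6, r=0.1, seed=21))
        ids = [f"S{i}" for i in range(100)]
        nf = tmp_path / "nut.csv"
        ef = tmp_path / "expr.csv"
        pd.DataFrame(ds.X, index=ids, columns=ds.column_names).to_csv(nf)
        pd.DataFrame({"target": ds.G}, index=ids).T.to_csv(ef)
        return nf, ef, ds.informative_set

    def test_recovers_informative_pair_and_writes_outputs(self, sim_files, tmp_path):
        nf, ef, informative = sim_files
        out = run_pipeline(nf, ef, ["target"], tmp_path / "out", k=2, B=200, seed=3)
        log = json.loads((out / "run_log.json").read_text())
        entry = log["genes"]["target"]
        assert entry["significant"]
        assert entry["p_value"] <= 0.05
        assert set(entry["top_combination"]) <= {"X1", "X2", "X3", "X4", "X5", "X6"}
        assert (out / "target_ranked.tsv").exists()
        assert (out / "target_surface.png").exists()

    def test_missing_gene_logged_not_fatal(self, sim_files, tmp_path):
        nf, ef, _ = sim_files
        out = run_pipeline(nf, ef, ["nope"], tmp_path / "out2", k=2, B=20, seed=3)
        log = json.loads((out / "run_log.json").read_text())
        assert "error" in log["genes"]["nope"]

    def test_rerun_identical_outputs(self, sim_files, tmp_path):
        nf, ef, _ = sim_files
        o1 = run_pipeline(nf, ef, ["target"], tmp_path / "a", B=100, seed=5, plot=False)
        o2 = run_pipeline(nf, ef, ["target"], tmp_path / "b", B=100, seed=5, plot=False)
        assert (o1 / "target_ranked.tsv").read_text() == (o2 / "target_ranked.tsv").read_text()
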