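"""IO round-trips, QC filtering, CP10K normalization and cluster profiles."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conftest import make_dataset
from toppathways import (
    EmptyDatasetError,
    LoadError,
    QCParams,
    ValidationError,
    aggregate_pathway_heatmap,
    cluster_profile,
    load_expression,
    normalize_cp10k,
    qc_filter,
    write_expression,
)
from conftest import make_db, make_profile


class TestLoadWrite:
    def test_round_trip_preserves_counts_exactly(self, tmp_path):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(7, 5))
        ds = make_dataset(counts, [f"G{i}" for i in range(7)], ["A", "A", "B", "B", "B"])
        write_expression(ds, tmp_path)
        loaded = load_expression(
            tmp_path / "matrix.mtx", tmp_path / "genes.tsv", tmp_path / "cells.tsv", ["s1"]
        )
        assert (loaded.counts != ds.counts).nnz == 0
        assert list(loaded.gene_ids) == list(ds.gene_ids)
        pd.testing.assert_frame_equal(loaded.cells, ds.cells)

    def test_small_matrix_shape(self, tmp_path):
        ds = make_dataset(np.arange(6).reshape(3, 2), ["a", "b", "c"], ["A", "B"])
        write_expression(ds, tmp_path)
        loaded = load_expression(
            tmp_path / "matrix.mtx", tmp_path / "genes.tsv", tmp_path / "cells.tsv", ["s1"]
        )
        assert (loaded.n_genes, loaded.n_cells) == (3, 2)

    def test_dimension_mismatch_names_offending_file(self, tmp_path):
        ds = make_dataset(np.ones((3, 2), dtype=int), ["a", "b", "c"], ["A", "B"])
        write_expression(ds, tmp_path)
        cells = pd.read_csv(tmp_path / "cells.tsv", sep="\t")
        pd.concat([cells, cells.iloc[[0]]]).to_csv(tmp_path / "cells.tsv", sep="\t", index=False)
        with pytest.raises(LoadError, match="cells.tsv"):
            load_expression(
                tmp_path / "matrix.mtx", tmp_path / "genes.tsv", tmp_path / "cells.tsv", ["s1"]
            )

    def test_duplicate_gene_id_rejected(self, tmp_path):
        ds = make_dataset(np.ones((2, 2), dtype=int), ["a", "b"], ["A", "B"])
        write_expression(ds, tmp_path)
        (tmp_path / "genes.tsv").write_text("a\na\n")
        with pytest.raises(ValidationError, match="duplicate gene"):
            load_expression(
                tmp_path / "matrix.mtx", tmp_path / "genes.tsv", tmp_path / "cells.tsv", ["s1"]
            )

    def test_unknown_stage_rejected(self, tmp_path):
        ds = make_dataset(np.ones((2, 2), dtype=int), ["a", "b"], ["A", "B"])
        write_expression(ds, tmp_path)
        with pytest.raises(ValidationError, match="stage"):
            load_expression(
                tmp_path / "matrix.mtx", tmp_path / "genes.tsv", tmp_path / "cells.tsv", ["other"]
            )


class TestQCFilter:
    def _band_dataset(self):
        # 5 cells with UMI totals 50, 100, 900, 1500, 1501 in a single gene
        counts = np.array([[50, 100, 900, 1500, 1501]])
        return make_dataset(counts, ["G1"], ["A"] * 5)

    def test_umi_band_inclusive(self):
        out = qc_filter(self._band_dataset(), QCParams())
        assert sorted(out.cells["umi"]) == [100, 900, 1500]

    def test_mito_prefix_case_insensitive(self):
        counts = np.array([[5, 5], [3, 3], [7, 7]])
        ds = make_dataset(counts, ["MT-CO1", "mt-nd1", "ACTB"], ["A", "B"])
        out = qc_filter(ds, QCParams(min_umi=0, max_umi=10**9))
        assert list(out.gene_ids) == ["ACTB"]
        assert list(out.cells["umi"]) == [7, 7]  # recomputed after gene removal

    def test_no_op_when_unbounded(self, toy_dataset):
        out = qc_filter(toy_dataset, QCParams(min_umi=0, max_umi=10**9))
        assert (out.counts != toy_dataset.counts).nnz == 0

    def test_idempotent(self, toy_dataset):
        params = QCParams(min_umi=0, max_umi=int(toy_dataset.cells["umi"].median()))
        once = qc_filter(toy_dataset, params)
        twice = qc_filter(once, params)
        assert (once.counts != twice.counts).nnz == 0
        pd.testing.assert_frame_equal(once.cells, twice.cells)

    def test_all_cells_removed_raises(self):
        with pytest.raises(EmptyDatasetError):
            qc_filter(self._band_dataset(), QCParams(min_umi=5000, max_umi=6000))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValidationError):
            QCParams(min_umi=200, max_umi=100)


class TestNormalizeCP10K:
    def test_formula(self):
        counts = np.array([[4], [1996]])  # cell with umi 2000, gene count 4
        ds = make_dataset(counts, ["G1", "G2"], ["A"])
        out = normalize_cp10k(ds)
        assert out.normalized[0, 0] == pytest.approx(20.0)

    def test_column_sums_are_1e4_and_zero_rows_stay_zero(self, toy_dataset):
        ds = toy_dataset
        zero_row = np.zeros((1, ds.n_cells), dtype=int)
        ds = make_dataset(
            np.vstack([np.asarray(ds.counts.todense()), zero_row]),
            list(ds.gene_ids) + ["ZERO"],
            list(ds.cells["cluster"]),
        )
        out = normalize_cp10k(ds)
        sums = np.asarray(out.normalized.sum(axis=0)).ravel()
        assert np.allclose(sums, 1e4, atol=1e-6)
        assert out.normalized[-1].nnz == 0

    def test_zero_umi_cell_instructs_qc(self):
        ds = make_dataset(np.zeros((2, 2), dtype=int), ["a", "b"], ["A", "B"])
        with pytest.raises(ValidationError, match="qc_filter"):
            normalize_cp10k(ds)


class TestClusterProfile:
    def test_hand_average(self):
        normalized = np.array([[2.0, 4.0]])
        ds = make_dataset(np.array([[1, 1]]), ["G1"], ["A", "A"], normalized=normalized)
        profile = cluster_profile(ds)
        assert profile.mean_expr.loc["G1", "A"] == pytest.approx(3.0)
        assert profile.expr_frac.loc["G1", "A"] == pytest.approx(1.0)

    def test_absent_gene_and_singleton_cluster(self):
        normalized = np.array([[0.0, 5.0], [1.0, 0.0]])
        counts = np.array([[0, 3], [2, 0]])
        ds = make_dataset(counts, ["G1", "G2"], ["A", "B"], normalized=normalized)
        profile = cluster_profile(ds)
        assert profile.mean_expr.loc["G1", "A"] == 0.0
        assert profile.expr_frac.loc["G1", "A"] == 0.0
        assert profile.mean_expr.loc["G1", "B"] == 5.0  # single-cell cluster

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(7)
        n_cells, n_genes = 50, 12
        clusters = rng.choice(["A", "B", "C"], size=n_cells).tolist()
        counts = rng.integers(0, 10, size=(n_genes, n_cells))
        counts[:, 0] += 1  # no zero-umi cell
        ds = normalize_cp10k(
            make_dataset(counts, [f"G{i}" for i in range(n_genes)], clusters)
        )
        profile = cluster_profile(ds)
        dense = np.asarray(ds.normalized.todense())
        for cl in sorted(set(clusters)):
            members = [i for i, c in enumerate(clusters) if c == cl]
            expected = dense[:, members].mean(axis=1)
            np.testing.assert_allclose(profile.mean_expr[cl].to_numpy(), expected, rtol=1e-12)
            frac = (counts[:, members] > 0).mean(axis=1)
            np.testing.assert_allclose(profile.expr_frac[cl].to_numpy(), frac, rtol=1e-12)


class TestHeatmapAggregation:
    def test_single_and_summed_ligands(self):
        profile = make_profile({"L1": {"A": 1.5, "B": 0.0}, "L2": {"A": 1.0, "B": 2.0}})
        db = make_db([("L1", "R1", "FGF"), ("L2", "R1", "FGF")])
        vec = aggregate_pathway_heatmap(profile, db, "FGF", "ligand")
        assert vec["A"] == pytest.approx(2.5)
        assert vec["B"] == pytest.approx(2.0)
        one = make_db([("L1", "R1", "FGF")])
        vec1 = aggregate_pathway_heatmap(profile, one, "FGF", "ligand")
        assert vec1["A"] == pytest.approx(1.5) and vec1["B"] == 0.0

    def test_duplicate_gene_counted_once(self):
        profile = make_profile({"L1": {"A": 1.0, "B": 2.0}})
        db = make_db([("L1", "R1", "FGF"), ("L1", "R2", "FGF")])
        vec = aggregate_pathway_heatmap(profile, db, "FGF", "ligand")
        assert vec["A"] == pytest.approx(1.0)

    def test_unknown_pathway_lists_available(self):
        profile = make_profile({"L1": {"A": 1.0}})
        db = make_db([("L1", "R1", "FGF")])
        with pytest.raises(ValidationError, match="FGF"):
            aggregate_pathway_heatmap(profile, db, "WNT", "ligand")

    def test_bad_role_rejected(self):
        profile = make_profile({"L1": {"A": 1.0}})
        db = make_db([("L1", "R1", "FGF")])
        with pytest.raises(ValidationError, match="role"):
            aggregate_pathway_heatmap(profile, db, "FGF", "tf")
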