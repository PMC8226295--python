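import numpy as np
import pytest
import scipy.sparse as sp

from chronocell import (
    CountMatrix,
    QCThresholds,
    filter_cells,
    normalize_log,
    pca,
    qc_metrics,
    scale_center,
    select_variable_genes,
)
from conftest import make_counts, make_norm


class TestQCMetrics:
    def test_umis_and_genes_match_dense_recomputation(self):
        rng = np.random.default_rng(5)
        m = make_counts(rng, n_cells=20, n_genes=50, lam=0.7)
        rep = qc_metrics(m)
        dense = np.asarray(m.counts.todense())
        assert np.array_equal(rep.per_cell["n_umis"].to_numpy(), dense.sum(axis=1))
        assert np.array_equal(
            rep.per_cell["n_genes_detected"].to_numpy(), (dense > 0).sum(axis=1)
        )

    def test_pure_mito_cell_pct_100(self):
        counts = sp.csr_matrix(np.array([[0, 3], [2, 0]]))
        m = CountMatrix(counts, np.array(["b0", "b1"], object), np.array(["g0", "gm"], object),
                        np.array(["s", "s"], object), np.array(["nuclear", "mito"], object))
        rep = qc_metrics(m)
        assert rep.per_cell["pct_mito"].tolist() == [100.0, 0.0]

    def test_zero_umi_cell_flagged_with_zero_percentages(self):
        counts = sp.csr_matrix(np.array([[0, 0], [1, 1]]))
        m = CountMatrix(counts, np.array(["b0", "b1"], object), np.array(["g0", "g1"], object),
                        np.array(["s", "s"], object), np.array(["mito", "chloro"], object))
        rep = qc_metrics(m)
        assert bool(rep.per_cell.loc["b0", "zero_umis"])
        assert rep.per_cell.loc["b0", "pct_mito"] == 0.0


class TestFilterCells:
    def _matrix_with(self, n_genes_detected, umis_each):
        """One cell expressing `n_genes_detected` genes totalling umis."""
        row = np.zeros(200, dtype=int)
        base = umis_each // max(n_genes_detected, 1)
        row[:n_genes_detected] = base
        row[0] += umis_each - base * n_genes_detected
        return row

    def test_boundary_cells(self):
        rows = np.vstack([
            self._matrix_with(99, 10_000),   # genes below threshold -> removed
            self._matrix_with(100, 300),     # exactly at both thresholds -> retained
            self._matrix_with(150, 299),     # UMIs below -> removed
            self._matrix_with(150, 5000),    # comfortably above -> retained
        ])
        m = CountMatrix(sp.csr_matrix(rows),
                        np.array([f"b{i}" for i in range(4)], object),
                        np.array([f"g{i}" for i in range(200)], object),
                        np.array(["s"] * 4, object),
                        np.array(["nuclear"] * 200, object))
        kept = filter_cells(m, QCThresholds())
        assert list(kept.barcodes) == ["b1", "b3"]

    def test_hand_enumerated_fixture(self):
        rng = np.random.default_rng(11)
        m = make_counts(rng, n_cells=20, n_genes=40, lam=1.0)
        t = QCThresholds(min_genes=15, min_umis=30)
        dense = np.asarray(m.counts.todense())
        expected = [i for i in range(20)
                    if (dense[i] > 0).sum() >= 15 and dense[i].sum() >= 30]
        kept = filter_cells(m, t)
        assert list(kept.barcodes) == [f"bc{i}" for i in expected]
        assert kept.n_genes == m.n_genes

    def test_idempotent(self):
        m = make_counts(np.random.default_rng(12), n_cells=30, n_genes=40, lam=1.5)
        t = QCThresholds(min_genes=10, min_umis=20)
        once = filter_cells(m, t)
        twice = filter_cells(once, t)
        assert once.equals(twice)

    def test_all_cells_removed_is_hard_error(self):
        m = make_counts(np.random.default_rng(13), n_cells=5, n_genes=10, lam=0.5)
        with pytest.raises(ValueError, match="fail QC"):
            filter_cells(m, QCThresholds(min_genes=10**6, min_umis=10**6))


class TestNormalizeLog:
    def test_stated_formula_on_small_cell(self):
        counts = sp.csr_matrix(np.array([[1, 1, 2]]))
        m = CountMatrix(counts, np.array(["b"], object), np.array(["g0", "g1", "g2"], object),
                        np.array(["s"], object), np.array(["nuclear"] * 3, object))
        n = normalize_log(m)
        dense = np.asarray(n.values.todense()).ravel()
        assert dense[2] == pytest.approx(np.log(1 + 10_000 * 2 / 4))
        assert dense[0] == pytest.approx(np.log(1 + 10_000 * 1 / 4))

    def test_zero_counts_stay_zero_and_sparsity_preserved(self):
        m = make_counts(np.random.default_rng(14), lam=0.5)
        m = filter_cells(m, QCThresholds(min_genes=1, min_umis=1))
        n = normalize_log(m)
        assert n.values.nnz == m.counts.nnz

    def test_conservation_sum_expm1_equals_scale_factor(self):
        for seed in range(10):
            m = make_counts(np.random.default_rng(seed), n_cells=15, n_genes=30, lam=1.0)
            m = filter_cells(m, QCThresholds(min_genes=1, min_umis=1))
            n = normalize_log(m)
            sums = np.asarray(np.expm1(n.values.todense()).sum(axis=1)).ravel()
            assert np.allclose(sums, 10_000, rtol=1e-6)

    def test_zero_total_cell_rejected(self):
        counts = sp.csr_matrix(np.array([[0, 0], [1, 2]]))
        m = CountMatrix(counts, np.array(["b0", "b1"], object), np.array(["g0", "g1"], object),
                        np.array(["s", "s"], object), np.array(["nuclear"] * 2, object))
        with pytest.raises(ValueError, match="filter_cells"):
            normalize_log(m)


class TestVariableGenes:
    def test_high_variance_gene_ranked_first(self):
        rng = np.random.default_rng(21)
        base = rng.normal(1.0, 0.05, size=(60, 20))
        base[:, 7] = rng.normal(1.0, 1.5, size=60)  # same mean, 10x the sd
        n = make_norm(np.clip(base, 0, None))
        ranked = select_variable_genes(n, n_top=5)
        assert ranked[0] == "g7"

    def test_constant_matrix_yields_nothing(self):
        n = make_norm(np.ones((10, 8)))
        assert len(select_variable_genes(n, n_top=5)) == 0

    def test_ranking_invariant_to_cell_permutation(self):
        rng = np.random.default_rng(22)
        x = rng.gamma(2.0, 1.0, size=(40, 30))
        n1 = make_norm(x)
        n2 = make_norm(x[rng.permutation(40)])
        assert list(select_variable_genes(n1, 10)) == list(select_variable_genes(n2, 10))

    def test_fewer_qualifying_genes_returns_all(self):
        rng = np.random.default_rng(23)
        n = make_norm(rng.gamma(2.0, 1.0, size=(20, 6)))
        assert len(select_variable_genes(n, n_top=2000)) == 6


class TestScaleAndPCA:
    def test_scaled_columns_centered_unit_variance(self):
        rng = np.random.default_rng(31)
        n = make_norm(rng.gamma(2.0, 1.0, size=(30, 12)))
        x, kept = scale_center(n, n.genes)
        assert np.allclose(x.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(x.std(axis=0), 1, atol=1e-6)

    def test_clipping_applied(self):
        x = np.zeros((101, 2))
        x[0, 0] = 1000.0  # extreme outlier: z-score far beyond 10
        n = make_norm(x + 1.0)
        scaled, _ = scale_center(n, n.genes)
        assert scaled.max() <= 10.0 + 1e-12

    def test_pca_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(32)
        n = make_norm(rng.gamma(2.0, 1.0, size=(30, 15)))
        x, _ = scale_center(n, n.genes)
        emb = pca(x, n_components=5)
        u, s, _ = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
        oracle = u[:, :5] * s[:5]
        assert np.allclose(np.abs(emb), np.abs(oracle), atol=1e-6)

    def test_rank_two_matrix_has_no_third_component(self):
        rng = np.random.default_rng(33)
        a = rng.normal(size=(40, 2))
        b = rng.normal(size=(2, 9))
        emb = pca(a @ b, n_components=5)
        assert emb[:, 2:].std() < 1e-10

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            pca(np.zeros((5, 4)), n_components=10)
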