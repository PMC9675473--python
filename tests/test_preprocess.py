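"""QC metrics, filtering, normalization, HVG and doublet-cluster flagging."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nephromac.core_io import ExpressionMatrix
from nephromac.preprocess import (
    EmptyResultError,
    HVGParams,
    QCParams,
    compute_qc,
    filter_cells_genes,
    flag_doublet_clusters,
    hvg_statistics,
    normalize_to_median,
    select_hvg,
)


class TestComputeQC:
    def test_metric_definitions(self, tiny_matrix):
        qc = compute_qc(tiny_matrix, "mt-")
        row = qc.set_index("cell_id")
        # cell c1: counts [3, 0, 1] over [A, mt-B, C]
        assert row.loc["c1", "n_genes"] == 2
        assert row.loc["c1", "total_counts"] == 4
        assert row.loc["c1", "mito_frac"] == 0.0
        # cell c2: [0, 5, 0] -> pure mitochondrial
        assert row.loc["c2", "mito_frac"] == 1.0

    def test_matches_per_cell_brute_force(self, random_matrix):
        qc = compute_qc(random_matrix, "mt-").set_index("cell_id")
        X = random_matrix.dense()
        mito = [g.lower().startswith("mt-") for g in random_matrix.gene_ids]
        for j, cell in enumerate(random_matrix.cell_ids):
            col = X[:, j]
            assert qc.loc[cell, "n_genes"] == int((col > 0).sum())
            assert qc.loc[cell, "total_counts"] == col.sum()
            expected = col[mito].sum() / col.sum() if col.sum() else 0.0
            assert qc.loc[cell, "mito_frac"] == pytest.approx(expected, abs=1e-12)

    def test_no_mito_match_warns_and_zeroes(self, tiny_matrix):
        with pytest.warns(UserWarning, match="matched no gene"):
            qc = compute_qc(tiny_matrix, "MTGENE-")
        assert (qc["mito_frac"] == 0).all()


def _matrix_with_n_genes(per_cell_genes, n_genes=3000):
    """One cell per requested detected-gene count, mito-free."""
    cols = []
    for k in per_cell_genes:
        col = np.zeros(n_genes)
        col[:k] = 1
        cols.append(col)
    dense = np.column_stack(cols)
    return ExpressionMatrix(
        sp.csr_matrix(dense),
        [f"G{i}" for i in range(n_genes)],
        [f"c{i}" for i in range(len(per_cell_genes))],
        layer="raw",
    )


class TestFilter:
    def test_gene_count_window(self):
        m = _matrix_with_n_genes([150, 300, 2600])
        qc = compute_qc(m, "mt-")
        out = filter_cells_genes(m, qc, QCParams(min_cells_per_gene=1))
        assert out.cell_ids == ["c1"]  # only the 300-gene cell survives

    def test_idempotence(self, random_matrix):
        params = QCParams(min_genes=1, max_genes=100, max_mito_frac=1.0,
                          min_cells_per_gene=2)
        qc = compute_qc(random_matrix, "mt-")
        once = filter_cells_genes(random_matrix, qc, params)
        twice = filter_cells_genes(once, compute_qc(once, "mt-"), params)
        assert twice.cell_ids == once.cell_ids
        assert twice.gene_ids == once.gene_ids

    def test_matches_brute_force_rule(self, random_matrix):
        params = QCParams(min_genes=5, max_genes=30, max_mito_frac=0.2,
                          min_cells_per_gene=3)
        qc = compute_qc(random_matrix, "mt-").set_index("cell_id")
        out = filter_cells_genes(random_matrix, qc.reset_index(), params)
        X = random_matrix.dense()
        keep_cells = [
            c for j, c in enumerate(random_matrix.cell_ids)
            if params.min_genes <= qc.loc[c, "n_genes"] <= params.max_genes
            and qc.loc[c, "mito_frac"] < params.max_mito_frac
        ]
        cols = [random_matrix.cell_ids.index(c) for c in keep_cells]
        keep_genes = [
            g for i, g in enumerate(random_matrix.gene_ids)
            if (X[i, cols] > 0).sum() >= params.min_cells_per_gene
        ]
        assert out.cell_ids == keep_cells
        assert out.gene_ids == keep_genes

    def test_all_cells_removed_is_explicit_error(self):
        m = _matrix_with_n_genes([150, 100])
        qc = compute_qc(m, "mt-")
        with pytest.raises(EmptyResultError):
            filter_cells_genes(m, qc, QCParams())


class TestNormalize:
    def test_stated_scale_factors(self):
        dense = np.array([[100, 200, 300]])
        m = ExpressionMatrix(sp.csr_matrix(dense), ["G0"], ["a", "b", "c"])
        out = normalize_to_median(m)
        totals = np.asarray(out.values.sum(axis=0)).ravel()
        # totals [100, 200, 300] -> factors [2, 1, 2/3], all totals 200
        np.testing.assert_allclose(totals, [200, 200, 200], rtol=1e-12)
        np.testing.assert_allclose(
            out.dense()[0] / dense[0], [2, 1, 2 / 3], rtol=1e-12
        )

    def test_equal_totals_is_identity(self):
        dense = np.array([[2, 2], [3, 3]])
        m = ExpressionMatrix(sp.csr_matrix(dense), ["g1", "g2"], ["a", "b"])
        np.testing.assert_allclose(normalize_to_median(m).dense(), dense)

    def test_all_totals_hit_median_and_zero_pattern_kept(self, random_matrix):
        qc = compute_qc(random_matrix, "mt-")
        m = filter_cells_genes(
            random_matrix, qc,
            QCParams(min_genes=1, max_genes=10**6, max_mito_frac=1.0,
                     min_cells_per_gene=1),
        )
        pre = np.asarray(m.values.sum(axis=0)).ravel()
        out = normalize_to_median(m)
        post = np.asarray(out.values.sum(axis=0)).ravel()
        np.testing.assert_allclose(post, np.median(pre), rtol=1e-9)
        assert out.layer == "normalized"
        assert ((m.dense() == 0) == (out.dense() == 0)).all()

    def test_all_zero_cell_rejected(self):
        m = ExpressionMatrix(
            sp.csr_matrix(np.array([[1, 0]])), ["g"], ["a", "b"]
        )
        with pytest.raises(ValueError, match="filter"):
            normalize_to_median(m)


class TestHVG:
    def _normalized(self, dense, genes=None):
        genes = genes or [f"G{i}" for i in range(dense.shape[0])]
        cells = [f"c{i}" for i in range(dense.shape[1])]
        m = ExpressionMatrix(sp.csr_matrix(dense.astype(float)), genes, cells)
        return normalize_to_median(m)

    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(3, size=(30, 20)).astype(float) + 1
        dense[0] = 2.0  # zero variance
        m = ExpressionMatrix(
            sp.csr_matrix(dense),
            [f"G{i}" for i in range(30)],
            [f"c{i}" for i in range(20)],
            layer="normalized",
        )
        selected = select_hvg(m, HVGParams(min_mean=0.0, max_mean=100, min_disp=0.5))
        assert "G0" not in selected

    def test_matches_independent_bin_rule(self, random_matrix):
        qc = compute_qc(random_matrix, "mt-")
        m = normalize_to_median(
            filter_cells_genes(
                random_matrix, qc,
                QCParams(min_genes=1, max_genes=10**6, max_mito_frac=1.0,
                         min_cells_per_gene=1),
            )
        )
        params = HVGParams(min_mean=0.0125, max_mean=3.0, min_disp=0.5)
        selected = set(select_hvg(m, params))

        # independent reimplementation: sort genes by mean, split into 20
        # equal-count chunks, z-score var/mean within each chunk
        X = np.log1p(m.dense())
        mean = X.mean(axis=1)
        var = X.var(axis=1, ddof=1)
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1), 0.0)
        # equal-frequency bins: gene at mean-rank i goes to bin i*20 // n
        order = np.argsort(mean, kind="stable")
        chunks = [[] for _ in range(20)]
        for rank, gene_idx in enumerate(order):
            chunks[(rank * 20) // len(order)].append(gene_idx)
        chunks = [np.array(c, dtype=int) for c in chunks]
        expected = set()
        for chunk in chunks:
            if len(chunk) == 0:
                continue
            mu = disp[chunk].mean()
            sd = disp[chunk].std(ddof=1) if len(chunk) > 1 else 0.0
            for i in chunk:
                z = (disp[i] - mu) / sd if sd > 0 else 0.0
                if params.min_mean <= mean[i] <= params.max_mean and z >= params.min_disp:
                    expected.add(m.gene_ids[i])
        assert selected == expected

    def test_raising_min_disp_is_monotone(self, random_matrix):
        qc = compute_qc(random_matrix, "mt-")
        m = normalize_to_median(
            filter_cells_genes(
                random_matrix, qc,
                QCParams(min_genes=1, max_genes=10**6, max_mito_frac=1.0,
                         min_cells_per_gene=1),
            )
        )
        lo = set(select_hvg(m, HVGParams(min_disp=0.25)))
        hi = set(select_hvg(m, HVGParams(min_disp=1.0)))
        assert hi <= lo

    def test_few_genes_single_bin_warning(self):
        dense = np.random.default_rng(1).poisson(2, size=(5, 10)).astype(float) + 1
        m = self._normalized(dense)
        with pytest.warns(UserWarning, match="single bin"):
            hvg_statistics(m, 20)


class TestDoubletFlagging:
    def test_null_clusters_not_flagged(self):
        rng = np.random.default_rng(5)
        scores = rng.beta(2, 20, size=1000)
        clusters = np.repeat([f"C{i}" for i in range(10)], 100)
        reports = flag_doublet_clusters(scores, clusters)
        assert sum(r.flagged for r in reports) == 0

    def test_hand_computed_outlier_oracle(self):
        # 9 clusters with medians pinned near 0.1, one shifted upward by
        # 10x the MAD-equivalent; statistic recomputed by hand below
        from scipy import stats as ss
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        base = [rng.uniform(0.09, 0.11, size=51) for _ in range(9)]
        medians9 = np.array([np.median(b) for b in base])
        center0 = np.median(medians9)
        mad0 = np.median(np.abs(medians9 - center0))
        shifted = np.full(51, center0 + 10 * 1.4826 * mad0)
        scores = np.concatenate(base + [shifted])
        clusters = np.repeat([f"C{i}" for i in range(10)], 51)

        reports = flag_doublet_clusters(scores, clusters)
        by = {r.cluster: r for r in reports}
        assert by["C9"].flagged and sum(r.flagged for r in reports) == 1

        medians = np.array([np.median(scores[clusters == f"C{i}"]) for i in range(10)])
        center = np.median(medians)
        scale = 1.4826 * np.median(np.abs(medians - center))
        z = (medians - center) / scale
        p = ss.t.sf(z, df=0.37 * 9)
        p_adj = multipletests(p, method="fdr_bh")[1]
        for i in range(10):
            r = by[f"C{i}"]
            assert r.robust_z == pytest.approx(z[i], abs=1e-12)
            assert r.p_adj_bh == pytest.approx(p_adj[i], abs=1e-12)

    def test_flagging_threshold_is_strict(self):
        rng = np.random.default_rng(8)
        base = [rng.uniform(0.09, 0.11, size=51) for _ in range(9)]
        medians9 = np.array([np.median(b) for b in base])
        mad0 = np.median(np.abs(medians9 - np.median(medians9)))
        shifted = np.full(51, np.median(medians9) + 10 * 1.4826 * mad0)
        scores = np.concatenate(base + [shifted])
        clusters = np.repeat([f"C{i}" for i in range(10)], 51)
        p_adj = {
            r.cluster: r.p_adj_bh
            for r in flag_doublet_clusters(scores, clusters)
        }["C9"]
        # alpha exactly at the adjusted p: strict '<' means not flagged
        at = flag_doublet_clusters(scores, clusters, alpha=p_adj)
        above = flag_doublet_clusters(scores, clusters, alpha=p_adj * 1.0001)
        assert not {r.cluster: r for r in at}["C9"].flagged
        assert {r.cluster: r for r in above}["C9"].flagged

    def test_degenerate_scale_flags_nothing(self):
        scores = np.tile([0.1, 0.2, 0.3], 3)  # identical cluster medians
        clusters = np.repeat(["a", "b", "c"], 3)
        reports = flag_doublet_clusters(scores, clusters)
        assert all(r.degenerate_scale and not r.flagged for r in reports)

    def test_needs_three_clusters(self):
        with pytest.raises(ValueError, match="3 clusters"):
            flag_doublet_clusters(np.ones(4) * 0.1, np.repeat(["a", "b"], 2))
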