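"""QC filtering and the binary co-expression (phi) index."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenocell.coexpr import (
    ContingencyTable,
    coex_index,
    coex_matrix,
    contingency,
    qc_filter,
)
from phenocell.errors import DataValidationError

from conftest import make_counts
from oracles import phi_as_correlation


class TestQCFilter:
    def test_empty_cell_removed(self):
        dense = np.ones((5, 4), dtype=int)
        dense[:, 2] = 0
        ccm = make_counts(dense, ["c1"] * 4)
        out = qc_filter(ccm, min_genes_per_cell=1, min_cells_per_gene=1)
        assert len(out.cell_ids) == 3
        assert "cell2" not in out.cell_ids

    def test_identity_when_clean(self):
        rng = np.random.default_rng(0)
        dense = rng.poisson(3.0, size=(10, 8)) + 1  # every gene detected everywhere
        ccm = make_counts(dense, ["c1"] * 4 + ["c2"] * 4)
        out = qc_filter(ccm, min_genes_per_cell=5, min_cells_per_gene=2, outlier_mad_k=50)
        assert out.gene_ids == ccm.gene_ids
        assert out.cell_ids == ccm.cell_ids
        assert (out.counts != ccm.counts).nnz == 0

    def test_extreme_total_outlier_removed(self):
        # 10 cells; one with total count 50x the median is the only removal
        dense = np.full((20, 10), 2, dtype=int)
        dense[:, 7] = 100
        ccm = make_counts(dense, ["c1"] * 10)
        med = np.median(dense.sum(0))
        assert dense.sum(0)[7] == 50 * med
        out = qc_filter(ccm, min_genes_per_cell=1, min_cells_per_gene=1, outlier_mad_k=5)
        assert len(out.cell_ids) == 9
        assert "cell7" not in out.cell_ids

    def test_rare_gene_removed_after_cells(self):
        dense = np.ones((4, 6), dtype=int)
        dense[3, :] = 0
        dense[3, 0] = 5
        ccm = make_counts(dense, ["c1"] * 6)
        out = qc_filter(ccm, min_genes_per_cell=1, min_cells_per_gene=2)
        assert "g3" not in out.gene_ids

    def test_all_clusters_dropped_is_error(self):
        ccm = make_counts(np.ones((3, 2), dtype=int), ["c1", "c1"])
        with pytest.raises(DataValidationError, match="every cluster"):
            qc_filter(ccm, min_genes_per_cell=10, min_cells_per_gene=1)


class TestContingency:
    def test_manual_count(self):
        ccm = make_counts([[0, 1, 2, 0], [0, 3, 0, 0]], ["c1"] * 4)
        t = contingency(ccm, "c1", "g0", "g1")
        assert (t.o_yy, t.o_yn, t.o_ny, t.o_nn) == (1, 1, 0, 2)

    def test_silent_gene(self):
        ccm = make_counts([[0, 0, 0], [1, 0, 2]], ["c1"] * 3)
        t = contingency(ccm, "c1", "g0", "g1")
        assert t.o_yy == 0 and t.o_yn == 0

    def test_identical_pattern(self):
        ccm = make_counts([[1, 0, 2], [5, 0, 1]], ["c1"] * 3)
        t = contingency(ccm, "c1", "g0", "g1")
        assert t.o_yn == 0 and t.o_ny == 0

    def test_expr_threshold(self):
        ccm = make_counts([[1, 2], [2, 2]], ["c1"] * 2)
        t = contingency(ccm, "c1", "g0", "g1", expr_threshold=1)
        assert (t.o_yy, t.o_yn, t.o_ny, t.o_nn) == (1, 0, 1, 0)

    def test_unknown_ids(self):
        ccm = make_counts([[1], [1]], ["c1"])
        with pytest.raises(DataValidationError):
            contingency(ccm, "cX", "g0", "g1")
        with pytest.raises(DataValidationError):
            contingency(ccm, "c1", "g0", "gZ")


class TestCoexIndex:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((5, 0, 0, 5), 1.0),
            ((2, 2, 2, 2), 0.0),
            ((30, 10, 10, 50), 1400 / 2400),
            ((0, 5, 5, 0), -1.0),
            ((5, 5, 0, 0), 0.0),  # degenerate margin
        ],
    )
    def test_examples(self, table, expected):
        assert coex_index(ContingencyTable(*table)) == pytest.approx(expected, abs=1e-12)

    def test_empty_table_error(self):
        with pytest.raises(DataValidationError):
            coex_index(ContingencyTable(0, 0, 0, 0))

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(1, 30))
    def test_equals_binarized_correlation(self, yy, yn, ny, nn):
        t = ContingencyTable(yy, yn, ny, nn)
        a = np.array([1] * yy + [1] * yn + [0] * ny + [0] * nn)
        b = np.array([1] * yy + [0] * yn + [1] * ny + [0] * nn)
        assert coex_index(t) == pytest.approx(phi_as_correlation(a, b), abs=1e-10)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(1, 20))
    def test_label_swap_symmetries(self, yy, yn, ny, nn):
        t = ContingencyTable(yy, yn, ny, nn)
        both_swapped = ContingencyTable(nn, ny, yn, yy)
        one_swapped = ContingencyTable(yn, yy, nn, ny)
        assert coex_index(t) == pytest.approx(coex_index(both_swapped), abs=1e-12)
        assert coex_index(t) == pytest.approx(-coex_index(one_swapped), abs=1e-12)

    def test_range(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            t = ContingencyTable(*rng.integers(0, 40, size=4))
            if t.n:
                assert -1.0 <= coex_index(t) <= 1.0

    def test_null_mean_near_zero_under_independence(self):
        """Independent Bernoulli expression: mean index within 3 SE of 0."""
        rng = np.random.default_rng(77)
        n = 1000
        for p in np.arange(0.1, 0.95, 0.1):
            vals = []
            for _ in range(500):
                a = rng.random(n) < p
                b = rng.random(n) < p
                vals.append(
                    coex_index(
                        ContingencyTable(
                            int((a & b).sum()), int((a & ~b).sum()),
                            int((~a & b).sum()), int((~a & ~b).sum()),
                        )
                    )
                )
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean()) < 3 * se + 1e-12


class TestCoexMatrix:
    def test_matches_pairwise_index(self):
        rng = np.random.default_rng(12)
        dense = rng.poisson(0.8, size=(6, 30))
        ccm = make_counts(dense, ["c1"] * 30)
        cm = coex_matrix(ccm, "c1")
        for i, ga in enumerate(cm.gene_ids):
            for j, gb in enumerate(cm.gene_ids):
                if i < j:
                    expected = coex_index(contingency(ccm, "c1", ga, gb))
                    assert cm.coex[i, j] == pytest.approx(expected, abs=1e-10)
                    assert cm.coex[j, i] == cm.coex[i, j]

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(4)
        dense = rng.poisson(1.0, size=(5, 20))
        perm = rng.permutation(20)
        cm1 = coex_matrix(make_counts(dense, ["c1"] * 20), "c1")
        cm2 = coex_matrix(make_counts(dense[:, perm], ["c1"] * 20), "c1")
        np.testing.assert_allclose(cm1.coex, cm2.coex, atol=1e-12)

    def test_degenerate_rows_zeroed_and_flagged(self):
        dense = np.array([[1, 1, 1], [0, 0, 0], [1, 0, 1]])
        cm = coex_matrix(make_counts(dense, ["c1"] * 3), "c1")
        assert cm.degenerate[0] and cm.degenerate[1] and not cm.degenerate[2]
        assert np.all(cm.coex[0, 1:] == 0)

    def test_small_universe_error(self):
        ccm = make_counts([[1, 0], [0, 1]], ["c1"] * 2)
        with pytest.raises(DataValidationError, match="2 genes"):
            coex_matrix(ccm, "c1", gene_universe={"g0"})

    def test_pair_accessors(self):
        rng = np.random.default_rng(2)
        dense = rng.poisson(1.0, size=(8, 40))
        ccm = make_counts(dense, ["c1"] * 40)
        cm = coex_matrix(ccm, "c1")
        gs = {"g0", "g1", "g2"}
        assert cm.set_pair_values(gs).size <= 3
        bg = cm.background_pair_values(gs)
        n_all = 8 * 7 // 2
        assert bg.size <= n_all - 3
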