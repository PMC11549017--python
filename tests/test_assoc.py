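"""K-S scoring, BH correction, min-FDR aggregation, size-bias test."""

import numpy as np
import pandas as pd
import pytest

from phenocell.assoc import (
    aggregate_cell_types,
    apply_fdr,
    bh_fdr,
    coex_association,
    de_association,
    ks_greater,
    results_to_frame,
    size_bias_test,
)
from phenocell.coexpr import CoexMatrix
from phenocell.diffexpr import LogFCMatrix
from phenocell.errors import DataValidationError

from oracles import bh_stepup, ks_greater_perm_exact, ks_greater_perm_mc


def lfc_of(matrix, clusters=None):
    arr = np.asarray(matrix, dtype=float)
    clusters = clusters or [f"c{i}" for i in range(arr.shape[1])]
    return LogFCMatrix(
        gene_ids=[f"g{i}" for i in range(arr.shape[0])],
        cluster_ids=clusters,
        logfc=arr,
        log_base=2.0,
        pseudocount=1.0,
        scope="within_tissue",
        cluster_tissue={c: "t1" for c in clusters},
    )


class TestKSGreater:
    def test_identical_samples(self):
        x = np.arange(5.0)
        stat, p = ks_greater(x, x)
        assert stat == 0.0 and p == 1.0

    def test_disjoint_above(self):
        stat, p = ks_greater([4, 5, 6], [1, 2, 3])
        assert stat == 1.0
        assert p == pytest.approx(1 / 20)  # one of C(6,3) splits

    def test_disjoint_below(self):
        stat, _ = ks_greater([1, 2, 3], [4, 5, 6])
        assert stat == 0.0

    def test_empty_sample(self):
        with pytest.raises(DataValidationError):
            ks_greater([], [1.0])

    @pytest.mark.parametrize("m,n", [(2, 5), (3, 4), (4, 4), (5, 3)])
    def test_exact_p_matches_permutation_enumeration(self, m, n):
        rng = np.random.default_rng(m * 10 + n)
        s, b = rng.normal(size=m), rng.normal(size=n)
        stat, p = ks_greater(s, b)
        o_stat, o_p = ks_greater_perm_exact(s, b)
        assert stat == pytest.approx(o_stat, abs=1e-12)
        assert p == pytest.approx(o_p, abs=1e-9)


class TestDEAssociation:
    def test_flat_logfc_p_one(self):
        lfc = lfc_of(np.zeros((30, 1)))
        r = de_association(lfc, "c0", {"g0", "g1", "g2"})
        assert r.p_value == pytest.approx(1.0)

    def test_small_set_skipped(self):
        lfc = lfc_of(np.zeros((30, 1)))
        r = de_association(lfc, "c0", {"g0", "gene_not_measured"})
        assert r.skipped_reason == "insufficient_genes"
        assert np.isnan(r.p_value)

    def test_planted_shift_detected_and_oracle_agrees(self):
        rng = np.random.default_rng(101)
        vals = rng.normal(0, 0.5, size=1030)
        vals[:30] += 2.0
        lfc = lfc_of(vals[:, None])
        gene_set = {f"g{i}" for i in range(30)}
        r = de_association(lfc, "c0", gene_set)
        assert r.p_value < 1e-6
        p_perm = ks_greater_perm_mc(vals[:30], vals[30:], n_perm=2000, rng=rng)
        assert p_perm <= 1 / 1000  # no permutation reached the observed stat

    def test_negative_shift_near_one(self):
        rng = np.random.default_rng(102)
        vals = rng.normal(0, 0.5, size=1030)
        vals[:30] -= 2.0
        lfc = lfc_of(vals[:, None])
        r = de_association(lfc, "c0", {f"g{i}" for i in range(30)})
        assert r.p_value > 0.99


def coex_of(phi, degenerate=None):
    phi = np.asarray(phi, dtype=float)
    n = phi.shape[0]
    return CoexMatrix(
        gene_ids=[f"g{i}" for i in range(n)],
        coex=phi,
        degenerate=degenerate if degenerate is not None else np.zeros(n, dtype=bool),
        cluster_id="c0",
        n_cells=100,
    )


class TestCoexAssociation:
    def _random_coex(self, rng, n, hot=None, strength=0.6):
        phi = rng.normal(0, 0.05, size=(n, n))
        phi = (phi + phi.T) / 2
        if hot:
            for i in hot:
                for j in hot:
                    if i != j:
                        phi[i, j] = strength + rng.normal(0, 0.05)
        np.fill_diagonal(phi, 1.0)
        return coex_of((phi + phi.T) / 2)

    def test_planted_module_detected(self):
        rng = np.random.default_rng(5)
        cm = self._random_coex(rng, 60, hot=range(10))
        r = coex_association(cm, {f"g{i}" for i in range(10)})
        assert r.p_value < 1e-6

    def test_null_module_oracle_agreement(self):
        rng = np.random.default_rng(6)
        cm = self._random_coex(rng, 40)
        gs = {f"g{i}" for i in range(8)}
        r = coex_association(cm, gs)
        set_vals = np.abs(cm.set_pair_values(gs))
        bg_vals = np.abs(cm.background_pair_values(gs))
        p_perm = ks_greater_perm_mc(set_vals, bg_vals, n_perm=500, rng=rng)
        # asymptotic and permutation p agree on order of magnitude
        assert (r.p_value < 0.05) == (p_perm < 0.05) or abs(r.p_value - p_perm) < 0.1

    def test_degenerate_pair_skipped(self):
        phi = np.zeros((4, 4))
        cm = coex_of(phi, degenerate=np.array([False, True, False, False]))
        r = coex_association(cm, {"g0", "g1"}, min_pair_count=1)
        assert r.skipped_reason == "insufficient_pairs"

    def test_two_sided_mode(self):
        rng = np.random.default_rng(8)
        cm = self._random_coex(rng, 50, hot=range(8), strength=-0.6)
        r_abs = coex_association(cm, {f"g{i}" for i in range(8)}, mode="abs_greater")
        r_two = coex_association(cm, {f"g{i}" for i in range(8)}, mode="two_sided")
        assert r_abs.p_value < 1e-4  # negative modules are "extreme" too
        assert r_two.p_value < 1e-4


class TestBHFDR:
    def test_examples(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range(self):
        with pytest.raises(DataValidationError):
            bh_fdr([0.5, 1.5])

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_stepup(p), atol=1e-12)

    def test_family_scoping(self):
        rows = []
        for tissue, p in [("t1", 0.01), ("t1", 0.04), ("t2", 0.01)]:
            rows.append(
                dict.fromkeys(
                    ["phenotype_id", "phenotype_name", "cluster_id", "cell_type"], "x"
                )
                | {"tissue": tissue, "metric": "diffexpr", "n_set": 5,
                   "n_background": 50, "ks_stat": 0.5, "p_value": p, "fdr": np.nan,
                   "skipped_reason": ""}
            )
        df = pd.DataFrame(rows)
        per_tissue = apply_fdr(df, family="per_tissue")
        glob = apply_fdr(df, family="global")
        # t2's single test is unadjusted per-tissue but shares m=3 globally
        assert per_tissue.loc[2, "fdr"] == pytest.approx(0.01)
        assert glob.loc[2, "fdr"] == pytest.approx(0.015)


class TestAggregation:
    def _results(self, fdrs, cell_types=None):
        rows = []
        for i, f in enumerate(fdrs):
            rows.append(
                {
                    "tissue": "t1", "phenotype_id": "HP:1", "phenotype_name": "p",
                    "cluster_id": f"c{i}",
                    "cell_type": (cell_types or ["hepatocyte"] * len(fdrs))[i],
                    "metric": "diffexpr", "n_set": 10, "n_background": 100,
                    "ks_stat": 0.5, "p_value": f, "fdr": f, "skipped_reason": "",
                }
            )
        return pd.DataFrame(rows)

    def test_min_fdr_and_significance(self):
        calls = aggregate_cell_types(self._results([0.5, 0.0002, 0.9]), 0.001)
        assert len(calls) == 1
        assert calls.loc[0, "min_fdr"] == pytest.approx(0.0002)
        assert bool(calls.loc[0, "significant"])

    def test_single_cluster_identity(self):
        calls = aggregate_cell_types(self._results([0.42]), 0.001)
        assert calls.loc[0, "min_fdr"] == pytest.approx(0.42)
        assert not bool(calls.loc[0, "significant"])

    def test_adding_cluster_never_raises_min(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            fdrs = list(rng.random(rng.integers(1, 6)))
            before = aggregate_cell_types(self._results(fdrs), 0.001).loc[0, "min_fdr"]
            after = aggregate_cell_types(
                self._results(fdrs + [float(rng.random())]), 0.001
            ).loc[0, "min_fdr"]
            assert after <= before + 1e-15

    def test_skipped_rows_excluded(self):
        df = self._results([0.9, 0.1])
        df.loc[1, "skipped_reason"] = "insufficient_genes"
        calls = aggregate_cell_types(df, 0.001)
        assert calls.loc[0, "min_fdr"] == pytest.approx(0.9)


class TestSizeBias:
    def test_identical_samples(self):
        p = size_bias_test([30, 40, 50, 60], [30, 40, 50, 60])
        assert p > 0.8

    def test_separated_sizes(self):
        assert size_bias_test(range(100, 131), range(20, 51)) < 0.001

    def test_single_elements(self):
        assert 0 <= size_bias_test([5], [30]) <= 1


def test_results_round_trip_columns():
    from phenocell.assoc import AssociationResult

    df = results_to_frame([AssociationResult(tissue="t", metric="diffexpr")])
    assert list(df.columns)[:3] == ["tissue", "phenotype_id", "phenotype_name"]
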