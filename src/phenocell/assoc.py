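"""Set-vs-background K-S scoring, FDR correction, cell-type calls.

For each (phenotype, cluster) pair two one-sided two-sample
Kolmogorov-Smirnov tests ask whether the phenotype's genes sit higher
than the rest of the transcriptome: on the differential-expression side
the samples are logFC values (set genes vs all other measured genes in
the cluster); on the co-expression side they are pairwise phi values
(within-set pairs vs the remaining pairs), taken in absolute value by
default so that "extreme" co-expression of either sign scores.  P-values
are Benjamini-Hochberg adjusted per tissue and metric, clusters sharing
a cell-type annotation are collapsed by minimum FDR, and a cell type is
called associated when that minimum FDR clears the threshold
(default < .001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpr import CoexMatrix
from .diffexpr import LogFCMatrix
from .errors import DataValidationError

DEFAULT_FDR_THRESHOLD = 1e-3
DEFAULT_MIN_SET_SIZE = 3
DEFAULT_MIN_PAIR_COUNT = 3
EXACT_MAX_SET = 10

RESULT_COLUMNS = [
    "tissue",
    "phenotype_id",
    "phenotype_name",
    "cluster_id",
    "cell_type",
    "metric",
    "n_set",
    "n_background",
    "ks_stat",
    "p_value",
    "fdr",
    "skipped_reason",
]


@dataclass
class AssociationResult:
    tissue: str = ""
    phenotype_id: str = ""
    phenotype_name: str = ""
    cluster_id: str = ""
    cell_type: str = ""
    metric: str = ""
    n_set: int = 0
    n_background: int = 0
    ks_stat: float = float("nan")
    p_value: float = float("nan")
    fdr: float = float("nan")
    skipped_reason: str = ""

    @property
    def skipped(self) -> bool:
        return bool(self.skipped_reason)


@dataclass
class CellTypeCall:
    tissue: str
    phenotype_id: str
    cell_type: str
    metric: str
    min_fdr: float
    significant: bool


# ---------------------------------------------------------------------------
# K-S
# ---------------------------------------------------------------------------


def ks_greater(
    set_values: np.ndarray, background_values: np.ndarray, exact_max_set: int = EXACT_MAX_SET
) -> tuple[float, float]:
    """One-sided two-sample K-S: is the set stochastically greater?

    The statistic is max(F_background - F_set); p-values are asymptotic,
    switching to the exact conditional distribution when the set sample
    is small (n_set <= ``exact_max_set``).
    """
    s = np.asarray(set_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if s.size == 0 or b.size == 0:
        raise DataValidationError("K-S test requires non-empty samples")
    method = "exact" if s.size <= exact_max_set else "asymp"
    res = stats.ks_2samp(s, b, alternative="less", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def ks_two_sided(set_values: np.ndarray, background_values: np.ndarray) -> tuple[float, float]:
    s = np.asarray(set_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if s.size == 0 or b.size == 0:
        raise DataValidationError("K-S test requires non-empty samples")
    res = stats.ks_2samp(s, b, alternative="two-sided")
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# per-pair associations (p-value stage)
# ---------------------------------------------------------------------------


def de_association(
    logfc: LogFCMatrix,
    cluster: str,
    gene_set: set[str],
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> AssociationResult:
    """K-S of set logFC vs the rest of the measured genes, one cluster."""
    col = logfc.column(cluster)
    in_set = np.asarray([g in gene_set for g in logfc.gene_ids])
    n_set = int(in_set.sum())
    res = AssociationResult(cluster_id=cluster, metric="diffexpr", n_set=n_set,
                            n_background=int((~in_set).sum()))
    if n_set < min_set_size:
        res.skipped_reason = "insufficient_genes"
        return res
    stat, p = ks_greater(col[in_set], col[~in_set])
    res.ks_stat, res.p_value = stat, p
    return res


def coex_association(
    coex: CoexMatrix,
    gene_set: set[str],
    mode: str = "abs_greater",
    min_pair_count: int = DEFAULT_MIN_PAIR_COUNT,
    include_mixed: bool = True,
    bg_sample: int | None = None,
    rng: np.random.Generator | None = None,
) -> AssociationResult:
    """K-S of within-set phi values vs the remaining pairs."""
    set_vals = coex.set_pair_values(gene_set)
    bg_vals = coex.background_pair_values(
        gene_set, include_mixed=include_mixed, sample=bg_sample, rng=rng
    )
    return _coex_core(set_vals, bg_vals, mode, min_pair_count, coex.cluster_id)


def coex_association_from_pairs(
    pairs: pd.DataFrame,
    gene_set: set[str],
    mode: str = "abs_greater",
    min_pair_count: int = DEFAULT_MIN_PAIR_COUNT,
    include_mixed: bool = True,
    cluster_id: str = "",
) -> AssociationResult:
    """Same test from a long-format (gene_a, gene_b, coex_phi) table."""
    ok = pairs["degenerate_flag"] == 0
    a_in = pairs["gene_a"].isin(gene_set)
    b_in = pairs["gene_b"].isin(gene_set)
    both = a_in & b_in
    set_vals = pairs.loc[ok & both, "coex_phi"].to_numpy()
    bg_mask = ok & ~both
    if not include_mixed:
        bg_mask &= ~(a_in | b_in)
    bg_vals = pairs.loc[bg_mask, "coex_phi"].to_numpy()
    return _coex_core(set_vals, bg_vals, mode, min_pair_count, cluster_id)


def _coex_core(
    set_vals: np.ndarray,
    bg_vals: np.ndarray,
    mode: str,
    min_pair_count: int,
    cluster_id: str,
) -> AssociationResult:
    if mode not in ("abs_greater", "two_sided"):
        raise DataValidationError(f"unknown coexpr mode {mode!r}")
    res = AssociationResult(cluster_id=cluster_id, metric="coexpr",
                            n_set=int(set_vals.size), n_background=int(bg_vals.size))
    if set_vals.size < min_pair_count:
        res.skipped_reason = "insufficient_pairs"
        return res
    if bg_vals.size == 0:
        res.skipped_reason = "no_background_pairs"
        return res
    if mode == "abs_greater":
        stat, p = ks_greater(np.abs(set_vals), np.abs(bg_vals))
    else:
        stat, p = ks_two_sided(set_vals, bg_vals)
    res.ks_stat, res.p_value = stat, p
    return res


# ---------------------------------------------------------------------------
# multiple testing and aggregation
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: pd.DataFrame, family: str = "per_tissue") -> pd.DataFrame:
    """Attach BH-adjusted FDR to a results table.

    ``family`` groups the correction: ``per_tissue`` adjusts within each
    tissue x metric family (skipped tests excluded); ``global`` adjusts
    per metric over everything.
    """
    if family not in ("per_tissue", "global"):
        raise DataValidationError(f"unknown FDR family {family!r}")
    out = results.copy()
    out["fdr"] = np.nan
    tested = out["skipped_reason"].fillna("") == ""
    keys = ["tissue", "metric"] if family == "per_tissue" else ["metric"]
    for _, idx in out.loc[tested].groupby(keys, sort=False).groups.items():
        out.loc[idx, "fdr"] = bh_fdr(out.loc[idx, "p_value"].to_numpy())
    return out


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results], columns=RESULT_COLUMNS)


def aggregate_cell_types(
    results: pd.DataFrame, fdr_threshold: float = DEFAULT_FDR_THRESHOLD
) -> pd.DataFrame:
    """Collapse cluster-level FDRs to per-cell-type minimum-FDR calls."""
    tested = results.loc[results["skipped_reason"].fillna("") == ""].copy()
    if tested.empty:
        return pd.DataFrame(
            columns=["tissue", "phenotype_id", "cell_type", "metric", "min_fdr", "significant"]
        )
    grouped = (
        tested.groupby(["tissue", "phenotype_id", "cell_type", "metric"], sort=False)["fdr"]
        .min()
        .reset_index()
        .rename(columns={"fdr": "min_fdr"})
    )
    grouped["significant"] = grouped["min_fdr"] < fdr_threshold
    return grouped


def size_bias_test(sizes_significant, sizes_nonsignificant) -> float:
    """Two-sided Mann-Whitney U p-value comparing phenotype-size samples."""
    a = np.asarray(sizes_significant, dtype=float)
    b = np.asarray(sizes_nonsignificant, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataValidationError("size-bias test requires non-empty samples")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
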