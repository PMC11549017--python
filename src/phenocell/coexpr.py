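"""Per-cluster QC and binary co-expression from 2x2 contingency tables.

A cell "expresses" a gene when its count exceeds a threshold (default:
any nonzero count).  For a gene pair within one cluster the 2x2 table
counts cells expressing both, only the first, only the second, or
neither; the co-expression index is the phi coefficient of that table —
the deviation of joint expression from independence, ranging over
[-1, 1] and equal to the Pearson correlation of the two binarized
vectors.  Pairs with a degenerate margin (a gene expressed in no cell or
every cell) get index 0 and are flagged, since no association is
estimable there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DataValidationError
from .io import CellCountMatrix

DEFAULT_MIN_GENES_PER_CELL = 200
DEFAULT_MIN_CELLS_PER_GENE = 3
DEFAULT_OUTLIER_MAD_K = 5.0


@dataclass
class ContingencyTable:
    o_yy: int
    o_yn: int
    o_ny: int
    o_nn: int

    @property
    def n(self) -> int:
        return self.o_yy + self.o_yn + self.o_ny + self.o_nn


@dataclass
class CoexMatrix:
    """Symmetric gene x gene phi matrix for one cluster."""

    gene_ids: list[str]
    coex: np.ndarray
    degenerate: np.ndarray  # per-gene flag: margin was 0 or n
    cluster_id: str
    n_cells: int

    def _indices(self, genes: set[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        return np.asarray(sorted(pos[g] for g in genes if g in pos), dtype=int)

    def set_pair_values(self, gene_set: set[str]) -> np.ndarray:
        """Values of non-degenerate pairs with both genes in the set."""
        idx = self._indices(gene_set)
        ok = idx[~self.degenerate[idx]]
        if ok.size < 2:
            return np.empty(0)
        sub = self.coex[np.ix_(ok, ok)]
        iu = np.triu_indices(ok.size, k=1)
        return sub[iu]

    def background_pair_values(
        self,
        gene_set: set[str],
        include_mixed: bool = True,
        sample: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Values of all other non-degenerate pairs.

        With ``include_mixed`` pairs with exactly one endpoint in the set
        count as background; otherwise only set-free pairs do.  ``sample``
        optionally subsamples (seeded ``rng`` required) for tractability.
        """
        n = len(self.gene_ids)
        in_set = np.zeros(n, dtype=bool)
        in_set[self._indices(gene_set)] = True
        ok = ~self.degenerate
        iu, ju = np.triu_indices(n, k=1)
        both = in_set[iu] & in_set[ju]
        valid = ok[iu] & ok[ju] & ~both
        if not include_mixed:
            valid &= ~(in_set[iu] | in_set[ju])
        vals = self.coex[iu[valid], ju[valid]]
        if sample is not None and vals.size > sample:
            if rng is None:
                raise DataValidationError("background subsampling requires an rng")
            vals = rng.choice(vals, size=sample, replace=False)
        return vals

    def to_pairs_frame(
        self,
        keep_genes: set[str] | None = None,
        bg_pair_sample: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> pd.DataFrame:
        """Long-format (gene_a, gene_b, coex_phi, degenerate_flag) table.

        With ``keep_genes`` all pairs among those genes are kept and the
        remaining pairs are subsampled to ``bg_pair_sample`` rows.
        """
        n = len(self.gene_ids)
        iu, ju = np.triu_indices(n, k=1)
        if keep_genes is not None:
            in_keep = np.zeros(n, dtype=bool)
            in_keep[self._indices(keep_genes)] = True
            is_kept = in_keep[iu] & in_keep[ju]
            sel = np.nonzero(is_kept)[0]
            rest = np.nonzero(~is_kept)[0]
            if bg_pair_sample is not None and rest.size > bg_pair_sample:
                if rng is None:
                    raise DataValidationError("background subsampling requires an rng")
                rest = np.sort(rng.choice(rest, size=bg_pair_sample, replace=False))
            sel = np.concatenate([sel, rest])
            sel.sort()
            iu, ju = iu[sel], ju[sel]
        genes = np.asarray(self.gene_ids)
        return pd.DataFrame(
            {
                "gene_a": genes[iu],
                "gene_b": genes[ju],
                "coex_phi": self.coex[iu, ju],
                "degenerate_flag": (self.degenerate[iu] | self.degenerate[ju]).astype(int),
            }
        )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    counts: CellCountMatrix,
    min_genes_per_cell: int = DEFAULT_MIN_GENES_PER_CELL,
    min_cells_per_gene: int = DEFAULT_MIN_CELLS_PER_GENE,
    outlier_mad_k: float = DEFAULT_OUTLIER_MAD_K,
) -> CellCountMatrix:
    """Remove low-coverage cells, within-cluster count outliers, rare genes.

    Cells detecting fewer than ``min_genes_per_cell`` genes go first; then,
    within each cluster, cells whose total count exceeds
    median + ``outlier_mad_k`` * MAD of the cluster's totals; finally genes
    detected in fewer than ``min_cells_per_gene`` remaining cells.  Clusters
    left with fewer than 2 cells are dropped (all dropped is a hard error).
    """
    if min_genes_per_cell < 1 or min_cells_per_gene < 1 or outlier_mad_k <= 0:
        raise DataValidationError("QC thresholds must be >= 1 (and MAD k > 0)")
    X = sp.csc_matrix(counts.counts)
    detected = np.asarray((X > 0).sum(axis=0)).ravel()
    totals = np.asarray(X.sum(axis=0)).ravel()
    keep_cell = detected >= min_genes_per_cell

    for cl in counts.cluster_ids:
        idx = counts.cell_indices_of_cluster(cl)
        idx = idx[keep_cell[idx]]
        if idx.size == 0:
            continue
        t = totals[idx]
        med = np.median(t)
        mad = np.median(np.abs(t - med))
        keep_cell[idx[t > med + outlier_mad_k * mad]] = False

    # drop clusters reduced below 2 cells
    for cl in counts.cluster_ids:
        idx = counts.cell_indices_of_cluster(cl)
        if keep_cell[idx].sum() < 2:
            keep_cell[idx] = False
    cell_idx = np.nonzero(keep_cell)[0]
    if cell_idx.size == 0:
        raise DataValidationError("QC removed every cluster")

    sub = sp.csr_matrix(X[:, cell_idx])
    gene_det = np.asarray((sub > 0).sum(axis=1)).ravel()
    gene_idx = np.nonzero(gene_det >= min_cells_per_gene)[0]

    cell_ids = [counts.cell_ids[i] for i in cell_idx]
    clusters_left = {counts.cell_cluster[c] for c in cell_ids}
    return CellCountMatrix(
        gene_ids=[counts.gene_ids[i] for i in gene_idx],
        cell_ids=cell_ids,
        counts=sub[gene_idx, :],
        cell_cluster={c: counts.cell_cluster[c] for c in cell_ids},
        cluster_celltype={c: counts.cluster_celltype[c] for c in clusters_left},
        cluster_tissue={c: counts.cluster_tissue[c] for c in clusters_left},
    )


# ---------------------------------------------------------------------------
# contingency and phi
# ---------------------------------------------------------------------------


def contingency(
    counts: CellCountMatrix,
    cluster: str,
    gene_a: str,
    gene_b: str,
    expr_threshold: int = 0,
) -> ContingencyTable:
    """2x2 expressed/not table for two genes over one cluster's cells."""
    if cluster not in counts.cluster_celltype:
        raise DataValidationError(f"unknown cluster {cluster!r}")
    idx = counts.cell_indices_of_cluster(cluster)
    if idx.size == 0:
        raise DataValidationError(f"cluster {cluster!r} has no cells")
    ia, ib = counts.gene_index(gene_a), counts.gene_index(gene_b)
    a = np.asarray(counts.counts[ia, idx].todense()).ravel() > expr_threshold
    b = np.asarray(counts.counts[ib, idx].todense()).ravel() > expr_threshold
    return ContingencyTable(
        o_yy=int((a & b).sum()),
        o_yn=int((a & ~b).sum()),
        o_ny=int((~a & b).sum()),
        o_nn=int((~a & ~b).sum()),
    )


def coex_index(table: ContingencyTable) -> float:
    """Phi coefficient of a 2x2 table; 0 by convention on a zero margin."""
    if table.n == 0:
        raise DataValidationError("empty contingency table")
    r1 = table.o_yy + table.o_yn
    r0 = table.o_ny + table.o_nn
    c1 = table.o_yy + table.o_ny
    c0 = table.o_yn + table.o_nn
    denom = float(r1) * r0 * c1 * c0
    if denom == 0:
        return 0.0
    return (table.o_yy * table.o_nn - table.o_yn * table.o_ny) / np.sqrt(denom)


def coex_matrix(
    counts: CellCountMatrix,
    cluster: str,
    gene_universe: set[str] | None = None,
    expr_threshold: int = 0,
) -> CoexMatrix:
    """All-pairs phi over a gene universe within one cluster.

    Vectorized: with binarized matrix B (genes x cells), joint counts are
    B B^T and phi follows from the margins.
    """
    if cluster not in counts.cluster_celltype:
        raise DataValidationError(f"unknown cluster {cluster!r}")
    if gene_universe is None:
        genes = list(counts.gene_ids)
    else:
        unknown = gene_universe - set(counts.gene_ids)
        if unknown:
            raise DataValidationError(f"genes not measured: {sorted(unknown)[:5]}")
        genes = [g for g in counts.gene_ids if g in gene_universe]
    if len(genes) < 2:
        raise DataValidationError("gene universe must contain at least 2 genes")
    idx = counts.cell_indices_of_cluster(cluster)
    if idx.size == 0:
        raise DataValidationError(f"cluster {cluster!r} has no cells")
    gidx = [counts.gene_ids.index(g) for g in genes]
    B = (counts.counts[gidx, :][:, idx].toarray() > expr_threshold).astype(np.float64)
    n = idx.size
    s = B.sum(axis=1)
    joint = B @ B.T
    num = n * joint - np.outer(s, s)
    var = s * (n - s)
    denom = np.sqrt(np.outer(var, var))
    degenerate = var == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    phi[degenerate, :] = 0.0
    phi[:, degenerate] = 0.0
    np.fill_diagonal(phi, 1.0)
    return CoexMatrix(
        gene_ids=genes,
        coex=phi,
        degenerate=degenerate,
        cluster_id=cluster,
        n_cells=int(n),
    )


def write_coex_pairs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_coex_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
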