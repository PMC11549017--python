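"""Readers and writers for the external formats the pipeline touches.

Single-cell counts travel as a Matrix Market coordinate file (genes as
rows, cells as columns) next to three TSVs: ``genes.tsv`` (gene_id),
``cells.tsv`` (cell_id, cluster_id) and ``clusters.tsv`` (cluster_id,
cell_type, tissue).  Ontologies are OBO 1.2 text; only ``[Term]`` stanzas
and their ``id``, ``name``, ``is_a`` and ``is_obsolete`` tags are
interpreted.  Phenotype-gene annotations follow the HPO
``phenotype_to_genes.txt`` dialect (tab-separated, extra columns ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import DataValidationError

logger = logging.getLogger(__name__)

TPM_TOTAL = 1e6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CellCountMatrix:
    """Genes x cells integer counts with cluster / cell-type / tissue maps.

    ``counts`` is kept as CSR; rows are genes, columns are cells.  Every
    cell belongs to exactly one cluster, every cluster to exactly one
    cell type and tissue.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix
    cell_cluster: dict[str, str]
    cluster_celltype: dict[str, str]
    cluster_tissue: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise DataValidationError(
                f"count matrix has {n_genes} rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise DataValidationError(
                f"count matrix has {n_cells} columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise DataValidationError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise DataValidationError("cell_ids are not unique")
        data = self.counts.data
        if data.size:
            if (data < 0).any():
                raise DataValidationError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise DataValidationError("non-integer count entry")
        missing = [c for c in self.cell_ids if c not in self.cell_cluster]
        if missing:
            raise DataValidationError(f"cells without cluster assignment: {missing[:5]}")
        for cl in set(self.cell_cluster.values()):
            if cl not in self.cluster_celltype:
                raise DataValidationError(f"cluster {cl!r} has no cell-type annotation")
            if cl not in self.cluster_tissue:
                raise DataValidationError(f"cluster {cl!r} has no tissue annotation")

    # -- convenience -------------------------------------------------------

    @property
    def cluster_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.cell_ids:
            seen.setdefault(self.cell_cluster[c], None)
        return list(seen)

    def cell_indices_of_cluster(self, cluster: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.cell_ids) if self.cell_cluster[c] == cluster]
        return np.asarray(idx, dtype=int)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise DataValidationError(f"unknown gene {gene!r}") from None


@dataclass
class ClusterTPMMatrix:
    """Genes x clusters TPM table (each column sums to 1e6)."""

    gene_ids: list[str]
    cluster_ids: list[str]
    tpm: np.ndarray
    cluster_tissue: dict[str, str]

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.gene_ids), len(self.cluster_ids)):
            raise DataValidationError(
                f"TPM matrix shape {self.tpm.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cluster_ids)} clusters"
            )
        if (self.tpm < 0).any():
            raise DataValidationError("negative TPM value")
        colsums = self.tpm.sum(axis=0)
        bad = [
            self.cluster_ids[j]
            for j in range(len(self.cluster_ids))
            if colsums[j] > 0 and abs(colsums[j] - TPM_TOTAL) / TPM_TOTAL > 1e-6
        ]
        if bad:
            logger.warning("TPM columns not summing to 1e6: %s", bad[:5])


@dataclass
class PhenotypeAnnotation:
    """Deduplicated (phenotype_id, phenotype_name, gene_id) records."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def genes_of(self, phenotype_id: str) -> set[str]:
        return {g for p, _, g in self.records if p == phenotype_id}

    @property
    def phenotype_names(self) -> dict[str, str]:
        return {p: n for p, n, _ in self.records}

    def by_phenotype(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for p, _, g in self.records:
            out.setdefault(p, set()).add(g)
        return out


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _default_genes_path(matrix_path: Path) -> Path:
    return matrix_path.with_name("genes.tsv")


def read_counts(
    matrix_path: str | Path,
    cells_meta_path: str | Path,
    clusters_meta_path: str | Path,
    genes_path: str | Path | None = None,
) -> CellCountMatrix:
    """Load a Matrix Market counts file plus its metadata TSVs.

    Genes are rows.  ``genes_path`` defaults to ``genes.tsv`` next to the
    matrix file.
    """
    matrix_path = Path(matrix_path)
    mat = mmread(str(matrix_path))
    mat = sp.csr_matrix(mat)
    if genes_path is None:
        genes_path = _default_genes_path(matrix_path)
    genes = pd.read_csv(genes_path, sep="\t")
    _require_columns(genes, ["gene_id"], genes_path)
    cells = pd.read_csv(cells_meta_path, sep="\t", dtype=str)
    _require_columns(cells, ["cell_id", "cluster_id"], cells_meta_path)
    clusters = pd.read_csv(clusters_meta_path, sep="\t", dtype=str)
    _require_columns(clusters, ["cluster_id", "cell_type", "tissue"], clusters_meta_path)

    n_genes, n_cells = mat.shape
    if len(genes) != n_genes:
        raise DataValidationError(
            f"matrix has {n_genes} gene rows but gene metadata has {len(genes)} rows"
        )
    if len(cells) != n_cells:
        raise DataValidationError(
            f"matrix has {n_cells} cell columns but cell metadata has {len(cells)} rows"
        )
    known = set(clusters["cluster_id"])
    unknown = sorted(set(cells["cluster_id"]) - known)
    if unknown:
        raise DataValidationError(f"cells assigned to unknown clusters: {unknown[:5]}")
    return CellCountMatrix(
        gene_ids=[str(g) for g in genes["gene_id"]],
        cell_ids=list(cells["cell_id"]),
        counts=mat,
        cell_cluster=dict(zip(cells["cell_id"], cells["cluster_id"])),
        cluster_celltype=dict(zip(clusters["cluster_id"], clusters["cell_type"])),
        cluster_tissue=dict(zip(clusters["cluster_id"], clusters["tissue"])),
    )


def write_counts(
    ccm: CellCountMatrix,
    matrix_path: str | Path,
    cells_meta_path: str | Path,
    clusters_meta_path: str | Path,
    genes_path: str | Path | None = None,
) -> None:
    matrix_path = Path(matrix_path)
    mmwrite(str(matrix_path), sp.coo_matrix(ccm.counts), field="integer")
    if genes_path is None:
        genes_path = _default_genes_path(matrix_path)
    pd.DataFrame({"gene_id": ccm.gene_ids}).to_csv(genes_path, sep="\t", index=False)
    pd.DataFrame(
        {"cell_id": ccm.cell_ids, "cluster_id": [ccm.cell_cluster[c] for c in ccm.cell_ids]}
    ).to_csv(cells_meta_path, sep="\t", index=False)
    cl = ccm.cluster_ids
    pd.DataFrame(
        {
            "cluster_id": cl,
            "cell_type": [ccm.cluster_celltype[c] for c in cl],
            "tissue": [ccm.cluster_tissue[c] for c in cl],
        }
    ).to_csv(clusters_meta_path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# cluster TPM
# ---------------------------------------------------------------------------


def read_cluster_tpm(
    path: str | Path, tissue_path: str | Path | None = None
) -> ClusterTPMMatrix:
    """Read a gene x cluster TPM TSV (gene_id column first).

    ``tissue_path`` is an optional cluster_id/tissue TSV; without it every
    cluster gets an empty tissue label.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["gene_id"], path)
    gene_ids = list(df["gene_id"])
    if len(set(gene_ids)) != len(gene_ids):
        dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
        raise DataValidationError(f"{path}: duplicate gene_id {dupes[:5]}")
    cluster_ids = [c for c in df.columns if c != "gene_id"]
    values = np.empty((len(gene_ids), len(cluster_ids)))
    for j, c in enumerate(cluster_ids):
        col = pd.to_numeric(df[c], errors="coerce")
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise DataValidationError(
                f"{path}: non-numeric value at gene {gene_ids[i]!r}, cluster {c!r}"
            )
        values[:, j] = col.to_numpy()
    if tissue_path is not None:
        tdf = pd.read_csv(tissue_path, sep="\t", dtype=str)
        _require_columns(tdf, ["cluster_id", "tissue"], tissue_path)
        tissue = dict(zip(tdf["cluster_id"], tdf["tissue"]))
    else:
        tissue = {c: "" for c in cluster_ids}
    return ClusterTPMMatrix(gene_ids, cluster_ids, values, tissue)


def write_cluster_tpm(
    tpm: ClusterTPMMatrix, path: str | Path, tissue_path: str | Path | None = None
) -> None:
    df = pd.DataFrame(tpm.tpm, columns=tpm.cluster_ids)
    df.insert(0, "gene_id", tpm.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if tissue_path is not None:
        pd.DataFrame(
            {
                "cluster_id": tpm.cluster_ids,
                "tissue": [tpm.cluster_tissue.get(c, "") for c in tpm.cluster_ids],
            }
        ).to_csv(tissue_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ontologies
# ---------------------------------------------------------------------------


def read_obo(path: str | Path) -> nx.DiGraph:
    """Parse an OBO 1.2 file into a child->parent is_a DiGraph.

    Obsolete terms are dropped.  ``is_a`` references to undeclared ids keep
    the edge and create a node with an empty name (warned).  A cyclic
    is_a structure is a hard error.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=True)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        name = data.get("name")
        if name is None:
            logger.warning("OBO term %s referenced but not defined; empty name", node)
            name = ""
        g.add_node(node, name=name)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise DataValidationError(f"is_a cycle detected: {cycle}")
    return g


def write_obo(graph: nx.DiGraph, path: str | Path, ontology_name: str = "synthetic") -> None:
    """Serialize a child->parent DiGraph back to minimal OBO 1.2 text."""
    lines = [f"format-version: 1.2", f"ontology: {ontology_name}", ""]
    for node in sorted(graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {node}")
        lines.append(f"name: {graph.nodes[node].get('name', '')}")
        for parent in sorted(graph.successors(node)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# phenotype annotations
# ---------------------------------------------------------------------------


def read_phenotype_annotations(path: str | Path) -> PhenotypeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ["phenotype_id", "phenotype_name", "gene_id"], path)
    seen: set[tuple[str, str]] = set()
    records = []
    for p, n, g in zip(df["phenotype_id"], df["phenotype_name"], df["gene_id"]):
        if (p, g) not in seen:
            seen.add((p, g))
            records.append((p, n, g))
    return PhenotypeAnnotation(records)


def write_phenotype_annotations(ann: PhenotypeAnnotation, path: str | Path) -> None:
    pd.DataFrame(ann.records, columns=["phenotype_id", "phenotype_name", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_links(path: str | Path) -> set[tuple[str, str]]:
    """Anatomy->phenotype cross-link TSV (anatomy_id, phenotype_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["anatomy_id", "phenotype_id"], path)
    return set(zip(df["anatomy_id"], df["phenotype_id"]))


def write_links(links: set[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(sorted(links), columns=["anatomy_id", "phenotype_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_tissue_anchors(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["tissue", "anatomy_id"], path)
    return dict(zip(df["tissue"], df["anatomy_id"]))


def write_tissue_anchors(anchors: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(anchors.items()), columns=["tissue", "anatomy_id"]).to_csv(
        path, sep="\t", index=False
    )
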