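"""Cluster-level TPM aggregation and log fold change.

Counts are pooled over all cells of a cluster (pseudobulk) and scaled to
transcripts per million, so each cluster column sums to 1e6.  The log
fold change of a gene in a cluster compares its TPM against the mean TPM
over the remaining clusters of the background scope (the same tissue by
default), with a pseudocount keeping zeros finite:

    logFC[g, c] = log_b( (TPM[g, c] + eps) / (mean_{c' != c} TPM[g, c'] + eps) )
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError
from .io import TPM_TOTAL, CellCountMatrix, ClusterTPMMatrix


@dataclass
class LogFCMatrix:
    gene_ids: list[str]
    cluster_ids: list[str]
    logfc: np.ndarray
    log_base: float
    pseudocount: float
    scope: str
    cluster_tissue: dict[str, str]

    def column(self, cluster: str) -> np.ndarray:
        try:
            j = self.cluster_ids.index(cluster)
        except ValueError:
            raise DataValidationError(f"unknown cluster {cluster!r}") from None
        return self.logfc[:, j]


def aggregate_tpm(counts: CellCountMatrix) -> ClusterTPMMatrix:
    """Pool raw counts per cluster and normalize to TPM."""
    clusters = counts.cluster_ids
    pooled = np.empty((counts.counts.shape[0], len(clusters)))
    for j, cl in enumerate(clusters):
        idx = counts.cell_indices_of_cluster(cl)
        if idx.size == 0:
            raise DataValidationError(f"cluster {cl!r} has no cells")
        pooled[:, j] = np.asarray(counts.counts[:, idx].sum(axis=1)).ravel()
    totals = pooled.sum(axis=0)
    zero = [clusters[j] for j in np.nonzero(totals == 0)[0]]
    if zero:
        raise DataValidationError(f"cluster(s) with zero total counts: {zero}")
    tpm = pooled / totals * TPM_TOTAL
    return ClusterTPMMatrix(
        gene_ids=list(counts.gene_ids),
        cluster_ids=clusters,
        tpm=tpm,
        cluster_tissue={c: counts.cluster_tissue[c] for c in clusters},
    )


def compute_logfc(
    tpm: ClusterTPMMatrix,
    pseudocount: float = 1.0,
    log_base: float = 2.0,
    scope: str = "within_tissue",
) -> LogFCMatrix:
    """Per-gene, per-cluster log fold change against the scope background.

    ``scope`` is ``within_tissue`` (background = other clusters of the
    same tissue) or ``whole_dataset``.
    """
    if pseudocount < 0:
        raise DataValidationError("pseudocount must be >= 0")
    if log_base <= 0 or log_base == 1:
        raise DataValidationError("log_base must be positive and != 1")
    if scope not in ("within_tissue", "whole_dataset"):
        raise DataValidationError(f"unknown scope {scope!r}")

    groups: dict[str, list[int]] = {}
    for j, cl in enumerate(tpm.cluster_ids):
        key = tpm.cluster_tissue.get(cl, "") if scope == "within_tissue" else "__all__"
        groups.setdefault(key, []).append(j)

    out = np.empty_like(tpm.tpm)
    for key, idx in groups.items():
        if len(idx) < 2:
            raise DataValidationError(
                f"background undefined: scope group {key!r} has a single cluster"
            )
        sub = tpm.tpm[:, idx]
        total = sub.sum(axis=1, keepdims=True)
        bg = (total - sub) / (len(idx) - 1)
        out[:, idx] = np.log((sub + pseudocount) / (bg + pseudocount)) / np.log(log_base)
    return LogFCMatrix(
        gene_ids=list(tpm.gene_ids),
        cluster_ids=list(tpm.cluster_ids),
        logfc=out,
        log_base=log_base,
        pseudocount=pseudocount,
        scope=scope,
        cluster_tissue=dict(tpm.cluster_tissue),
    )


def write_logfc(lfc: LogFCMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# log_base={lfc.log_base} pseudocount={lfc.pseudocount} scope={lfc.scope}\n"
        )
        df = pd.DataFrame(lfc.logfc, columns=lfc.cluster_ids)
        df.insert(0, "gene_id", lfc.gene_ids)
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_logfc(path: str | Path, cluster_tissue: dict[str, str] | None = None) -> LogFCMatrix:
    header = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                header[k] = v
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    cluster_ids = [c for c in df.columns if c != "gene_id"]
    return LogFCMatrix(
        gene_ids=list(df["gene_id"].astype(str)),
        cluster_ids=cluster_ids,
        logfc=df[cluster_ids].to_numpy(dtype=float),
        log_base=float(header.get("log_base", 2.0)),
        pseudocount=float(header.get("pseudocount", 1.0)),
        scope=header.get("scope", "within_tissue"),
        cluster_tissue=cluster_tissue or {},
    )
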