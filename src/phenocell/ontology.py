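"""Tissue-to-phenotype mapping through anatomy and phenotype ontologies.

Each analyzed tissue is anchored to one anatomy term.  The anchor's
subtree collects anatomy terms; cross-links carry those to phenotype
terms, which are expanded to their own descendants.  The candidate
phenotypes are then reduced to the informative, non-redundant ones:
terms with at least ``min_genes`` annotated genes and no descendant term
with more than ``min_genes`` genes.  The asymmetry (>= to keep, strictly
> to disqualify) is deliberate and configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import DataValidationError
from .io import PhenotypeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENES = 20


@dataclass
class OntologySet:
    """Anatomy + phenotype DAGs, cross-links, annotations, tissue anchors."""

    anatomy: nx.DiGraph
    phenotype: nx.DiGraph
    links: set[tuple[str, str]]
    annotations: PhenotypeAnnotation
    tissue_anchor: dict[str, str]
    annotations_propagated: bool = True

    def __post_init__(self) -> None:
        for tissue, anchor in self.tissue_anchor.items():
            if anchor not in self.anatomy:
                raise DataValidationError(
                    f"tissue {tissue!r} anchored to unknown anatomy term {anchor!r}"
                )
        for a, p in self.links:
            if a not in self.anatomy:
                logger.warning("link endpoint %s not in anatomy graph", a)
            if p not in self.phenotype:
                logger.warning("link endpoint %s not in phenotype graph", p)


@dataclass
class TissuePhenotypeMap:
    """Per tissue, the informative phenotype terms and their gene sets."""

    entries: dict[str, list[tuple[str, set[str]]]] = field(default_factory=dict)

    def to_frame(self, names: dict[str, str] | None = None) -> pd.DataFrame:
        names = names or {}
        rows = []
        for tissue, lst in self.entries.items():
            for pid, genes in lst:
                rows.append(
                    {
                        "tissue": tissue,
                        "phenotype_id": pid,
                        "phenotype_name": names.get(pid, ""),
                        "n_genes": len(genes),
                        "gene_ids": ",".join(sorted(genes)),
                    }
                )
        return pd.DataFrame(
            rows, columns=["tissue", "phenotype_id", "phenotype_name", "n_genes", "gene_ids"]
        )

    def write(self, path: str | Path, names: dict[str, str] | None = None) -> None:
        self.to_frame(names).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TissuePhenotypeMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries: dict[str, list[tuple[str, set[str]]]] = {}
        for _, row in df.iterrows():
            genes = set(row["gene_ids"].split(",")) if row["gene_ids"] else set()
            entries.setdefault(row["tissue"], []).append((row["phenotype_id"], genes))
        return cls(entries)


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------


def descendants(graph: nx.DiGraph, term: str, include_self: bool = False) -> set[str]:
    """Transitive closure of is_a children of ``term``.

    The graph stores child->parent edges, so a descendant of T is any
    node from which T is reachable.
    """
    if term not in graph:
        raise DataValidationError(f"unknown term {term!r}")
    out = set(nx.ancestors(graph, term))
    if include_self:
        out.add(term)
    return out


def tissue_phenotype_terms(onts: OntologySet, tissue: str) -> set[str]:
    """All phenotype terms reachable from a tissue's anatomy subtree."""
    if tissue not in onts.tissue_anchor:
        raise DataValidationError(f"unknown tissue {tissue!r}")
    anchor = onts.tissue_anchor[tissue]
    anat = descendants(onts.anatomy, anchor, include_self=True)
    linked = {p for a, p in onts.links if a in anat}
    out: set[str] = set()
    for p in linked:
        if p in onts.phenotype:
            out |= descendants(onts.phenotype, p, include_self=True)
        else:
            out.add(p)
    return out


def phenotype_gene_set(
    onts: OntologySet, phenotype: str, propagate: bool | None = None
) -> set[str]:
    """Genes annotated to a phenotype term.

    With ``propagate`` the union over the term and its descendants is
    returned; HPO-dialect annotation files already propagate, so the
    default follows ``onts.annotations_propagated``.
    """
    if phenotype not in onts.phenotype:
        raise DataValidationError(f"phenotype {phenotype!r} not in ontology")
    if propagate is None:
        propagate = not onts.annotations_propagated
    by_pheno = onts.annotations.by_phenotype()
    genes = set(by_pheno.get(phenotype, set()))
    if propagate:
        for d in descendants(onts.phenotype, phenotype):
            genes |= by_pheno.get(d, set())
    return genes


def filter_informative(
    onts: OntologySet,
    candidate_terms: set[str],
    min_genes: int = DEFAULT_MIN_GENES,
    strict_descendant_gt: bool = True,
    propagate: bool | None = None,
) -> list[tuple[str, set[str]]]:
    """Keep informative, non-redundant phenotype terms.

    A term survives iff it has >= ``min_genes`` annotated genes and no
    descendant anywhere in the phenotype graph has more than ``min_genes``
    (or >= min_genes when ``strict_descendant_gt`` is off).
    """
    if min_genes < 1:
        raise DataValidationError("min_genes must be >= 1")
    kept = []
    for term in sorted(candidate_terms):
        genes = phenotype_gene_set(onts, term, propagate=propagate)
        if len(genes) < min_genes:
            continue
        disqualified = False
        for d in descendants(onts.phenotype, term):
            nd = len(phenotype_gene_set(onts, d, propagate=propagate))
            if nd > min_genes or (not strict_descendant_gt and nd >= min_genes):
                disqualified = True
                break
        if not disqualified:
            kept.append((term, genes))
    return kept


def build_tissue_phenotype_map(
    onts: OntologySet,
    min_genes: int = DEFAULT_MIN_GENES,
    strict_descendant_gt: bool = True,
) -> TissuePhenotypeMap:
    """Run traversal + informativeness filter for every anchored tissue.

    Tissues whose informative-phenotype list comes out empty are dropped
    with a logged notice.
    """
    entries: dict[str, list[tuple[str, set[str]]]] = {}
    for tissue in onts.tissue_anchor:
        candidates = tissue_phenotype_terms(onts, tissue)
        kept = filter_informative(
            onts, candidates, min_genes=min_genes, strict_descendant_gt=strict_descendant_gt
        )
        if not kept:
            logger.info("tissue %s has no informative phenotypes; dropped", tissue)
            continue
        entries[tissue] = kept
    return TissuePhenotypeMap(entries)
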