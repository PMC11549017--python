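"""Seeded synthetic inputs with the structure the analysis assumes.

The generator emulates a clustered single-cell atlas: negative-binomial
counts with a per-gene lognormal baseline and per-cell library-size
factors, organised into tissues -> clusters -> cells with repeated
cell-type annotations.  Two association mechanisms can be planted per
(phenotype, cluster):

* a differential-expression shift — the phenotype's genes have their
  mean multiplied by 2**shift in the target cluster only;
* a co-expression module — within the target cluster the phenotype's
  genes share a per-cell latent on/off gate, which induces positive
  dependence of binarized expression while leaving every gene's marginal
  mean unchanged (a gene is drawn at mean mu/p_on when its gate is on,
  zero otherwise, with the gate on with probability p_on).

Alongside the counts the generator emits toy anatomy and phenotype DAGs
with cross-links (including, per tissue, a redundant parent/child term
pair and an under-annotated term that exercise the informativeness
filter), a propagated-style phenotype-gene annotation table, a
co-mention count table in which planted pairs are strongly co-mentioned
subject to configurable false-positive/false-negative noise, and the
ground-truth table used for recovery scoring.

All randomness flows from one seed through named SeedSequence spawns,
so each component has its own stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .io import (
    CellCountMatrix,
    PhenotypeAnnotation,
    write_counts,
    write_links,
    write_obo,
    write_phenotype_annotations,
    write_tissue_anchors,
)
from .ontology import OntologySet

DEFAULT_DE_SHIFT = 2.0
DEFAULT_COEX_LOADING = 0.6


@dataclass
class SimConfig:
    """Study-scale knobs for the synthetic atlas.

    Defaults are the desk scale the pipeline is exercised at: 2 tissues
    x 4 clusters x 300 cells x 1500 genes, 6 phenotypes per tissue.
    """

    n_tissues: int = 2
    clusters_per_tissue: int = 4
    cells_per_cluster: int = 300
    n_genes: int = 1500
    phenotypes_per_tissue: int = 6
    genes_per_phenotype: tuple[int, int] = (20, 40)
    # baseline expression: lognormal gene means scaled to this expected
    # per-cell total, NB dispersion (size), lognormal library-factor sd
    target_library_size: float = 2500.0
    baseline_sigma: float = 1.0
    dispersion: float = 2.0
    library_sigma: float = 0.3
    gate_p_on: float = 0.5
    # planted mechanisms: (phenotype_id, cluster_id, strength)
    planted_de: list[tuple[str, str, float]] = field(default_factory=list)
    planted_coex: list[tuple[str, str, float]] = field(default_factory=list)
    # literature noise: planted pairs dropped (fn) / null pairs promoted (fp)
    coment_fp_rate: float = 0.02
    coment_fn_rate: float = 0.10
    coment_corpus: int = 1_000_000
    min_genes: int = 20
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_tissues, self.clusters_per_tissue, self.cells_per_cluster,
               self.n_genes, self.phenotypes_per_tissue) < 1:
            raise ConfigError("all counts must be positive")
        lo, hi = self.genes_per_phenotype
        if not (1 <= lo <= hi):
            raise ConfigError("invalid genes_per_phenotype range")
        if not (0 < self.gate_p_on < 1):
            raise ConfigError("gate_p_on must be in (0, 1)")
        for _, _, s in self.planted_de:
            if not np.isfinite(s):
                raise ConfigError("non-finite DE shift")
        for _, _, l in self.planted_coex:
            if not (0 < l < 1):
                raise ConfigError("coex loading must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Planted (tissue, phenotype, cell type, mechanism) associations."""

    planted: list[tuple[str, str, str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.planted, columns=["tissue", "phenotype_id", "cell_type", "mechanism"]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls([tuple(r) for r in df.itertuples(index=False)])


# ---------------------------------------------------------------------------
# identifier scheme
# ---------------------------------------------------------------------------


def tissue_name(i: int) -> str:
    return f"tissue{i + 1:02d}"


def cluster_name(i: int, j: int) -> str:
    return f"t{i + 1:02d}c{j + 1}"


def phenotype_term(i: int, k: int) -> str:
    return f"HP:T{i + 1:02d}P{k + 1:02d}"


def _celltypes_for(n_clusters: int) -> list[str]:
    """Cell-type labels with the first two clusters sharing one type."""
    labels = []
    for j in range(n_clusters):
        labels.append("ctA" if j < 2 and n_clusters >= 2 else f"ct{chr(ord('A') + max(j - 1, 0))}")
    return labels


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Desk-scale config with the standard plants.

    Per tissue: phenotype 1 gets a DE shift (2.0 log2 units) in cluster 1,
    phenotype 2 a co-expression gate (loading 0.6) in cluster 3, and
    phenotype 3 both mechanisms in cluster 4; the rest are decoys.
    """
    cfg = SimConfig(seed=seed, **{k: v for k, v in overrides.items()
                                  if k not in ("planted_de", "planted_coex")})
    if "planted_de" in overrides or "planted_coex" in overrides:
        cfg.planted_de = list(overrides.get("planted_de", []))
        cfg.planted_coex = list(overrides.get("planted_coex", []))
    else:
        for i in range(cfg.n_tissues):
            cfg.planted_de.append((phenotype_term(i, 0), cluster_name(i, 0), DEFAULT_DE_SHIFT))
            if cfg.clusters_per_tissue >= 3:
                cfg.planted_coex.append(
                    (phenotype_term(i, 1), cluster_name(i, 2), DEFAULT_COEX_LOADING)
                )
            if cfg.clusters_per_tissue >= 4 and cfg.phenotypes_per_tissue >= 3:
                cfg.planted_de.append((phenotype_term(i, 2), cluster_name(i, 3), DEFAULT_DE_SHIFT))
                cfg.planted_coex.append(
                    (phenotype_term(i, 2), cluster_name(i, 3), DEFAULT_COEX_LOADING)
                )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate(
    config: SimConfig,
) -> tuple[CellCountMatrix, OntologySet, pd.DataFrame, SyntheticTruth]:
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    ss_sets, ss_counts, ss_coment, ss_base = ss.spawn(4)
    rng_sets = np.random.default_rng(ss_sets)
    rng_coment = np.random.default_rng(ss_coment)
    rng_base = np.random.default_rng(ss_base)

    genes = [f"G{g:04d}" for g in range(config.n_genes)]
    tissues = [tissue_name(i) for i in range(config.n_tissues)]
    celltype_labels = _celltypes_for(config.clusters_per_tissue)

    # -- cluster layout ----------------------------------------------------
    cluster_ids, cluster_celltype, cluster_tissue = [], {}, {}
    for i, t in enumerate(tissues):
        for j in range(config.clusters_per_tissue):
            c = cluster_name(i, j)
            cluster_ids.append(c)
            cluster_celltype[c] = celltype_labels[j]
            cluster_tissue[c] = t

    # -- phenotype gene sets (disjoint, so plants do not bleed) -----------
    lo, hi = config.genes_per_phenotype
    pheno_ids = [
        phenotype_term(i, k)
        for i in range(config.n_tissues)
        for k in range(config.phenotypes_per_tissue)
    ]
    extra_per_tissue = config.min_genes + 4  # parent extras + small decoy term
    need = len(pheno_ids) * max(hi, config.min_genes + 1) + config.n_tissues * extra_per_tissue
    if need > config.n_genes:
        raise ConfigError(
            f"gene pool too small: need up to {need} genes for annotations, have {config.n_genes}"
        )
    pool = list(rng_sets.permutation(config.n_genes))
    gene_sets: dict[str, set[str]] = {}
    for i in range(config.n_tissues):
        for k in range(config.phenotypes_per_tissue):
            pid = phenotype_term(i, k)
            # the first phenotype sits under a redundant parent; keep its
            # set strictly above min_genes so the filter resolves to it
            floor = max(lo, config.min_genes + 1) if k == 0 else lo
            size = int(rng_sets.integers(floor, max(hi, floor) + 1))
            gene_sets[pid] = {genes[pool.pop()] for _ in range(size)}

    planted_pheno = {p for p, _, _ in config.planted_de} | {
        p for p, _, _ in config.planted_coex
    }
    unknown = planted_pheno - set(pheno_ids)
    if unknown:
        raise ConfigError(f"planted phenotypes not generated: {sorted(unknown)}")
    for p, c, _ in config.planted_de + config.planted_coex:
        if c not in cluster_celltype:
            raise ConfigError(f"planted cluster {c!r} not generated")

    # -- ontologies --------------------------------------------------------
    anatomy = nx.DiGraph()
    phenotype = nx.DiGraph()
    anatomy.add_node("UBERON:ROOT", name="body")
    phenotype.add_node("HP:ROOT", name="phenotypic abnormality")
    links: set[tuple[str, str]] = set()
    anchors: dict[str, str] = {}
    ann_records: list[tuple[str, str, str]] = []

    def annotate(pid: str, name: str, gs: set[str]) -> None:
        for g in sorted(gs):
            ann_records.append((pid, name, g))

    for i, t in enumerate(tissues):
        anchor = f"UBERON:T{i + 1:02d}"
        subs = [f"{anchor}S1", f"{anchor}S2"]
        anatomy.add_node(anchor, name=f"{t} anatomy")
        anatomy.add_edge(anchor, "UBERON:ROOT")
        for s in subs:
            anatomy.add_node(s, name=f"{t} part")
            anatomy.add_edge(s, anchor)
        anchors[t] = anchor

        for k in range(config.phenotypes_per_tissue):
            pid = phenotype_term(i, k)
            name = f"{t} phenotype {k + 1}"
            phenotype.add_node(pid, name=name)
            phenotype.add_edge(pid, "HP:ROOT")
            annotate(pid, name, gene_sets[pid])
            if k == 0:
                # redundant parent over the first phenotype: the anatomy link
                # points at the parent; traversal reaches the child as a
                # descendant and the informativeness filter drops the parent
                parent = f"HP:T{i + 1:02d}RED"
                phenotype.add_node(parent, name=f"{t} redundant parent")
                phenotype.add_edge(parent, "HP:ROOT")
                phenotype.remove_edge(pid, "HP:ROOT")
                phenotype.add_edge(pid, parent)
                extras = {genes[pool.pop()] for _ in range(4)}
                annotate(parent, f"{t} redundant parent", gene_sets[pid] | extras)
                links.add((anchor, parent))
            else:
                # alternate link anchoring across the anatomy subtree
                links.add((subs[k % 2], pid))
        # under-annotated decoy term: informativeness filter must drop it
        small = f"HP:T{i + 1:02d}SMALL"
        phenotype.add_node(small, name=f"{t} small term")
        phenotype.add_edge(small, "HP:ROOT")
        annotate(small, f"{t} small term", {genes[pool.pop()] for _ in range(config.min_genes - 1)})
        links.add((anchor, small))

    onts = OntologySet(
        anatomy=anatomy,
        phenotype=phenotype,
        links=links,
        annotations=PhenotypeAnnotation(ann_records),
        tissue_anchor=anchors,
        annotations_propagated=True,
    )

    # -- counts ------------------------------------------------------------
    base = rng_base.lognormal(mean=0.0, sigma=config.baseline_sigma, size=config.n_genes)
    base *= config.target_library_size / base.sum()
    gene_pos = {g: i for i, g in enumerate(genes)}
    de_by_cluster: dict[str, dict[int, float]] = {}
    for pid, c, shift in config.planted_de:
        d = de_by_cluster.setdefault(c, {})
        for g in gene_sets[pid]:
            d[gene_pos[g]] = d.get(gene_pos[g], 0.0) + shift
    coex_by_cluster: dict[str, list[tuple[list[int], float]]] = {}
    for pid, c, loading in config.planted_coex:
        coex_by_cluster.setdefault(c, []).append(
            (sorted(gene_pos[g] for g in gene_sets[pid]), loading)
        )

    cell_ids: list[str] = []
    cell_cluster: dict[str, str] = {}
    blocks = []
    cluster_streams = ss_counts.spawn(len(cluster_ids))
    r = config.dispersion
    for c, sub_ss in zip(cluster_ids, cluster_streams):
        rng = np.random.default_rng(sub_ss)
        n_cells = config.cells_per_cluster
        mu_g = base.copy()
        for gi, shift in de_by_cluster.get(c, {}).items():
            mu_g[gi] *= 2.0 ** shift
        lib = rng.lognormal(mean=0.0, sigma=config.library_sigma, size=n_cells)
        mu = mu_g[:, None] * lib[None, :]
        counts = rng.negative_binomial(r, r / (r + mu))
        for gidx, loading in coex_by_cluster.get(c, []):
            p_on = config.gate_p_on
            z = rng.random(n_cells) < p_on
            follow = rng.random((len(gidx), n_cells)) < loading
            own = rng.random((len(gidx), n_cells)) < p_on
            gate = np.where(follow, z[None, :], own)
            mu_set = mu[gidx, :] / p_on
            counts[gidx, :] = gate * rng.negative_binomial(r, r / (r + mu_set))
        blocks.append(sp.csr_matrix(counts))
        for ci in range(n_cells):
            cid = f"{c}_cell{ci + 1:04d}"
            cell_ids.append(cid)
            cell_cluster[cid] = c

    ccm = CellCountMatrix(
        gene_ids=genes,
        cell_ids=cell_ids,
        counts=sp.hstack(blocks, format="csr"),
        cell_cluster=cell_cluster,
        cluster_celltype=cluster_celltype,
        cluster_tissue=cluster_tissue,
    )

    # -- truth and co-mentions ---------------------------------------------
    truth_rows: set[tuple[str, str, str, str]] = set()
    for pid, c, _ in config.planted_de:
        truth_rows.add((cluster_tissue[c], pid, cluster_celltype[c], "diffexpr"))
    for pid, c, _ in config.planted_coex:
        truth_rows.add((cluster_tissue[c], pid, cluster_celltype[c], "coexpr"))
    truth = SyntheticTruth(sorted(truth_rows))

    planted_pairs = {(pid, ct) for _, pid, ct, _ in truth_rows}
    coment_rows = []
    N = config.coment_corpus
    for i, t in enumerate(tissues):
        cts = sorted(set(celltype_labels))
        for k in range(config.phenotypes_per_tissue):
            pid = phenotype_term(i, k)
            for ct in cts:
                planted = (pid, ct) in planted_pairs
                u = rng_coment.random()
                if planted and u >= config.coment_fn_rate:
                    n_phen, n_ct, n_both = 300, 3000, 30
                elif not planted and u < config.coment_fp_rate:
                    n_phen, n_ct, n_both = 300, 3000, 30
                else:
                    if rng_coment.random() < 0.5:
                        continue  # never co-mentioned: absent from the table
                    n_phen = int(rng_coment.integers(100, 500))
                    n_ct = int(rng_coment.integers(1000, 5000))
                    n_both = int(rng_coment.hypergeometric(n_phen, N - n_phen, n_ct))
                coment_rows.append(
                    {"phenotype_id": pid, "cell_type": ct, "n_phen": n_phen,
                     "n_ct": n_ct, "n_both": n_both, "n_corpus": N}
                )
    coment = pd.DataFrame(
        coment_rows,
        columns=["phenotype_id", "cell_type", "n_phen", "n_ct", "n_both", "n_corpus"],
    )
    return ccm, onts, coment, truth


def simulate_to_dir(config: SimConfig, outdir: str | Path) -> None:
    """Run the generator and write every input file the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ccm, onts, coment, truth = simulate(config)
    write_counts(
        ccm, outdir / "counts.mtx", outdir / "cells.tsv", outdir / "clusters.tsv",
        outdir / "genes.tsv",
    )
    write_obo(onts.anatomy, outdir / "anatomy.obo", "synthetic-anatomy")
    write_obo(onts.phenotype, outdir / "phenotype.obo", "synthetic-phenotype")
    write_links(onts.links, outdir / "links.tsv")
    write_tissue_anchors(onts.tissue_anchor, outdir / "tissue_anchors.tsv")
    write_phenotype_annotations(onts.annotations, outdir / "phenotype_to_genes.tsv")
    coment.to_csv(outdir / "comentions.tsv", sep="\t", index=False)
    truth.write(outdir / "truth.tsv")


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def truth_recovery_report(
    calls: pd.DataFrame, truth: SyntheticTruth, universe: set[tuple[str, str, str, str]] | None = None
) -> dict:
    """Per-mechanism sensitivity and the false-call rate over unplanted triples.

    ``calls`` is the cell-type call table.  The unplanted universe
    defaults to every (tissue, phenotype, cell_type, metric) combination
    present in ``calls``.
    """
    sig = {
        (r.tissue, r.phenotype_id, r.cell_type, r.metric)
        for r in calls.itertuples(index=False)
        if r.significant
    }
    call_universe = {
        (r.tissue, r.phenotype_id, r.cell_type, r.metric)
        for r in calls.itertuples(index=False)
    }
    planted = set(truth.planted)
    missing = planted - call_universe
    if missing and not (planted & call_universe):
        raise ConfigError(f"truth identifiers unknown to calls: {sorted(missing)[:3]}")
    universe = universe or call_universe
    report: dict = {}
    for mech in ("diffexpr", "coexpr"):
        mech_planted = {t for t in planted if t[3] == mech}
        if mech_planted:
            report[f"sensitivity_{mech}"] = len(mech_planted & sig) / len(mech_planted)
        else:
            report[f"sensitivity_{mech}"] = None
    unplanted = universe - planted
    report["false_call_rate"] = (
        len(unplanted & sig) / len(unplanted) if unplanted else None
    )
    report["n_planted"] = len(planted)
    report["n_unplanted"] = len(unplanted)
    return report
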