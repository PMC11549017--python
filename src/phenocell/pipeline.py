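"""Staged end-to-end orchestration with plain files between stages.

Stage order mirrors the analysis: (simulate) -> map -> diffexpr ->
coexpr -> test -> aggregate -> validate.  Every stage reads its inputs
from and writes its outputs to one working directory, so each stage is
independently runnable and re-running with an unchanged config
reproduces byte-identical files.  A ``manifest.json`` records the config
hash, seed and per-output row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, coexpr, diffexpr, litval
from .errors import ConfigError, MissingArtifactError
from .io import (
    read_cluster_tpm,
    read_counts,
    read_links,
    read_obo,
    read_phenotype_annotations,
    read_tissue_anchors,
    write_cluster_tpm,
)
from .ontology import OntologySet, TissuePhenotypeMap, build_tissue_phenotype_map
from .simulate import SimConfig, simulate_to_dir

logger = logging.getLogger(__name__)

STAGES = ["simulate", "map", "diffexpr", "coexpr", "test", "aggregate", "validate"]

# stage -> list of (required file, producing stage)
_REQUIRES = {
    "map": [
        ("anatomy.obo", "simulate"),
        ("phenotype.obo", "simulate"),
        ("links.tsv", "simulate"),
        ("tissue_anchors.tsv", "simulate"),
        ("phenotype_to_genes.tsv", "simulate"),
    ],
    "diffexpr": [("counts.mtx", "simulate"), ("cells.tsv", "simulate"), ("clusters.tsv", "simulate")],
    "coexpr": [
        ("counts.mtx", "simulate"),
        ("cells.tsv", "simulate"),
        ("clusters.tsv", "simulate"),
        ("tissue_phenotypes.tsv", "map"),
    ],
    "test": [
        ("logfc.tsv", "diffexpr"),
        ("tissue_phenotypes.tsv", "map"),
        ("clusters.tsv", "simulate"),
        ("coex", "coexpr"),
    ],
    "aggregate": [("results.tsv", "test"), ("tissue_phenotypes.tsv", "map")],
    "validate": [("celltype_calls.tsv", "aggregate"), ("comentions.tsv", "simulate")],
}


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the study defaults."""

    outdir: Path = Path("phenocell_run")
    seed: int = 0
    # ontology mapping
    min_genes: int = 20
    strict_descendant_gt: bool = True
    annotations_propagated: bool = True
    # differential expression
    log_base: float = 2.0
    pseudocount: float = 1.0
    logfc_scope: str = "within_tissue"
    # QC / co-expression
    qc_min_genes_per_cell: int = 200
    qc_min_cells_per_gene: int = 3
    qc_outlier_mad_k: float = 5.0
    expr_threshold: int = 0
    bg_gene_sample: int = 2000
    bg_pair_sample: int = 200_000
    # statistics
    metrics: tuple[str, ...] = ("diffexpr", "coexpr")
    coexpr_mode: str = "abs_greater"
    include_mixed_background: bool = True
    min_set_size: int = 3
    min_pair_count: int = 3
    fdr_family: str = "per_tissue"
    fdr_threshold: float = 1e-3
    # validation
    coment_alpha: float = 1e-3
    # synthetic input generation (None -> inputs supplied externally)
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if not (0 < self.fdr_threshold < 1) or not (0 < self.coment_alpha < 1):
            raise ConfigError("thresholds must lie in (0, 1)")
        if self.min_genes < 1:
            raise ConfigError("min_genes must be >= 1")
        bad = set(self.metrics) - {"diffexpr", "coexpr"}
        if bad:
            raise ConfigError(f"unknown metrics {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        if isinstance(raw.get("metrics"), list):
            raw["metrics"] = tuple(raw["metrics"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        raw.update(overrides)
        cfg = cls(**raw)
        if sim is not None:
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(sim) - sim_known
            if bad:
                raise ConfigError(f"unknown sim config keys {sorted(bad)}")
            if isinstance(sim.get("genes_per_phenotype"), list):
                sim["genes_per_phenotype"] = tuple(sim["genes_per_phenotype"])
            sim.setdefault("seed", cfg.seed)
            cfg.sim = SimConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # analysis identity, not artifact location
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _check_inputs(stage: str, outdir: Path) -> None:
    for fname, producer in _REQUIRES.get(stage, []):
        if not (outdir / fname).exists():
            raise MissingArtifactError(
                f"stage {stage!r} needs {fname} (produced by stage {producer!r}); "
                f"not found in {outdir}"
            )


def _update_manifest(config: PipelineConfig, stage: str, outputs: dict[str, int]) -> None:
    path = config.outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest.update(
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "fdr_threshold": config.fdr_threshold,
            "min_genes": config.min_genes,
            "coment_alpha": config.coment_alpha,
        }
    )
    manifest.setdefault("stages", {})[stage] = {"outputs": outputs}
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _load_counts(outdir: Path):
    return read_counts(outdir / "counts.mtx", outdir / "cells.tsv", outdir / "clusters.tsv")


def _bg_gene_rng(config: PipelineConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, 1017]))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig) -> None:
    if config.sim is None:
        raise ConfigError("stage 'simulate' requires a [sim] config section")
    config.outdir.mkdir(parents=True, exist_ok=True)
    simulate_to_dir(config.sim, config.outdir)
    _update_manifest(config, "simulate", {"counts.mtx": config.sim.n_genes})


def stage_map(config: PipelineConfig) -> None:
    out = config.outdir
    _check_inputs("map", out)
    onts = OntologySet(
        anatomy=read_obo(out / "anatomy.obo"),
        phenotype=read_obo(out / "phenotype.obo"),
        links=read_links(out / "links.tsv"),
        annotations=read_phenotype_annotations(out / "phenotype_to_genes.tsv"),
        tissue_anchor=read_tissue_anchors(out / "tissue_anchors.tsv"),
        annotations_propagated=config.annotations_propagated,
    )
    tpmap = build_tissue_phenotype_map(
        onts, min_genes=config.min_genes, strict_descendant_gt=config.strict_descendant_gt
    )
    tpmap.write(out / "tissue_phenotypes.tsv", onts.annotations.phenotype_names)
    _update_manifest(
        config, "map", {"tissue_phenotypes.tsv": int(len(tpmap.to_frame()))}
    )


def stage_diffexpr(config: PipelineConfig) -> None:
    out = config.outdir
    _check_inputs("diffexpr", out)
    counts = _load_counts(out)
    tpm = diffexpr.aggregate_tpm(counts)
    write_cluster_tpm(tpm, out / "tpm.tsv", out / "cluster_tissues.tsv")
    lfc = diffexpr.compute_logfc(
        tpm, pseudocount=config.pseudocount, log_base=config.log_base, scope=config.logfc_scope
    )
    diffexpr.write_logfc(lfc, out / "logfc.tsv")
    _update_manifest(config, "diffexpr", {"logfc.tsv": len(lfc.gene_ids)})


def stage_coexpr(config: PipelineConfig) -> None:
    out = config.outdir
    _check_inputs("coexpr", out)
    counts = _load_counts(out)
    counts = coexpr.qc_filter(
        counts,
        min_genes_per_cell=config.qc_min_genes_per_cell,
        min_cells_per_gene=config.qc_min_cells_per_gene,
        outlier_mad_k=config.qc_outlier_mad_k,
    )
    tpmap = TissuePhenotypeMap.read(out / "tissue_phenotypes.tsv")
    measured = set(counts.gene_ids)
    pheno_union: dict[str, set[str]] = {
        tissue: set().union(*(g for _, g in entries)) & measured
        for tissue, entries in tpmap.entries.items()
    }
    rng = _bg_gene_rng(config)
    all_pheno = set().union(*pheno_union.values()) if pheno_union else set()
    rest = sorted(measured - all_pheno)
    n_bg = min(config.bg_gene_sample, len(rest))
    bg_genes = set(rng.choice(rest, size=n_bg, replace=False)) if n_bg else set()

    coex_dir = out / "coex"
    coex_dir.mkdir(exist_ok=True)
    outputs = {}
    for cluster in counts.cluster_ids:
        tissue = counts.cluster_tissue[cluster]
        keep = pheno_union.get(tissue, set())
        universe = keep | bg_genes
        if len(universe) < 2:
            logger.warning("cluster %s: universe below 2 genes; skipped", cluster)
            continue
        cm = coexpr.coex_matrix(
            counts, cluster, gene_universe=universe, expr_threshold=config.expr_threshold
        )
        pairs = cm.to_pairs_frame(
            keep_genes=keep, bg_pair_sample=config.bg_pair_sample, rng=rng
        )
        coexpr.write_coex_pairs(pairs, coex_dir / f"{cluster}.tsv")
        outputs[f"coex/{cluster}.tsv"] = len(pairs)
    _update_manifest(config, "coexpr", outputs)


def stage_test(config: PipelineConfig) -> None:
    out = config.outdir
    _check_inputs("test", out)
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t", dtype=str)
    cluster_tissue = dict(zip(clusters["cluster_id"], clusters["tissue"]))
    cluster_celltype = dict(zip(clusters["cluster_id"], clusters["cell_type"]))
    lfc = diffexpr.read_logfc(out / "logfc.tsv", cluster_tissue)
    tp = pd.read_csv(out / "tissue_phenotypes.tsv", sep="\t", dtype=str)

    results = []
    coex_cache: dict[str, pd.DataFrame | None] = {}
    for tissue, sub in tp.groupby("tissue", sort=True):
        tissue_clusters = [c for c in lfc.cluster_ids if cluster_tissue.get(c) == tissue]
        for _, row in sub.iterrows():
            gene_set = set(row["gene_ids"].split(","))
            for cluster in tissue_clusters:
                if "diffexpr" in config.metrics:
                    r = assoc.de_association(
                        lfc, cluster, gene_set, min_set_size=config.min_set_size
                    )
                    _fill(r, tissue, row, cluster, cluster_celltype)
                    results.append(r)
                if "coexpr" in config.metrics:
                    if cluster not in coex_cache:
                        p = out / "coex" / f"{cluster}.tsv"
                        coex_cache[cluster] = coexpr.read_coex_pairs(p) if p.exists() else None
                    pairs = coex_cache[cluster]
                    if pairs is None:
                        r = assoc.AssociationResult(
                            cluster_id=cluster, metric="coexpr",
                            skipped_reason="no_coex_table",
                        )
                    else:
                        r = assoc.coex_association_from_pairs(
                            pairs,
                            gene_set,
                            mode=config.coexpr_mode,
                            min_pair_count=config.min_pair_count,
                            include_mixed=config.include_mixed_background,
                            cluster_id=cluster,
                        )
                    _fill(r, tissue, row, cluster, cluster_celltype)
                    results.append(r)
    df = assoc.results_to_frame(results)
    df = assoc.apply_fdr(df, family=config.fdr_family)
    df.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.6g")
    _update_manifest(config, "test", {"results.tsv": len(df)})


def _fill(r, tissue, row, cluster, cluster_celltype) -> None:
    r.tissue = tissue
    r.phenotype_id = row["phenotype_id"]
    r.phenotype_name = row.get("phenotype_name", "") or ""
    r.cell_type = cluster_celltype.get(cluster, "")


def stage_aggregate(config: PipelineConfig) -> None:
    out = config.outdir
    _check_inputs("aggregate", out)
    results = pd.read_csv(out / "results.tsv", sep="\t")
    calls = assoc.aggregate_cell_types(results, fdr_threshold=config.fdr_threshold)
    calls.to_csv(out / "celltype_calls.tsv", sep="\t", index=False, float_format="%.6g")

    # phenotype-size bias of significant vs non-significant associations
    tp = pd.read_csv(out / "tissue_phenotypes.tsv", sep="\t", dtype={"n_genes": int})
    sizes = dict(zip(zip(tp["tissue"], tp["phenotype_id"]), tp["n_genes"]))
    bias_rows = []
    for metric, sub in calls.groupby("metric", sort=True):
        s = [sizes[(r.tissue, r.phenotype_id)] for r in sub.itertuples() if r.significant]
        ns = [sizes[(r.tissue, r.phenotype_id)] for r in sub.itertuples() if not r.significant]
        p = assoc.size_bias_test(s, ns) if s and ns else float("nan")
        bias_rows.append({"metric": metric, "test": "mann_whitney_u", "p_value": p})
    pd.DataFrame(bias_rows).to_csv(out / "size_bias.tsv", sep="\t", index=False)
    _update_manifest(config, "aggregate", {"celltype_calls.tsv": len(calls)})


def stage_validate(config: PipelineConfig) -> None:
    out = config.outdir
    _check_inputs("validate", out)
    calls = pd.read_csv(out / "celltype_calls.tsv", sep="\t")
    records = litval.load_comentions(out / "comentions.tsv")
    universe = set(zip(calls["phenotype_id"].astype(str), calls["cell_type"].astype(str)))
    positives, negatives = litval.build_gold(records, universe, alpha=config.coment_alpha)
    summaries = litval.validate(calls, positives, negatives)
    litval.summary_frame(summaries).to_csv(
        out / "validation_summary.tsv", sep="\t", index=False, float_format="%.6g"
    )
    _update_manifest(config, "validate", {"validation_summary.tsv": len(summaries)})


# ---------------------------------------------------------------------------
# in-memory path (no intermediate files)
# ---------------------------------------------------------------------------


def analyze(ccm, onts, config: PipelineConfig):
    """Run map -> diffexpr -> coexpr -> test -> aggregate on in-memory inputs.

    Returns ``(results, calls)`` DataFrames identical in content to the
    staged file path; used when intermediate artifacts are not needed.
    """
    tpmap = build_tissue_phenotype_map(
        onts, min_genes=config.min_genes, strict_descendant_gt=config.strict_descendant_gt
    )
    names = onts.annotations.phenotype_names

    tpm = diffexpr.aggregate_tpm(ccm)
    lfc = diffexpr.compute_logfc(
        tpm, pseudocount=config.pseudocount, log_base=config.log_base, scope=config.logfc_scope
    )
    qc = coexpr.qc_filter(
        ccm,
        min_genes_per_cell=config.qc_min_genes_per_cell,
        min_cells_per_gene=config.qc_min_cells_per_gene,
        outlier_mad_k=config.qc_outlier_mad_k,
    )
    measured = set(qc.gene_ids)
    pheno_union = {
        tissue: set().union(*(g for _, g in entries)) & measured
        for tissue, entries in tpmap.entries.items()
    }
    rng = _bg_gene_rng(config)
    all_pheno = set().union(*pheno_union.values()) if pheno_union else set()
    rest = sorted(measured - all_pheno)
    n_bg = min(config.bg_gene_sample, len(rest))
    bg_genes = set(rng.choice(rest, size=n_bg, replace=False)) if n_bg else set()

    results = []
    for tissue, entries in tpmap.entries.items():
        tissue_clusters = [c for c in lfc.cluster_ids if lfc.cluster_tissue.get(c) == tissue]
        qc_clusters = set(qc.cluster_ids)
        coex_by_cluster = {}
        if "coexpr" in config.metrics:
            universe = pheno_union[tissue] | bg_genes
            for cluster in tissue_clusters:
                if cluster in qc_clusters and len(universe) >= 2:
                    coex_by_cluster[cluster] = coexpr.coex_matrix(
                        qc, cluster, gene_universe=universe,
                        expr_threshold=config.expr_threshold,
                    )
        for pid, gene_set in entries:
            for cluster in tissue_clusters:
                if "diffexpr" in config.metrics:
                    r = assoc.de_association(
                        lfc, cluster, gene_set, min_set_size=config.min_set_size
                    )
                    r.tissue, r.phenotype_id = tissue, pid
                    r.phenotype_name = names.get(pid, "")
                    r.cell_type = ccm.cluster_celltype.get(cluster, "")
                    results.append(r)
                if "coexpr" in config.metrics:
                    cm = coex_by_cluster.get(cluster)
                    if cm is None:
                        r = assoc.AssociationResult(
                            cluster_id=cluster, metric="coexpr",
                            skipped_reason="no_coex_table",
                        )
                    else:
                        r = assoc.coex_association(
                            cm,
                            gene_set,
                            mode=config.coexpr_mode,
                            min_pair_count=config.min_pair_count,
                            include_mixed=config.include_mixed_background,
                            bg_sample=config.bg_pair_sample,
                            rng=rng,
                        )
                    r.tissue, r.phenotype_id = tissue, pid
                    r.phenotype_name = names.get(pid, "")
                    r.cell_type = ccm.cluster_celltype.get(cluster, "")
                    results.append(r)
    df = assoc.results_to_frame(results)
    df = assoc.apply_fdr(df, family=config.fdr_family)
    calls = assoc.aggregate_cell_types(df, fdr_threshold=config.fdr_threshold)
    return df, calls


_STAGE_FN = {
    "simulate": stage_simulate,
    "map": stage_map,
    "diffexpr": stage_diffexpr,
    "coexpr": stage_coexpr,
    "test": stage_test,
    "aggregate": stage_aggregate,
    "validate": stage_validate,
}


def run_stage(name: str, config: PipelineConfig) -> None:
    if name not in _STAGE_FN:
        raise ConfigError(f"unknown stage {name!r}; stages are {STAGES}")
    logger.info("[%s] starting", name)
    _STAGE_FN[name](config)
    logger.info("[%s] done", name)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order and return a run summary."""
    order = STAGES if config.sim is not None else STAGES[1:]
    for name in order:
        run_stage(name, config)
    results = pd.read_csv(config.outdir / "results.tsv", sep="\t")
    calls = pd.read_csv(config.outdir / "celltype_calls.tsv", sep="\t")
    tested = results["skipped_reason"].fillna("") == ""
    summary = {
        "n_tests_run": int(tested.sum()),
        "n_tests_skipped": int((~tested).sum()),
        "n_results_rows": len(results),
        "n_celltype_calls": len(calls),
        "n_significant": int(calls["significant"].sum()),
    }
    for metric in config.metrics:
        sub = calls[calls["metric"] == metric]
        summary[f"n_significant_{metric}"] = int(sub["significant"].sum())
    return summary
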