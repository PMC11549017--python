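"""Literature co-mention gold set and validation of cell-type calls.

Co-mention counts (articles mentioning the phenotype, the cell type,
both, and the corpus size) are scored with an upper-tail hypergeometric
test: the probability of at least the observed overlap if the two sets
of articles were independent draws from the corpus.  Pairs below the
significance cutoff (default .001) form the positive gold set; all other
analyzed pairs — including pairs never co-mentioned — are negatives.
Calls are then summarized as the fraction of positives captured
(significant) and the fraction of negatives correctly left uncalled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataValidationError

DEFAULT_COMENT_ALPHA = 1e-3

Pair = tuple[str, str]  # (phenotype_id, cell_type)


@dataclass
class ComentRecord:
    phenotype_id: str
    cell_type: str
    n_phenotype_articles: int
    n_celltype_articles: int
    n_comention_articles: int
    n_corpus_articles: int
    p_value: float = float("nan")


@dataclass
class ValidationSummary:
    metric: str
    n_positive: int
    n_negative: int
    captured_fraction: float
    negative_correct_fraction: float


def coment_significance(
    n_phenotype_articles: int,
    n_celltype_articles: int,
    n_comention_articles: int,
    n_corpus_articles: int,
) -> float:
    """Upper-tail hypergeometric p of >= the observed co-mention count."""
    k, a, b, n = n_comention_articles, n_phenotype_articles, n_celltype_articles, n_corpus_articles
    if not (0 <= k <= min(a, b) <= n) or a > n or b > n:
        raise DataValidationError(
            f"inconsistent co-mention counts: both={k}, margins=({a},{b}), corpus={n}"
        )
    return float(min(1.0, stats.hypergeom.sf(k - 1, n, a, b)))


def load_comentions(path: str | Path) -> list[ComentRecord]:
    """Read a co-mention table, count-form or precomputed-p form."""
    df = pd.read_csv(path, sep="\t", dtype={"phenotype_id": str, "cell_type": str})
    records = []
    if {"n_phen", "n_ct", "n_both", "n_corpus"} <= set(df.columns):
        for _, r in df.iterrows():
            rec = ComentRecord(
                r["phenotype_id"], r["cell_type"],
                int(r["n_phen"]), int(r["n_ct"]), int(r["n_both"]), int(r["n_corpus"]),
            )
            rec.p_value = coment_significance(
                rec.n_phenotype_articles, rec.n_celltype_articles,
                rec.n_comention_articles, rec.n_corpus_articles,
            )
            records.append(rec)
    elif "p_value" in df.columns:
        for _, r in df.iterrows():
            records.append(
                ComentRecord(r["phenotype_id"], r["cell_type"], 0, 0, 0, 0,
                             p_value=float(r["p_value"]))
            )
    else:
        raise DataValidationError(
            f"{path}: expected count columns (n_phen, n_ct, n_both, n_corpus) or p_value"
        )
    return records


def build_gold(
    records: list[ComentRecord],
    universe: set[Pair],
    alpha: float = DEFAULT_COMENT_ALPHA,
) -> tuple[set[Pair], set[Pair]]:
    """Partition the analyzed pairs into literature positives/negatives.

    A pair is positive iff its co-mention p-value is strictly below
    ``alpha``; pairs without a record are negative.
    """
    if not (0 < alpha < 1):
        raise DataValidationError("alpha must be in (0, 1)")
    pvals: dict[Pair, float] = {}
    for rec in records:
        key = (rec.phenotype_id, rec.cell_type)
        p = rec.p_value
        if np.isnan(p):
            p = coment_significance(
                rec.n_phenotype_articles, rec.n_celltype_articles,
                rec.n_comention_articles, rec.n_corpus_articles,
            )
        pvals[key] = min(p, pvals.get(key, 1.0))
    positives = {pair for pair in universe if pvals.get(pair, 1.0) < alpha}
    return positives, universe - positives


def validate(
    calls: pd.DataFrame,
    positives: set[Pair],
    negatives: set[Pair],
) -> list[ValidationSummary]:
    """Score significant calls against the gold partition, per metric.

    ``calls`` is the cell-type call table (phenotype_id, cell_type,
    metric, significant).  Every called pair must lie in the partition's
    universe.
    """
    universe = positives | negatives
    out = []
    for metric, sub in calls.groupby("metric", sort=True):
        pairs = list(zip(sub["phenotype_id"], sub["cell_type"]))
        outside = [p for p in pairs if p not in universe]
        if outside:
            raise DataValidationError(f"calls outside gold universe: {outside[:5]}")
        sig = {p for p, s in zip(pairs, sub["significant"]) if s}
        n_pos, n_neg = len(positives), len(negatives)
        captured = len(sig & positives) / n_pos if n_pos else float("nan")
        neg_correct = len(negatives - sig) / n_neg if n_neg else float("nan")
        out.append(ValidationSummary(metric, n_pos, n_neg, captured, neg_correct))
    return out


def summary_frame(summaries: list[ValidationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [s.__dict__ for s in summaries],
        columns=["metric", "n_positive", "n_negative",
                 "captured_fraction", "negative_correct_fraction"],
    )
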