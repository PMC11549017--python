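# Methods

`phenocell` asks, for each disease phenotype and each cell cluster of a
tissue, whether the phenotype's annotated genes behave unusually in that
cluster — either expressed more highly than the rest of the
transcriptome (differential expression) or unusually co-expressed with
one another (co-expression) — and aggregates cluster-level evidence into
per-cell-type association calls. This note records the model, the
defaults and why they are what they are, what the synthetic data does
and does not emulate, and the known limitations.

## Tissue-to-phenotype mapping

Tissues are anchored to anatomy-ontology terms; the anchor's is_a
subtree is collected, cross-links carry anatomy terms to phenotype
terms, and each linked phenotype term is expanded to its own
descendants. Candidate phenotypes are then reduced to informative,
non-redundant terms: a term is kept iff it has at least `min_genes`
(default 20) annotated genes and **no** descendant term with **more
than** `min_genes` genes. The asymmetry (`>=` to keep, strictly `>` to
disqualify) is deliberate: a descendant with exactly `min_genes` genes
does not displace its ancestor. Both readings are supported
(`strict_descendant_gt`); the strict reading is the default. The
descendant scan covers the whole phenotype graph, not only terms mapped
to the tissue — the conservative choice, since redundancy is a property
of the ontology, not of the tissue. Tissues whose informative-phenotype
list is empty are dropped from analysis with a logged notice.

Annotation files in the `phenotype_to_genes` dialect already propagate
genes up the hierarchy, so gene sets are taken at face value by default
(`annotations_propagated: true`); for raw direct-annotation tables the
loader unions a term's genes with its descendants'.

## Differential expression

Counts are pooled over all cells of a cluster (pseudobulk) and scaled to
transcripts per million, which suppresses per-cell dropout noise. The
score per gene g and cluster c is

    logFC[g,c] = log2( (TPM[g,c] + eps) / (bg[g,c] + eps) ),
    bg[g,c]    = mean of TPM[g,c'] over the other clusters in scope

with pseudocount `eps = 1` TPM. Choices the formulation leaves open:

* **log base 2** — recorded in outputs so effect sizes are interpretable;
* **pseudocount 1 TPM** — the ratio is undefined at zero TPM; additive
  smoothing preserves the invariant that a gene constant across
  clusters has logFC exactly 0;
* **background scope `within_tissue`** (default) — atlas datasets are
  organised per tissue, so "the rest of the clusters of the dataset"
  is read as the same tissue's other clusters; `whole_dataset` is
  available;
* the background is the **unweighted mean** over the other clusters,
  not a cell-count-weighted mean.

## Co-expression

Cells first pass QC: cells detecting fewer than 200 genes are dropped,
then within each cluster cells whose total count exceeds
median + 5 x MAD, then genes detected in fewer than 3 remaining cells.
These are conventional scRNA-seq thresholds and all are configurable.

Within one cluster, a cell "expresses" a gene iff its count exceeds a
threshold (default 0, i.e. any nonzero count). For a gene pair, the
2x2 table of cells (both / only first / only second / neither) yields
the **phi coefficient**

    phi = (o_yy * o_nn - o_yn * o_ny) / sqrt(r1 * r0 * c1 * c0),

identically the Pearson correlation of the two binarized vectors,
ranging over [-1, 1] with 0 at exact independence. Pairs involving a
gene with a degenerate margin (never or always expressed) get phi = 0
by convention and are flagged; no association is estimable there, and 0
keeps downstream distributions well defined. The output column is
named `coex_phi` deliberately: this is a margin-based index, **not**
COTAN's COEX, whose model-based expected counts additionally adjust for
per-cell sequencing depth. That adjustment is intentionally not
reimplemented here; the consequence is discussed under Limitations.

For tractability the all-pairs matrix is computed over a gene universe:
the union of the tissue's phenotype genes plus a seeded random
background sample of genes (`bg_gene_sample`, default 2000 — i.e. all
genes at the default synthetic scale), and the stored/background pair
sample is capped (`bg_pair_sample`, default 200 000); the set-vs-
background test needs a large background sample of pair values, not
literally every pair.

## Statistical assessment

For each (phenotype, cluster) pair and metric, a **one-sided two-sample
Kolmogorov–Smirnov test** compares the set sample against the
background sample, asking whether the set is stochastically greater
(statistic max(F_bg - F_set)):

* diffexpr: set = logFC of the phenotype's measured genes in the
  cluster; background = logFC of all other measured genes;
* coexpr: set = phi of pairs with both genes in the set; background =
  all other scored pairs (mixed pairs included by default). "Extreme"
  co-expression is operationalized as the one-sided test on |phi|
  (default `abs_greater`), so strongly negative modules also score; a
  standard two-sided test on signed values is available (`two_sided`).

P-values are asymptotic, switching to the exact conditional
distribution when the set sample has <= 10 values. Sets with fewer than
3 genes (or 3 non-degenerate pairs) are skipped with a recorded reason
and excluded from the correction family.

Benjamini–Hochberg adjustment is applied per tissue x metric family
(config `fdr_family`, `global` available). Clusters sharing a cell-type
annotation are collapsed by **minimum FDR** — one sufficiently strong
subtype suffices — and a cell type is called associated when its
minimum FDR is < .001.

Phenotype-size bias is assessed with a two-sided Mann–Whitney U test
comparing gene-set sizes of significant vs non-significant
associations (the output labels the test).

## Literature validation

Co-mention counts (articles mentioning the phenotype, the cell type,
both, and the corpus size) are scored with the upper-tail
hypergeometric probability of at least the observed overlap under
independence. Pairs with p < .001 (strict) form the positive gold set;
all other analyzed pairs — including pairs never co-mentioned — are
negatives. Precomputed p-value tables can be ingested directly,
bypassing the hypergeometric model. Reported metrics: the fraction of
positives captured (significant) and the fraction of negatives
correctly left uncalled.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at a desk scale chosen so the full pipeline runs in well under a minute
on one CPU: 2 tissues x 4 clusters x 300 cells x 1500 genes, 6
phenotypes per tissue. Components:

* **counts**: negative binomial with dispersion r = 2, per-gene
  lognormal(sigma = 1) baseline means scaled to an expected 2 500
  counts per cell, and per-cell lognormal(sigma = 0.3) library-size
  factors — the minimal generative model showing the overdispersion and
  zero inflation that binarized co-expression assumes;
* **planted differential expression**: the phenotype's gene means are
  multiplied by 2^shift (default shift 2.0) in the target cluster only;
* **planted co-expression**: within the target cluster the phenotype's
  genes share a per-cell latent on/off gate (on with p = 0.5); each
  gene follows the shared gate with probability equal to the loading
  (default 0.6), otherwise flips its own coin, and an "on" gene is
  drawn at mean mu/p so the marginal mean is exactly preserved. Gating
  induces 2x2-table dependence directly on the binarized scale, which
  is why it is used instead of correlated Gaussian noise;
* **ontology**: per tissue an anatomy anchor with a small subtree,
  linked phenotype terms, a redundant parent/child pair (the link
  points at the parent; traversal reaches the child and the
  informativeness filter must resolve to it — the child's set is drawn
  strictly above `min_genes` so the resolution is deterministic) and an
  under-annotated 19-gene decoy term;
* **gene sets are drawn disjointly** across phenotypes so planted
  signals do not bleed into decoys; real annotation sets overlap, so
  recovery numbers here are an upper bound on real-data behaviour;
* **co-mentions**: planted (phenotype, cell type) pairs receive counts
  with overwhelming overlap (p << .001) subject to a 10% false-negative
  rate; unplanted pairs receive independent-overlap counts or no record
  at all, with a 2% false-positive rate; corpus size 1e6.

All randomness flows from one seed through named `SeedSequence` spawns
(gene sets / per-cluster counts / co-mentions / baseline), so adding a
component does not perturb the others and identical configs produce
byte-identical files.

What the generator does **not** emulate: tissue-specific expression
programs, batch effects, doublets, ambient RNA, overlapping gene sets,
and real ontology depth. Passing recovery tests therefore demonstrates
correctness of the machinery under the assumed generative model, not
performance on atlas-scale data.

## Numerical choices and degenerate inputs

* TPM columns must sum to 1e6 (relative tolerance 1e-6) when produced
  internally; externally loaded tables that deviate are accepted with a
  warning.
* A scope group with a single cluster has no background and is a hard
  error, as is a cluster with zero total counts.
* Skipped tests carry reason codes (`insufficient_genes`,
  `insufficient_pairs`, `no_coex_table`) and are reported, never
  silently dropped.
* BH adjustment validates inputs in [0, 1] and clips at 1.
* Exit codes: 0 success, 2 config error, 3 data validation error,
  4 missing upstream artifact.

## Limitations

* The phi coefficient inherits a sequencing-depth artifact: per-cell
  library-size variation makes detection co-vary across genes with
  gene-specific sensitivity, so within-set pair values are not
  independent and the co-expression K-S test is mildly anticonservative
  under the null (measured null rejection at p < .05 is roughly 0.07
  at the default simulation scale, and drops to the nominal 0.05 when
  library-size variation is switched off). Depth-adjusted expected
  counts (as in COTAN) would remove this at the cost of a model fit per
  cluster; with the stringent .001 FDR call threshold the practical
  impact on calls is small.
* Minimum-FDR aggregation is the permissive reading of cell-type
  evidence: one cluster suffices, and no multiplicity correction is
  applied across clusters within a type.
* The hypergeometric co-mention model treats article sets as uniform
  random draws; real literature co-occurrence is burstier, so gold-set
  positives from real corpora are noisier than the synthetic ones.
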