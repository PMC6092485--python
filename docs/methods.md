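# Methods

This note documents the models, parameter choices and numerical
conventions behind `homoeonet`, and what its synthetic-data validation
does and does not demonstrate.

## Homoeologous group classification

Genes are partitioned by reciprocal-best-hit (RBH) logic over a
cross-subgenome protein-similarity table (12-column BLAST tabular
format). Filtering keeps hits with e-value ≤ 1e-5 **and** identity ≥ 90%
(both boundaries inclusive, matching common BLAST practice), dropping
self-hits and within-subgenome hits. The best hit of a gene toward each
foreign subgenome is the maximal-bitscore hit; bitscore is preferred
over e-value as the primary criterion because it is alignment-length
aware. Ties break deterministically: smaller e-value, then higher
identity, then lexicographically smallest subject id — so the grouping
is invariant to the order of input lines.

Classification runs in priority order:

1. **Triplet (ABD)** — three genes, one per subgenome, whose three pairs
   are all reciprocal best hits. Triplets are claimed first so their
   pairs are never double-counted as doublets.
2. **Doublet (AB/AD/BD)** — a remaining RBH pair where *neither* member
   has any filtered hit touching the third subgenome. "Has a hit" is
   evaluated in both directions (as query or as subject): a
   one-directional hit still evidences homology, so it disqualifies the
   doublet call.
3. **Unique (A/B/D)** — a gene with no filtered cross-subgenome hits at
   all.
4. **Other** — every remaining gene, as a singleton (typically genes
   with cross-subgenome homology that fails reciprocity).

The output is a partition: every catalog gene appears in exactly one
group. Input assumes one representative sequence per gene; duplicate
gene ids in the catalog are an input error.

## Expression classes

Counts are normalized to RPM (reads per million mapped reads) using
explicit per-sample mapped-read totals, defaulting to column sums when
absent. No length normalization is applied: all thresholds downstream
are calibrated to RPM. A gene is **significantly expressed** when
RPM ≥ 3 (inclusive) in at least k samples with

    k = max(1, ceil(min_sample_fraction × S)),   default fraction 0.01,

which yields k = 8 at S = 727 (the ceiling reconciles "at least eight
datasets" with "≥ 1% of 727" = 7.27 and generalizes the rule to any S).
Genes detected in 1..k−1 samples are **spatiotemporally expressed**;
genes never detected are **non-significant**. The three classes
partition the gene set by construction. Note that at small S the
default fraction gives k = 1 and the spatiotemporal class is empty;
analyses of small cohorts should raise the fraction (the bundled
examples use 0.1 at S = 80 to retain the k = 8 rule).

A triplet counts as an **expressed triplet** when all three homoeologs
are significantly expressed. The partial-expression statistic ("genes
expressed from one or two homoeologous loci") is computed as the member
genes of multi-locus groups (triplets and doublets) in which at least
one but not all members are significantly expressed.

## Signed co-expression network

Network input is log2(RPM + 1) over a chosen gene subset (typically the
homoeologs of expressed triplets). Genes with zero variance are removed
(their correlation is undefined). Adjacency is signed,

    a(i,j) = ((1 + cor(i,j)) / 2)^β,    default β = 9,

with Pearson correlation over all samples (no robust correlation in
v1), and the unsigned topological overlap is

    TOM(i,j) = (L(i,j) + a(i,j)) / (min(k_i, k_j) + 1 − a(i,j)),
    L(i,j) = Σ_{u≠i,j} a(i,u) a(u,j),   k_i = Σ_{u≠i} a(i,u).

Modules come from average-linkage agglomerative clustering of 1 − TOM
with a **static height cut**, followed by a minimum-module-size filter
(default 30) and eigengene merging. The dynamic-hybrid tree cut used in
the reference co-expression framework is deliberately replaced by this
static cut: the full PAM-stage algorithm is out of proportion to the
analysis, and module detection is validated by planted-module recovery
on synthetic data rather than by matching any external tool
gene-for-gene. The framework's `reassignThreshold` has no analogue in a
static-cut scheme and is dropped.

**Static cut height.** The default is 0.95. Two planted modules whose
latent profiles correlate at r merge under average linkage at height
≈ 1 − 2·((1+r)/2)^β, which is ≈ 0.996 at r = 0 but drops below 0.99
already at r ≈ 0.12 — a level that two independent 60-sample latent
profiles reach by chance quite often. A cut of 0.95 tolerates chance
inter-module correlation up to r ≈ 0.33 while sitting far above
within-module join heights (≤ ~0.7 at the default noise levels), and
planted-module recovery confirms the margin (median ARI 1.0 versus
0.82 at a 0.99 cut). The parameter remains user-settable for dense or
strongly correlated designs.

Module eigengenes are the first principal component (SVD) of the
member-standardized expression, scaled to unit variance and
sign-oriented so that the mean correlation with member profiles is
non-negative; the explained-variance fraction is reported. Merging is
iterative: while any module pair has eigengene dissimilarity
1 − cor < merge_cut_height (default 0.25), the closest pair merges
(ties broken toward smaller module ids) and eigengenes are recomputed.
Merging can only reduce the module count, and modules are finally
renumbered 1..M by decreasing size with 0 reserved for unassigned
genes.

Soft-power selection builds the signed adjacency for each candidate β,
bins log10 connectivity into 10 equal-occupancy bins, regresses log10
bin frequency on log10 mean connectivity, and records the signed fit
R² = −sign(slope)·R². The smallest β reaching the target (default
0.80) is chosen, else the argmax; degenerate (near-constant)
connectivity distributions score 0.

## Triplet analytics

Each expressed triplet is labeled from its members' module ids
(0 = unassigned): all three equal and ≥ 1 → **ABD**; exactly two equal
(≥ 1) with the third elsewhere → **AB-D/AD-B/BD-A**, the odd member
being the *differentiated homoeolog* — this includes the case where
the odd member is unassigned, recorded via `any_unassigned`; three
distinct assigned modules → **A-B-D**; two or three unassigned →
**NOT_CLUSTERED**. The one layout not covered by those rules — one
member unassigned and the other two in *different* modules — is
reported as A-B-D with `any_unassigned = True` and no differentiated
member, since there is no same-module pair to anchor a two-vs-one
call.

Per-sample pair bias: homoeologs x, y are differentially expressed in a
sample iff max(RPM) ≥ 3 and the fold change is ≥ 3, where a zero
denominator counts as an unbounded fold (no pseudo-count; the RPM ≥ 3
guard alone controls noise). All comparisons are inclusive. Triplet
consistency flags use the maximum over the three pairs of the per-pair
fraction of biased samples (`biased_50` at ≥ 0.50, `biased_95` at
≥ 0.95); the per-pair proportions are all reported so alternative
aggregations can be recomputed. Module differentiation summaries count
triplet homoeologs and differentiated homoeologs per module and flag
modules at proportion ≥ 0.20 (module 0 is reported but never flagged).

## Enrichment

Term over-representation uses the upper-tail hypergeometric test
(one-sided Fisher): for a term carried by K of N reference genes,
p = P(X ≥ a) for a carriers among the n study genes. Terms annotated to
more than 5,000 genes are excluded at load time (a term of exactly
5,000 genes is retained). Benjamini–Hochberg adjustment is applied
across the tested terms of one study set; significance is FDR ≤ 0.001
inclusive. Annotation transfer from model-species homologs is out of
scope — annotations are an input file.

## Synthetic data generator

The generator emulates the statistical structure of a hexaploid
transcriptome compendium, not its biology. Groups are planted directly:
triplets receive all six directed cross-subgenome hits (identity
≥ 95%, e-value ≤ 1e-30, bitscores 600–1000, mutual bests), doublets one
reciprocal pair with no hits touching the third subgenome, unique genes
no cross-subgenome hits, and decoy "other" genes a directed hit to a
triplet member with bitscore strictly below every planted best — so the
hit fails reciprocity and exercises the RBH filter. When no triplets
exist, decoys point at a designated bait decoy that emits no hits of
its own, which likewise breaks reciprocity.

Expression follows a latent-module model. Module k has a sample profile
m_k(s) ~ N(0,1) i.i.d. across samples; gene g in module k has

    log2 mean(g, s) = μ_g + β_g·m_k(s) + δ_g + ε(g, s),

with μ_g ~ U(3, 8) (log2 RPM), β_g ~ U(beta_min, beta_max) shared
within a triplet (default range 0.5–2), δ_g = log2(bias_fold) for the
up-shifted member of each biased triplet (default fold 4) and 0
otherwise, and ε ~ N(0, noise_sd²). Differentiated triplets place one
member in a different module with its own β. Spatiotemporal genes are
masked: detectable (log2 RPM clamped to ≥ log2 10) in 1..max(1,
⌈0.01·S⌉ − 1) random samples — the native 1–7 range at S = 727 — and
floored to RPM 0.05 elsewhere. Masking by construction, not a tissue
model. Bias, differentiation and spatiotemporal plantings are drawn
from disjoint gene pools when counts allow, because masking a biased or
differentiated member would destroy the very signal planted.

The per-sample expression vector is scaled to sum to 10⁶ (an RPM
scale), multiplied by the target library size (uniform ±15% around
`mean_library_size`, default 2×10⁷ mapped reads), and counts are drawn
from a Poisson at that rate. Poisson rather than negative-binomial
noise is the default because the downstream procedure is
threshold-based, not likelihood-based; the emitted library sizes are
the realized column sums, so RPM recomputed downstream conserves 10⁶
per column exactly. With `noise_sd = 0` the generator is fully
deterministic: expected (continuous) counts are emitted, so planted
ratios (exactly `bias_fold` per sample) and within-module log-profile
correlations (exactly 1) are exact — the mode used by construction
tests.

Two consequences of the RPM scaling are worth knowing. First, because
RPM denominators are column sums, all genes share a per-sample
compositional term; with a single planted module that term cancels the
latent entirely, so module-structure analyses need ≥ 2 modules.
Second, the absolute RPM floor of masked genes scales inversely with
the number of genes; spatiotemporal plantings are reliable from a few
hundred genes upward (the bundled tests use 600–1,200).

**What passing tests show.** Recovery results (module ARI,
differentiated-homoeolog sensitivity/precision, bias detection) hold
under this generative model: Poisson counts, log-normal-like latent
structure, constant multiplicative bias, and i.i.d. samples. Real
compendia add overdispersion, batch structure, correlated samples from
the same study/tissue, and mapping artifacts between near-identical
homoeologs; none of these are emulated, so synthetic recovery rates are
upper bounds, not field estimates.

## Problem sizes and determinism

All stochastic steps take explicit seeds and are reproducible
bit-for-bit. The bundled validation uses 600-gene / 60-sample
configurations for recovery benchmarks (20 seeds for module recovery,
10 for differentiation and bias) and one 3,140-gene / 80-sample run for
end-to-end invariants; these sizes give stable medians while keeping
the suite quick. Brute-force oracles (exhaustive triple enumeration,
triple-loop TOM, exact hypergeometric tails) are run at 40–300 genes
where exhaustive computation is exact and fast.

## Known limitations

- Pearson-only correlation; no bicor/robust option.
- Static-cut module detection will not reproduce the reference
  dynamic-cut tool gene-for-gene (by design); nested or
  strongly-overlapping modules are out of reach of a single global cut.
- The expression model has no gene-length effects (RPM, not RPKM/TPM)
  and no replicate structure; replicate-aware differential expression
  testing is out of scope.
- Enrichment ignores annotation-graph structure (no true-path
  propagation or semantic summarization).
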