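# homoeonet

Homoeolog co-expression network analysis for allopolyploid transcriptomes.

Allopolyploid species such as hexaploid bread wheat (*Triticum aestivum*,
AABBDD) carry near-identical gene copies — homoeologs — on each parental
subgenome. After polyploidization, homoeologs can diverge transcriptionally:
one copy may be silenced, expressed only in particular tissues, or rewired
into a different regulatory program than its two partners. `homoeonet`
provides a complete, testable pipeline for mapping that divergence from
standard inputs (a BLAST tabular protein-similarity table, a gene→subgenome
catalog, and an RNA-seq count matrix):

1. **Homoeologous groups** — reciprocal-best-hit (RBH) classification of
   genes into triplets (one homoeolog per subgenome, mutually reciprocal
   best hits across all three subgenome pairs), doublets, subgenome-unique
   genes, and "others" whose cross-subgenome homology fails reciprocity.
   Hits are filtered at e-value ≤ 1e-5 and identity ≥ 90%.
2. **Expression calling** — RPM normalization (reads per million mapped
   reads) and classification of genes as significantly expressed
   (RPM ≥ 3 in ≥ k samples, k = ⌈1% · S⌉; k = 8 at S = 727),
   spatiotemporally expressed (1..k−1 samples), or non-significant.
3. **Signed co-expression network** — the weighted co-expression framework
   with signed adjacency a(i,j) = ((1 + cor(i,j))/2)^β (default β = 9),
   unsigned topological overlap
   TOM(i,j) = (Σ_u a(i,u)a(u,j) + a(i,j)) / (min(k_i, k_j) + 1 − a(i,j)),
   average-linkage clustering of 1 − TOM with a static height cut and a
   minimum module size of 30, and iterative merging of modules whose
   eigengenes (first principal components) are closer than 0.25 in
   correlation dissimilarity. Soft-power selection by scale-free topology
   fit is included.
4. **Triplet analytics** — module-membership patterns per triplet
   (ABD, AB-D, AD-B, BD-A, A-B-D, not clustered), the *differentiated
   homoeolog* of every two-vs-one triplet, per-sample homoeolog expression
   bias (pair flagged when max RPM ≥ 3 and fold change ≥ 3), consistency
   flags at ≥ 50% and ≥ 95% of samples, and per-module summaries flagging
   modules where differentiated homoeologs make up ≥ 20% of the genes.
5. **Enrichment** — upper-tail hypergeometric term over-representation with
   Benjamini–Hochberg FDR (terms annotated to > 5,000 genes excluded,
   significance at FDR ≤ 0.001).
6. **Synthetic data** — a generator of allopolyploid catalogs, hit tables
   and count matrices with planted group structure, co-expression modules,
   homoeolog bias, differentiated homoeologs and spatiotemporal expression,
   so every stage is validated against known ground truth.

The package is a library first: import it from Python, or use the thin
`homoeonet` CLI (`simulate`, `groups`, `express`, `network`, `triplets`,
`enrich`) for file-based runs. The `examples/` directory contains one short
narrative script per capability.

## Worked example

```python
import homoeonet as hn
from sklearn.metrics import adjusted_rand_score

config = hn.SimulationConfig(
    n_triplets=200, n_doublets=0, n_unique=0, n_other=0,
    n_samples=60, n_modules=5, frac_differentiated=0.15,
    frac_spatiotemporal=0.0, noise_sd=0.3, beta_min=1.0, seed=5,
)
catalog, hits, matrix, truth = hn.simulate_dataset(config)

groups = hn.build_groups(hits, catalog)          # RBH classification
rpm = hn.compute_rpm(matrix)                      # counts -> RPM
result = hn.build_modules(rpm)                    # signed network modules

genes = list(catalog)
ari = adjusted_rand_score([truth.module_labels[g] for g in genes],
                          [result.assignment[g] for g in genes])
print(f"adjusted Rand index vs planted modules: {ari:.3f}")
```

Running `python examples/coexpression_modules.py` (the same analysis)
prints:

```
module sizes: {1: 128, 2: 127, 3: 120, 4: 114, 5: 111}
adjusted Rand index vs planted modules: 1.000
module 1: eigengene explains 93% of member variance
...
```

The five planted modules are recovered exactly (ARI = 1.0: the partition
of the 600 homoeologs into co-expression modules is identical to the
generator's ground truth up to relabeling), and each module eigengene
summarizes > 90% of its members' expression variance.
`python examples/triplet_bias_analysis.py` continues the analysis through
triplet patterns, differentiated-homoeolog detection and bias scoring.

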