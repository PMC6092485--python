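"""Call significantly / spatiotemporally / non-significantly expressed genes.

Counts are scaled to RPM (reads per million mapped reads); a gene is
significantly expressed when RPM >= 3 in at least k samples, with
k = ceil(1% of the sample count) (k = 8 at 727 samples).  Genes
detected in 1..k-1 samples are spatiotemporally expressed.
"""

import homoeonet as hn

config = hn.SimulationConfig(
    n_triplets=200, n_doublets=20, n_unique=20, n_other=10,
    n_samples=80, frac_spatiotemporal=0.08, seed=3,
)
catalog, hits, matrix, truth = hn.simulate_dataset(config)

rpm = hn.compute_rpm(matrix)
# With 80 samples a 10% fraction reproduces the k = 8 detection rule.
classes = hn.call_expression_classes(rpm, min_rpm=3, min_sample_fraction=0.1)
print(f"sample threshold k = {classes.k}")
print(f"expressed: {len(classes.expressed)}  "
      f"spatiotemporal: {len(classes.spatiotemporal)}  "
      f"non-significant: {len(classes.non_significant)}")
print(f"planted spatiotemporal genes: {len(truth.spatiotemporal_genes)}")

# Per-group expression: a triplet counts as expressed when all three
# homoeologs are significantly expressed.
groups = hn.build_groups(hits, catalog)
table, summary = hn.classify_group_expression(groups, classes)
print(f"expressed triplets: {summary['n_expressed_triplets']}")
print(f"genes in partially expressed groups: {summary['n_genes_one_or_two_loci']}")
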