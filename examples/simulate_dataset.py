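"""Generate a small synthetic hexaploid dataset and inspect its ground truth.

The generator plants homoeologous triplets/doublets/unique/decoy genes,
co-expression modules, homoeolog expression bias and spatiotemporally
expressed genes, and emits the truth labels alongside the data.
"""

import homoeonet as hn

config = hn.SimulationConfig(
    n_triplets=100, n_doublets=10, n_unique=10, n_other=5,
    n_samples=40, n_modules=4, frac_differentiated=0.1, frac_biased=0.1,
    frac_spatiotemporal=0.05, seed=7,
)
catalog, hits, matrix, truth = hn.simulate_dataset(config)

print(f"genes: {len(catalog)}  similarity hits: {len(hits)}  "
      f"samples: {matrix.values.shape[1]}")
print(f"planted modules: {config.n_modules}")
print(f"differentiated homoeologs: {len(truth.differentiated_genes)}")
print(f"biased triplets: {len(truth.biased_triplets)}")
print(f"spatiotemporal genes: {len(truth.spatiotemporal_genes)}")
# Column sums of the count matrix are the emitted library sizes, so RPM
# computed downstream conserves 1e6 per sample.
print("library size of first sample:", f"{matrix.library_sizes.iloc[0]:.0f}")
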