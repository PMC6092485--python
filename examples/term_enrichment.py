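"""Test a gene set for annotation-term over-representation.

Upper-tail hypergeometric test per term (terms annotated to more than
5,000 genes are excluded at load time), Benjamini-Hochberg FDR across
terms, significance at FDR <= 0.001.
"""

import io

import homoeonet as hn

# A toy annotation: term GO:A marks the first 30 of 200 reference genes.
lines = [f"g{i:03d}\tGO:A\tresponse to stimulus" for i in range(30)]
lines += [f"g{i:03d}\tGO:B\thousekeeping" for i in range(0, 200, 2)]
ann = hn.load_annotations(io.StringIO("\n".join(lines) + "\n"))

reference = {f"g{i:03d}" for i in range(200)}
study = {f"g{i:03d}" for i in range(25)}  # 25 genes, all carrying GO:A

results = hn.term_enrichment(study, reference, ann, alpha=0.001)
print(results[["study_count", "ref_count", "p_value", "fdr", "significant"]])
# GO:A is strongly over-represented (all 25 study genes carry it, versus
# 30 of 200 in the reference); GO:B tracks the background and is not.
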