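"""Term over-representation testing for gene sets.

A generic annotation map (term -> genes) is tested against a study set
drawn from a reference set with the upper-tail hypergeometric test
(one-sided Fisher), followed by Benjamini-Hochberg adjustment across
terms.  Terms annotated to more than ``max_term_size`` genes are
excluded at load time to curb uninformative broad terms; significance
is called at FDR <= alpha (default 0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """term id -> set of annotated gene ids, after size filtering."""

    terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)
    dropped_oversized: list[str] = field(default_factory=list)

    def genes_for(self, term: str) -> set[str]:
        return self.terms.get(term, set())


def load_annotations(
    source: str | Path | TextIO | Iterable[str], max_term_size: int = 5000
) -> AnnotationMap:
    """Load a two-column (gene_id, term_id) TSV into an annotation map.

    Terms annotated to *more than* ``max_term_size`` genes are dropped
    (and recorded); duplicate (gene, term) lines collapse.  An optional
    third column supplies a term label.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return load_annotations(fh, max_term_size)
    terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for lineno, line in enumerate(source, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected gene_id<TAB>term_id")
        gene, term = fields[0], fields[1]
        terms.setdefault(term, set()).add(gene)
        if len(fields) > 2 and fields[2]:
            labels[term] = fields[2]
    dropped = sorted(t for t, genes in terms.items() if len(genes) > max_term_size)
    for t in dropped:
        del terms[t]
    if dropped:
        logger.info("dropped %d terms annotated to more than %d genes", len(dropped), max_term_size)
    return AnnotationMap(terms, labels, dropped)


def term_enrichment(
    study: set[str],
    reference: set[str],
    ann: AnnotationMap,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of annotation terms.

    For each term with K carriers among the N reference genes, the
    p-value is P(X >= a) for a carriers among the n study genes.
    Benjamini-Hochberg adjustment is applied across the tested terms;
    ``significant`` marks fdr <= alpha (inclusive).  Results are sorted
    by (fdr, p_value, term).
    """
    study = set(study)
    reference = set(reference)
    if not reference:
        raise ValueError("reference set is empty")
    if not study <= reference:
        extra = sorted(study - reference)[:5]
        raise ValueError(f"study genes outside the reference set: {extra} ...")
    N = len(reference)
    n = len(study)
    rows = []
    for term in sorted(ann.terms):
        carriers = ann.terms[term] & reference
        K = len(carriers)
        if K == 0:
            continue
        a = len(carriers & study)
        p = float(hypergeom.sf(a - 1, N, K, n))
        p = min(p, 1.0)
        rows.append({"term": term, "label": ann.labels.get(term, ""),
                     "study_count": a, "study_size": n,
                     "ref_count": K, "ref_size": N, "p_value": p})
    if not rows:
        return pd.DataFrame(
            columns=["term", "label", "study_count", "study_size", "ref_count",
                     "ref_size", "p_value", "fdr", "significant"]
        ).set_index("term")
    table = pd.DataFrame(rows)
    _rej, fdr, _a, _b = multipletests(table["p_value"], method="fdr_bh")
    table["fdr"] = fdr
    table["significant"] = table["fdr"] <= alpha
    table = table.sort_values(["fdr", "p_value", "term"]).set_index("term")
    return table


def write_enrichment(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
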