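"""RPM normalization and expression-class calling.

Expression values are reads per million mapped reads (RPM): the raw
count scaled by the per-sample mapped-read total.  A gene is called
*significantly expressed* when its RPM reaches ``min_rpm`` in at least
``k`` samples, where k = max(1, ceil(min_sample_fraction * S)); with
727 samples and a 1% fraction this gives k = 8.  Genes detected in
1..k-1 samples are *spatiotemporally expressed*; genes never detected
are *non-significant*.  No length normalization is applied — all
downstream thresholds are calibrated to RPM.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .groups import SUBGENOMES, HomoeologGroup

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative matrix with per-sample library sizes.

    ``kind`` is ``"counts"`` or ``"rpm"``.  ``library_sizes`` holds the
    mapped-read totals used as RPM denominators; when not supplied they
    default to the column sums of the count matrix.
    """

    values: pd.DataFrame
    kind: str = "counts"
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "rpm"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative values in expression matrix")
        if self.library_sizes is None:
            if self.kind == "counts":
                logger.info("library sizes absent; using column sums of the count matrix")
                self.library_sizes = self.values.sum(axis=0)
            else:
                raise ValueError("an RPM matrix requires explicit library sizes")
        self.library_sizes = self.library_sizes.reindex(self.values.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()][0]
            raise ValueError(f"no library size for sample {missing!r}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class ExpressionClasses:
    """Partition of genes into expressed / spatiotemporal / non-significant."""

    expressed: set[str]
    spatiotemporal: set[str]
    non_significant: set[str]
    k: int
    n_detected: pd.Series = field(repr=False)

    def class_of(self, gene: str) -> str:
        if gene in self.expressed:
            return "expressed"
        if gene in self.spatiotemporal:
            return "spatiotemporal"
        return "non_significant"


def compute_rpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Scale counts to reads per million mapped reads."""
    if counts.kind != "counts":
        raise ValueError("compute_rpm expects a count matrix")
    libs = counts.library_sizes
    zero = libs.index[libs <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero[0]!r}")
    rpm = counts.values / libs.to_numpy()[np.newaxis, :] * 1e6
    return ExpressionMatrix(rpm, kind="rpm", library_sizes=libs)


def call_expression_classes(
    rpm: ExpressionMatrix,
    min_rpm: float = 3.0,
    min_sample_fraction: float = 0.01,
) -> ExpressionClasses:
    """Classify genes by the number of samples where RPM >= min_rpm."""
    if rpm.kind != "rpm":
        raise ValueError("call_expression_classes expects an RPM matrix")
    if not 0 < min_sample_fraction <= 1:
        raise ValueError("min_sample_fraction must be in (0, 1]")
    n_samples = rpm.values.shape[1]
    k = max(1, math.ceil(min_sample_fraction * n_samples))
    detected = (rpm.values >= min_rpm).sum(axis=1)
    expressed = set(detected.index[detected >= k])
    spatiotemporal = set(detected.index[(detected >= 1) & (detected < k)])
    non_significant = set(detected.index[detected == 0])
    return ExpressionClasses(expressed, spatiotemporal, non_significant, k, detected)


def classify_group_expression(
    groups: Iterable[HomoeologGroup], classes: ExpressionClasses
) -> tuple[pd.DataFrame, dict]:
    """Per-group expression status and the partial-expression statistic.

    Returns a table with one row per group (n_members, n_members_expressed,
    is_expressed_triplet) and a summary dict including the number of genes
    belonging to multi-locus groups in which only one or two of the
    homoeologous loci are significantly expressed.
    """
    known = classes.expressed | classes.spatiotemporal | classes.non_significant
    rows = []
    n_genes_one_or_two_loci = 0
    for g in groups:
        members = [g.members[s] for s in SUBGENOMES if s in g.members]
        n_expr = 0
        for m in members:
            if m not in known:
                logger.warning("group %s member %s absent from matrix; counted unexpressed", g.group_id, m)
            elif m in classes.expressed:
                n_expr += 1
        if len(members) >= 2 and 1 <= n_expr < len(members):
            n_genes_one_or_two_loci += len(members)
        rows.append(
            {
                "group_id": g.group_id,
                "type": g.type,
                "n_members": len(members),
                "n_members_expressed": n_expr,
                "is_expressed_triplet": g.type == "ABD" and n_expr == 3,
            }
        )
    table = pd.DataFrame(rows).set_index("group_id")
    summary = {
        "n_expressed_triplets": int(table["is_expressed_triplet"].sum()),
        "n_genes_one_or_two_loci": n_genes_one_or_two_loci,
    }
    return table, summary


def read_counts(
    counts_path: str | Path, libsizes_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a counts TSV (first column gene_id, remaining columns samples)
    and an optional two-column library-size TSV (sample_id, mapped_reads)."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    libs = None
    if libsizes_path is not None:
        ls = pd.read_csv(libsizes_path, sep="\t", index_col=0).iloc[:, 0]
        libs = ls.astype(float)
    return ExpressionMatrix(df.astype(float), kind="counts", library_sizes=libs)


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def write_classes(classes: ExpressionClasses, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\tn_samples_detected\n")
        for gene in classes.n_detected.index:
            fh.write(f"{gene}\t{classes.class_of(gene)}\t{int(classes.n_detected[gene])}\n")
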