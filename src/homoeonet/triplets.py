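"""Per-triplet analytics: module-membership patterns, differentiated
homoeologs, per-sample expression bias and module-level differentiation
summaries.

A *differentiated homoeolog* is the member of an expressed triplet
assigned to a co-expression module different from its two partners
(the two-vs-one patterns AB-D, AD-B, BD-A).  *Homoeolog expression
bias* in a sample is a pairwise fold-change call: the pair is biased
when the larger RPM reaches ``min_rpm`` and the fold change is at
least ``min_fold`` (a zero denominator counts as an unbounded fold).
Triplet-level consistency flags use the maximum over the three pairs
of the per-pair fraction of biased samples: ``biased_50`` at >= 50% of
samples, ``biased_95`` at >= 95%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionClasses, ExpressionMatrix
from .groups import SUBGENOMES, HomoeologGroup

PATTERNS = ("ABD", "AB-D", "AD-B", "BD-A", "A-B-D", "NOT_CLUSTERED")

_PAIRS = (("A", "B"), ("A", "D"), ("B", "D"))


@dataclass(frozen=True)
class TripletPattern:
    triplet_id: str
    pattern: str
    differentiated_member: str | None
    any_unassigned: bool
    modules: tuple[int, int, int]


@dataclass(frozen=True)
class BiasProfile:
    triplet_id: str
    pair_counts: Mapping[str, int]
    pair_proportions: Mapping[str, float]
    triplet_max_proportion: float
    biased_50: bool
    biased_95: bool


@dataclass
class DifferentiatedSet:
    """Differentiated homoeologs with their per-subgenome breakdown."""

    genes: set[str]
    counts_by_subgenome: dict[str, int]
    proportions_by_subgenome: dict[str, float]
    n_triplets: int


def classify_triplet_pattern(
    triplet: HomoeologGroup, assignment: Mapping[str, int]
) -> TripletPattern:
    """Pattern of a triplet's three module memberships (0 = unassigned).

    All three in one module -> ABD; exactly two sharing a module with
    the third elsewhere (including unassigned) -> the two-letter pattern
    with the odd member as differentiated; three distinct assigned
    modules -> A-B-D; two or three unassigned -> NOT_CLUSTERED.  The one
    unresolvable layout — one unassigned member plus two members in
    *different* modules — is reported as A-B-D with no differentiated
    member.  ``any_unassigned`` records whether a module-0 member took
    part in the call.
    """
    if triplet.type != "ABD":
        raise ValueError(f"group {triplet.group_id} is not an ABD triplet")
    mods = tuple(int(assignment.get(triplet.members[s], 0)) for s in SUBGENOMES)
    ma, mb, md = mods
    n_unassigned = sum(m == 0 for m in mods)
    any_un = n_unassigned > 0
    if n_unassigned >= 2:
        return TripletPattern(triplet.group_id, "NOT_CLUSTERED", None, any_un, mods)
    if ma == mb == md and ma >= 1:
        return TripletPattern(triplet.group_id, "ABD", None, any_un, mods)
    for (s1, s2), odd in ((("A", "B"), "D"), (("A", "D"), "B"), (("B", "D"), "A")):
        i1, i2 = SUBGENOMES.index(s1), SUBGENOMES.index(s2)
        iodd = SUBGENOMES.index(odd)
        if mods[i1] == mods[i2] and mods[i1] >= 1 and mods[iodd] != mods[i1]:
            return TripletPattern(triplet.group_id, f"{s1}{s2}-{odd}", odd, any_un, mods)
    return TripletPattern(triplet.group_id, "A-B-D", None, any_un, mods)


def differentiated_homoeologs(
    patterns: Iterable[TripletPattern],
    triplets: Mapping[str, HomoeologGroup],
) -> DifferentiatedSet:
    """The lone member of every two-vs-one triplet, with the
    per-subgenome counts and proportions (over all classified triplets)."""
    genes: set[str] = set()
    counts = {s: 0 for s in SUBGENOMES}
    n = 0
    for p in patterns:
        n += 1
        if p.differentiated_member is not None:
            genes.add(triplets[p.triplet_id].members[p.differentiated_member])
            counts[p.differentiated_member] += 1
    props = {s: (counts[s] / n if n else 0.0) for s in SUBGENOMES}
    return DifferentiatedSet(genes, counts, props, n)


def module_differentiation_summary(
    assignment: Mapping[str, int],
    differentiated: set[str],
    triplet_genes: Iterable[str],
) -> pd.DataFrame:
    """Per-module counts of triplet homoeologs and differentiated ones.

    One row per module id present among the triplet genes (including 0,
    reported but never flagged); ``high_flag`` marks modules where
    differentiated homoeologs make up >= 20% of the module's genes.
    """
    rows: dict[int, dict] = {}
    for g in triplet_genes:
        m = int(assignment.get(g, 0))
        rec = rows.setdefault(m, {"module": m, "n_genes": 0, "n_differentiated": 0})
        rec["n_genes"] += 1
        if g in differentiated:
            rec["n_differentiated"] += 1
    table = pd.DataFrame(sorted(rows.values(), key=lambda r: r["module"]))
    table["proportion"] = table["n_differentiated"] / table["n_genes"]
    table["high_flag"] = (table["proportion"] >= 0.20) & (table["module"] != 0)
    return table.set_index("module")


def pair_bias_in_sample(
    rpm_x: float, rpm_y: float, min_rpm: float = 3.0, min_fold: float = 3.0
) -> bool:
    """Is one homoeolog differentially expressed against the other in a
    sample?  True iff max(rpm) >= min_rpm and fold >= min_fold, a zero
    denominator counting as an unbounded fold."""
    hi = max(rpm_x, rpm_y)
    lo = min(rpm_x, rpm_y)
    return hi >= min_rpm and (lo == 0 or hi / lo >= min_fold)


def bias_profile(
    rpm: ExpressionMatrix,
    triplet: HomoeologGroup,
    min_rpm: float = 3.0,
    min_fold: float = 3.0,
    consistency_thresholds: tuple[float, float] = (0.50, 0.95),
) -> BiasProfile:
    """Per-pair bias sample counts and consistency flags for one triplet."""
    if triplet.type != "ABD":
        raise ValueError(f"group {triplet.group_id} is not an ABD triplet")
    profiles = {}
    for s in SUBGENOMES:
        gene = triplet.members[s]
        if gene not in rpm.values.index:
            raise KeyError(f"triplet member {gene} absent from the expression matrix")
        profiles[s] = rpm.values.loc[gene].to_numpy(dtype=float)
    n_samples = rpm.values.shape[1]
    counts: dict[str, int] = {}
    for s1, s2 in _PAIRS:
        x, y = profiles[s1], profiles[s2]
        hi = np.maximum(x, y)
        lo = np.minimum(x, y)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold_ok = (lo == 0) | (hi >= min_fold * lo)
        counts[f"{s1}{s2}"] = int(((hi >= min_rpm) & fold_ok).sum())
    props = {p: c / n_samples for p, c in counts.items()}
    max_prop = max(props.values())
    t50, t95 = consistency_thresholds
    return BiasProfile(
        triplet.group_id, counts, props, max_prop, max_prop >= t50, max_prop >= t95
    )


def summarize_triplet_catalog(
    triplets: Iterable[HomoeologGroup],
    classes: ExpressionClasses,
    patterns: Mapping[str, TripletPattern],
    profiles: Mapping[str, BiasProfile],
    assignment: Mapping[str, int],
) -> tuple[pd.DataFrame, dict]:
    """One row per ABD triplet plus a run-level summary block.

    The table joins expression classes, module memberships, pattern,
    differentiated member and pair-bias proportions; the summary holds
    pattern counts/percentages over the triplets carrying a pattern and
    the consistency-flag counts.
    """
    rows = []
    for t in triplets:
        if t.type != "ABD":
            continue
        p = patterns.get(t.group_id)
        b = profiles.get(t.group_id)
        row = {"triplet_id": t.group_id}
        for s in SUBGENOMES:
            gene = t.members[s]
            row[f"gene_{s}"] = gene
            row[f"class_{s}"] = classes.class_of(gene)
            row[f"module_{s}"] = int(assignment.get(gene, 0))
        row["pattern"] = p.pattern if p else ""
        row["differentiated_member"] = (p.differentiated_member or "") if p else ""
        row["any_unassigned"] = p.any_unassigned if p else False
        for pair in ("AB", "AD", "BD"):
            row[f"bias_prop_{pair}"] = b.pair_proportions[pair] if b else float("nan")
        row["triplet_max_proportion"] = b.triplet_max_proportion if b else float("nan")
        row["biased_50"] = b.biased_50 if b else False
        row["biased_95"] = b.biased_95 if b else False
        rows.append(row)
    table = pd.DataFrame(rows).set_index("triplet_id")
    with_pattern = table[table["pattern"] != ""]
    n = len(with_pattern)
    pattern_counts = {p: int((with_pattern["pattern"] == p).sum()) for p in PATTERNS}
    summary = {
        "n_triplets": len(table),
        "n_classified": n,
        "pattern_counts": pattern_counts,
        "pattern_percentages": {
            p: (100.0 * c / n if n else 0.0) for p, c in pattern_counts.items()
        },
        "n_biased_50": int(table["biased_50"].sum()),
        "n_biased_95": int(table["biased_95"].sum()),
    }
    return table, summary


def write_triplet_catalog(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
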