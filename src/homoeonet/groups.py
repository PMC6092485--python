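"""Homoeologous group construction from cross-subgenome similarity hits.

Genes of an allopolyploid are partitioned into homoeologous triplets
(one member per subgenome, mutually reciprocal best hits), doublets
(a reciprocal best pair with no homology evidence on the third
subgenome), subgenome-unique genes (no cross-subgenome hits at all)
and "other" genes (cross-subgenome homology that fails reciprocity).

The input is a 12-column BLAST tabular hit table plus a gene catalog
assigning every gene to one subgenome (A, B or D in hexaploid wheat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TextIO

logger = logging.getLogger(__name__)

SUBGENOMES = ("A", "B", "D")

#: group types in classification priority order
GROUP_TYPES = ("ABD", "AB", "AD", "BD", "A", "B", "D", "OTHER")


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise protein alignment record (BLAST outfmt-6 dialect).

    Mismatches, gap opens and the alignment coordinates are parsed but
    take no part in the grouping logic.
    """

    query: str
    subject: str
    identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class HomoeologGroup:
    """A classified gene group.

    ``members`` maps subgenome label -> gene id; ABD groups carry three
    entries, doublets two, unique and OTHER groups one.
    """

    group_id: str
    type: str
    members: Mapping[str, str]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.members[s] for s in SUBGENOMES if s in self.members)


def parse_similarity_hits(stream: TextIO | Iterable[str]) -> list[SimilarityHit]:
    """Parse 12-column BLAST tabular text into :class:`SimilarityHit` records.

    Blank lines and ``#`` comment lines are skipped.  Lines with fewer
    than 12 tab-separated fields, or non-numeric numeric fields, raise
    ``ValueError`` naming the offending line number.
    """
    hits: list[SimilarityHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(
                f"line {lineno}: expected >= 12 tab-separated fields, got {len(fields)}"
            )
        try:
            hit = SimilarityHit(
                query=fields[0],
                subject=fields[1],
                identity=float(fields[2]),
                alignment_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                qstart=int(fields[6]),
                qend=int(fields[7]),
                sstart=int(fields[8]),
                send=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed hit record: {exc}") from None
        hits.append(hit)
    return hits


def read_similarity_hits(path: str | Path) -> list[SimilarityHit]:
    with open(path) as fh:
        return parse_similarity_hits(fh)


def subgenome_of(label: str) -> str:
    """Subgenome letter from a catalog value: either a bare letter or a
    chromosome name such as ``"5B"`` (the trailing letter)."""
    label = label.strip()
    sub = label[-1] if len(label) > 1 else label
    if sub not in SUBGENOMES:
        raise ValueError(f"cannot derive subgenome from catalog label {label!r}")
    return sub


def read_catalog(path: str | Path) -> dict[str, str]:
    """Read a two-column gene catalog TSV (gene_id, subgenome-or-chromosome).

    Duplicate gene ids are an input error (one representative sequence
    per gene is assumed).
    """
    catalog: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 fields in catalog")
            gene, label = fields[0], fields[1]
            if gene in catalog:
                raise ValueError(f"line {lineno}: duplicate gene id {gene!r}")
            catalog[gene] = subgenome_of(label)
    return catalog


def filter_hits(
    hits: Iterable[SimilarityHit],
    catalog: Mapping[str, str],
    evalue_max: float = 1e-5,
    identity_min: float = 90.0,
) -> list[SimilarityHit]:
    """Keep cross-subgenome hits passing the similarity cutoffs.

    A hit is retained iff evalue <= evalue_max, identity >= identity_min
    (both boundaries inclusive), query != subject, and query and subject
    lie on different subgenomes.  Hits involving genes absent from the
    catalog are dropped (counted and logged).
    """
    kept: list[SimilarityHit] = []
    n_uncatalogued = 0
    for h in hits:
        qs = catalog.get(h.query)
        ss = catalog.get(h.subject)
        if qs is None or ss is None:
            n_uncatalogued += 1
            continue
        if h.query == h.subject or qs == ss:
            continue
        if h.evalue <= evalue_max and h.identity >= identity_min:
            kept.append(h)
    if n_uncatalogued:
        logger.info("dropped %d hits involving genes absent from the catalog", n_uncatalogued)
    return kept


def _better(a: SimilarityHit, b: SimilarityHit) -> bool:
    """True if hit ``a`` beats ``b``: higher bitscore, then smaller
    e-value, then higher identity, then lexicographically smaller subject."""
    ka = (-a.bitscore, a.evalue, -a.identity, a.subject)
    kb = (-b.bitscore, b.evalue, -b.identity, b.subject)
    return ka < kb


def best_cross_hits(
    hits: Iterable[SimilarityHit], catalog: Mapping[str, str]
) -> dict[tuple[str, str], str]:
    """Best subject per (query gene, foreign subgenome), by bitscore.

    Ties are broken deterministically: smaller e-value, higher identity,
    lexicographically smallest subject id.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query, catalog[h.subject])
        cur = best.get(key)
        if cur is None or _better(h, cur):
            best[key] = h
    return {key: h.subject for key, h in best.items()}


def reciprocal_best_pairs(
    best: Mapping[tuple[str, str], str], catalog: Mapping[str, str]
) -> set[frozenset[str]]:
    """Unordered cross-subgenome pairs {x, y} with mutual best hits."""
    pairs: set[frozenset[str]] = set()
    for (query, _tsub), subject in best.items():
        if best.get((subject, catalog[query])) == query:
            pairs.add(frozenset((query, subject)))
    return pairs


def classify_homoeolog_groups(
    pairs: set[frozenset[str]],
    hits: Iterable[SimilarityHit],
    catalog: Mapping[str, str],
) -> list[HomoeologGroup]:
    """Partition the catalog into ABD / doublet / unique / OTHER groups.

    Priority order: triplets are claimed first (three genes whose three
    pairs are all reciprocal best hits); then doublets — a remaining RBH
    pair where *neither* member has any filtered hit, in either
    direction, touching the third subgenome; then subgenome-unique genes
    (no filtered cross-subgenome hits at all); every remaining gene is
    an OTHER singleton.  Output is a partition: every catalog gene in
    exactly one group, deterministically ordered and numbered.
    """
    hits = list(hits)
    # RBH partner of a gene per foreign subgenome (unique under unique best hits)
    partner: dict[tuple[str, str], str] = {}
    for pair in pairs:
        x, y = tuple(pair)
        for a, b in ((x, y), (y, x)):
            key = (a, catalog[b])
            if key in partner and partner[key] != b:
                raise RuntimeError(f"gene {a} has two RBH partners on subgenome {catalog[b]}")
            partner[key] = b

    # subgenomes touched by any filtered hit, in either direction
    touched: dict[str, set[str]] = {g: set() for g in catalog}
    for h in hits:
        touched[h.query].add(catalog[h.subject])
        touched[h.subject].add(catalog[h.query])

    used: set[str] = set()
    triplets: list[tuple[str, str, str]] = []
    for a in sorted(g for g, s in catalog.items() if s == "A"):
        b = partner.get((a, "B"))
        d = partner.get((a, "D"))
        if b is None or d is None:
            continue
        if partner.get((b, "D")) == d:
            for g in (a, b, d):
                if g in used:
                    raise RuntimeError(f"gene {g} matched into two triplets")
            triplets.append((a, b, d))
            used.update((a, b, d))

    doublets: list[dict[str, str]] = []
    for pair in sorted(pairs, key=lambda p: sorted(p)):
        x, y = sorted(pair)
        if x in used or y in used:
            continue
        members = {catalog[x]: x, catalog[y]: y}
        third = next(s for s in SUBGENOMES if s not in members)
        if third not in touched[x] and third not in touched[y]:
            doublets.append(members)
            used.update((x, y))

    uniques: list[tuple[str, str]] = []
    others: list[tuple[str, str]] = []
    for g in sorted(set(catalog) - used):
        if touched[g]:
            others.append((catalog[g], g))
        else:
            uniques.append((catalog[g], g))

    groups: list[HomoeologGroup] = []
    counter = 0

    def add(gtype: str, members: dict[str, str]) -> None:
        nonlocal counter
        counter += 1
        groups.append(HomoeologGroup(f"HG{counter:06d}", gtype, dict(members)))

    for a, b, d in triplets:
        add("ABD", {"A": a, "B": b, "D": d})
    for members in doublets:
        add("".join(sorted(members)), members)
    for sub, g in uniques:
        add(sub, {sub: g})
    for sub, g in others:
        add("OTHER", {sub: g})
    return groups


def build_groups(
    hits: Iterable[SimilarityHit],
    catalog: Mapping[str, str],
    evalue_max: float = 1e-5,
    identity_min: float = 90.0,
) -> list[HomoeologGroup]:
    """Filter hits, find reciprocal best pairs and classify, in one call."""
    filtered = filter_hits(hits, catalog, evalue_max=evalue_max, identity_min=identity_min)
    best = best_cross_hits(filtered, catalog)
    pairs = reciprocal_best_pairs(best, catalog)
    return classify_homoeolog_groups(pairs, filtered, catalog)


def write_groups(groups: Iterable[HomoeologGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\ttype\tgene_A\tgene_B\tgene_D\n")
        for g in groups:
            fh.write(
                f"{g.group_id}\t{g.type}\t"
                f"{g.members.get('A', '')}\t{g.members.get('B', '')}\t{g.members.get('D', '')}\n"
            )


def read_groups(path: str | Path) -> list[HomoeologGroup]:
    groups: list[HomoeologGroup] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("group_id"):
            raise ValueError("groups file lacks the expected header")
        for line in fh:
            gid, gtype, ga, gb, gd = line.rstrip("\n").split("\t")
            members = {s: g for s, g in zip(SUBGENOMES, (ga, gb, gd)) if g}
            groups.append(HomoeologGroup(gid, gtype, members))
    return groups
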