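"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: best hits by linear
scan, reciprocity by scanning all hit pairs, triplets by exhaustive
enumeration of all cross-subgenome triples, TOM by triple-nested loops,
and hypergeometric tails by exact combinatorial enumeration.
"""

from __future__ import annotations

from math import comb

import numpy as np

SUBGENOMES = ("A", "B", "D")


def oracle_best_hits(hits, catalog):
    """Best subject per (query, foreign subgenome) by linear scan with the
    full tie-break chain (bitscore, evalue, identity, subject id)."""
    best = {}
    for h in hits:
        key = (h.query, catalog[h.subject])
        cur = best.get(key)
        if cur is None:
            best[key] = h
            continue
        a = (-h.bitscore, h.evalue, -h.identity, h.subject)
        b = (-cur.bitscore, cur.evalue, -cur.identity, cur.subject)
        if a < b:
            best[key] = h
    return {k: h.subject for k, h in best.items()}


def oracle_rbh_pairs(hits, catalog):
    best = oracle_best_hits(hits, catalog)
    pairs = set()
    for (q, _t), s in best.items():
        if best.get((s, catalog[q])) == q:
            pairs.add(frozenset((q, s)))
    return pairs


def oracle_classify(hits, catalog):
    """Exhaustive classification: enumerate all (a, b, d) triples and check
    the three reciprocal-best conditions directly; then doublets, uniques
    and others by definition.  Returns gene -> type label."""
    pairs = oracle_rbh_pairs(hits, catalog)
    by_sub = {s: sorted(g for g, sg in catalog.items() if sg == s) for s in SUBGENOMES}
    touched = {g: set() for g in catalog}
    for h in hits:
        touched[h.query].add(catalog[h.subject])
        touched[h.subject].add(catalog[h.query])

    labels = {}
    in_triplet = set()
    for a in by_sub["A"]:
        for b in by_sub["B"]:
            if frozenset((a, b)) not in pairs:
                continue
            for d in by_sub["D"]:
                if frozenset((a, d)) in pairs and frozenset((b, d)) in pairs:
                    for g in (a, b, d):
                        labels[g] = "ABD"
                        in_triplet.add(g)
    for pair in pairs:
        x, y = tuple(pair)
        if x in in_triplet or y in in_triplet:
            continue
        subs = {catalog[x], catalog[y]}
        third = next(s for s in SUBGENOMES if s not in subs)
        if third not in touched[x] and third not in touched[y]:
            t = "".join(sorted(subs))
            labels[x] = t
            labels[y] = t
    for g in catalog:
        if g in labels:
            continue
        labels[g] = catalog[g] if not touched[g] else "OTHER"
    return labels


def oracle_tom(adj: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap by triple-nested loops."""
    n = adj.shape[0]
    tom = np.ones((n, n))
    k = np.array([sum(adj[i, u] for u in range(n) if u != i) for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(adj[i, u] * adj[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (L + adj[i, j]) / (min(k[i], k[j]) + 1 - adj[i, j])
    return tom


def oracle_hypergeom_tail(a: int, N: int, K: int, n: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, n) by exact enumeration."""
    total = comb(N, n)
    upper = min(K, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(a, upper + 1)) / total


def random_hit_instance(rng, n_genes=40):
    """A random catalog + hit table exercising ties and decoys."""
    from homoeonet.groups import SimilarityHit

    catalog = {}
    for i in range(n_genes):
        catalog[f"g{i:03d}"] = SUBGENOMES[int(rng.integers(0, 3))]
    genes = list(catalog)
    hits = []
    n_hits = int(rng.integers(n_genes, 4 * n_genes))
    for _ in range(n_hits):
        q, s = rng.choice(genes, size=2, replace=False)
        if catalog[q] == catalog[s]:
            continue
        bitscore = float(rng.choice([200.0, 300.0, 400.0, 500.0]))  # ties likely
        evalue = float(rng.choice([1e-50, 1e-30, 1e-10]))
        identity = float(rng.choice([91.0, 95.0, 99.0]))
        hits.append(SimilarityHit(q, s, identity, 300, 5, 1, 1, 300, 1, 300,
                                  evalue, bitscore))
    return catalog, hits
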