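"""Synthetic allopolyploid datasets with known ground truth.

The generator emulates a hexaploid gene set: homoeologous triplets
(one gene per subgenome, mutual reciprocal best hits), doublets,
subgenome-unique genes and decoy "other" genes whose hits fail
reciprocity.  Expression follows a latent-module model: each planted
module k has a sample profile m_k(s) ~ N(0,1); gene g in module k has

    log2 mean(g, s) = mu_g + beta_g * m_k(s) + delta_g + eps(g, s)

with beta_g drawn per group, delta_g the planted homoeolog log2-bias
offset (log2(bias_fold) for one member of each biased triplet), and
eps ~ N(0, noise_sd^2).  Counts are Poisson with rate proportional to
2^log2mean scaled to the sample library size; with noise_sd = 0 the
expected counts are emitted directly (a fully deterministic mode in
which planted ratios and correlations are exact).  Differentiated
triplets place one member in a different module; spatiotemporal genes
are masked below the detection floor in all but a few samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .groups import SUBGENOMES, SimilarityHit

#: RPM level guaranteed in the retained samples of a masked gene
_SPAT_HI_LOG2RPM = math.log2(10.0)
#: RPM level of masked samples, far below the detection threshold
_SPAT_LO_LOG2RPM = math.log2(0.05)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic allopolyploid dataset.

    Counts of planted group types, sample/module numbers, and the
    fractions of triplets carrying planted differentiation (one member
    in another module) or expression bias (one member offset by
    ``bias_fold``), plus the fraction of genes expressed in only a few
    samples.  ``noise_sd`` is the standard deviation of the log2-scale
    residual; ``mean_library_size`` the mapped reads per sample.
    """

    n_triplets: int = 200
    n_doublets: int = 20
    n_unique: int = 20
    n_other: int = 10
    n_samples: int = 60
    n_modules: int = 5
    frac_differentiated: float = 0.15
    frac_biased: float = 0.15
    bias_fold: float = 4.0
    frac_spatiotemporal: float = 0.05
    noise_sd: float = 0.3
    mean_library_size: int = 20_000_000
    seed: int = 0
    beta_min: float = 0.5
    beta_max: float = 2.0
    mu_min: float = 3.0
    mu_max: float = 8.0

    def __post_init__(self) -> None:
        for name in ("frac_differentiated", "frac_biased", "frac_spatiotemporal"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_triplets < 0 or self.n_doublets < 0 or self.n_unique < 0 or self.n_other < 0:
            raise ValueError("group counts must be non-negative")
        if self.n_triplets + self.n_doublets + self.n_unique + self.n_other == 0:
            raise ValueError("at least one gene must be generated")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.bias_fold < 1:
            raise ValueError("bias_fold must be >= 1")
        if self.frac_differentiated > 0 and self.n_modules < 2:
            raise ValueError("differentiated triplets require n_modules >= 2")
        if self.n_other > 0 and self.n_triplets == 0 and self.n_other < 2:
            raise ValueError("decoy hits need triplets or at least two 'other' genes")
        if not 0 < self.beta_min <= self.beta_max:
            raise ValueError("need 0 < beta_min <= beta_max")


@dataclass
class GroundTruth:
    """Planted labels emitted alongside the synthetic data."""

    group_labels: dict[str, str] = field(default_factory=dict)
    triplet_members: dict[str, dict[str, str]] = field(default_factory=dict)
    module_labels: dict[str, int] = field(default_factory=dict)
    differentiated_genes: set[str] = field(default_factory=set)
    biased_pairs: set[tuple[str, tuple[str, str], float]] = field(default_factory=set)
    biased_triplets: set[str] = field(default_factory=set)
    differentiated_triplets: set[str] = field(default_factory=set)
    spatiotemporal_genes: set[str] = field(default_factory=set)


def _hit(rng: np.random.Generator, query: str, subject: str,
         identity: float, evalue: float, bitscore: float) -> SimilarityHit:
    length = int(rng.integers(200, 600))
    mism = int(round(length * (100.0 - identity) / 100.0))
    return SimilarityHit(
        query=query, subject=subject, identity=round(identity, 2),
        alignment_length=length, mismatches=mism, gap_opens=int(rng.integers(0, 4)),
        qstart=1, qend=length, sstart=1, send=length,
        evalue=evalue, bitscore=round(bitscore, 1),
    )


def _strong_hit(rng: np.random.Generator, query: str, subject: str) -> SimilarityHit:
    identity = float(rng.uniform(95.0, 99.5))
    evalue = 10.0 ** float(rng.uniform(-180.0, -50.0))
    bitscore = float(rng.uniform(600.0, 1000.0))
    return _hit(rng, query, subject, identity, evalue, bitscore)


def simulate_catalog(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[SimilarityHit], GroundTruth]:
    """Generate the gene catalog, similarity-hit table and group truth.

    Triplets get all six directed cross-subgenome hits (identity >= 95,
    e-value <= 1e-30, mutual bests); doublets one reciprocal pair and no
    hits touching the third subgenome; unique genes no cross-subgenome
    hits; "other" genes a decoy hit that fails reciprocity (a directed
    hit to a triplet member with bitscore strictly below the planted
    best, or a one-directional hit to another decoy when no triplets
    exist).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    catalog: dict[str, str] = {}
    hits: list[SimilarityHit] = []
    truth = GroundTruth()

    triplet_genes: list[tuple[str, str]] = []  # (gene, subgenome) decoy targets
    for t in range(config.n_triplets):
        tid = f"T{t:05d}"
        members = {s: f"{tid}_{s}" for s in SUBGENOMES}
        for s, g in members.items():
            catalog[g] = s
            truth.group_labels[g] = "ABD"
            triplet_genes.append((g, s))
        truth.triplet_members[tid] = members
        for s1 in SUBGENOMES:
            for s2 in SUBGENOMES:
                if s1 != s2:
                    hits.append(_strong_hit(rng, members[s1], members[s2]))

    pair_choices = ("AB", "AD", "BD")
    for d in range(config.n_doublets):
        pair = pair_choices[int(rng.integers(0, 3))]
        members = {s: f"DB{d:05d}_{s}" for s in pair}
        for s, g in members.items():
            catalog[g] = s
            truth.group_labels[g] = pair
        g1, g2 = (members[s] for s in pair)
        hits.append(_strong_hit(rng, g1, g2))
        hits.append(_strong_hit(rng, g2, g1))

    for u in range(config.n_unique):
        s = SUBGENOMES[int(rng.integers(0, 3))]
        g = f"U{u:05d}_{s}"
        catalog[g] = s
        truth.group_labels[g] = s

    other_genes: list[tuple[str, str]] = []
    for o in range(config.n_other):
        s = SUBGENOMES[int(rng.integers(0, 3))]
        g = f"O{o:05d}_{s}"
        catalog[g] = s
        truth.group_labels[g] = "OTHER"
        other_genes.append((g, s))
    if other_genes and not triplet_genes:
        # bait scheme: the first decoy never emits hits, so no reciprocal
        # pair can form among the decoys pointing at it
        bait, bait_sub = other_genes[0]
        if all(s == bait_sub for _g, s in other_genes):
            g1, _ = other_genes[1]
            new_s = next(x for x in SUBGENOMES if x != bait_sub)
            catalog[g1] = new_s
            other_genes[1] = (g1, new_s)
    for i, (g, s) in enumerate(other_genes):
        if triplet_genes:
            # decoy: directed hit to a triplet member on another subgenome,
            # with bitscore strictly below every planted best (>= 600)
            foreign = [(tg, ts) for tg, ts in triplet_genes if ts != s]
            target, _ts = foreign[int(rng.integers(0, len(foreign)))]
        else:
            if i == 0:
                continue  # the bait only receives hits
            bait, bait_sub = other_genes[0]
            if s != bait_sub:
                target = bait
            else:
                # same subgenome as the bait: point at any decoy on a
                # different subgenome (one exists by construction; such a
                # decoy's own best is the bait, so reciprocity still fails)
                target = next(og for og, os_ in other_genes if os_ != s)
        identity = float(rng.uniform(90.5, 94.5))
        evalue = 10.0 ** float(rng.uniform(-60.0, -20.0))
        bitscore = float(rng.uniform(100.0, 400.0))
        hits.append(_hit(rng, g, target, identity, evalue, bitscore))

    return catalog, hits, truth


def _choose(rng: np.random.Generator, items: list, n: int) -> list:
    if n <= 0:
        return []
    idx = rng.choice(len(items), size=min(n, len(items)), replace=False)
    return [items[i] for i in sorted(idx)]


def simulate_expression(
    catalog: dict[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Generate the count matrix and update the truth with module labels,
    bias pairs and spatiotemporal genes.

    Returns (counts, library_sizes, truth); the emitted library sizes
    are the column sums of the count matrix, so RPM computed from them
    conserves the per-column total of 1e6.
    """
    genes = list(catalog)
    for g in genes:
        if g not in truth.group_labels:
            raise ValueError(f"catalog gene {g} missing from truth labels")
    rng = np.random.default_rng([config.seed, 1])
    S = config.n_samples
    samples = [f"S{j:03d}" for j in range(S)]
    latent = rng.standard_normal((config.n_modules + 1, S))  # row 0 unused

    tids = sorted(truth.triplet_members)
    n_diff = int(round(config.frac_differentiated * len(tids)))
    n_bias = int(round(config.frac_biased * len(tids)))
    diff_tids = set(_choose(rng, tids, n_diff))
    # biased triplets are drawn from the non-differentiated pool when possible,
    # so the planted bias signal is not confounded by module differentiation
    bias_pool = [t for t in tids if t not in diff_tids]
    if len(bias_pool) < n_bias:
        bias_pool = tids
    bias_tids = set(_choose(rng, bias_pool, n_bias))
    truth.differentiated_triplets = diff_tids
    truth.biased_triplets = bias_tids

    module_of: dict[str, int] = {}
    mu: dict[str, float] = {}
    beta: dict[str, float] = {}
    delta: dict[str, float] = {}

    def draw_mu() -> float:
        return float(rng.uniform(config.mu_min, config.mu_max))

    def draw_beta() -> float:
        return float(rng.uniform(config.beta_min, config.beta_max))

    def draw_module() -> int:
        return int(rng.integers(1, config.n_modules + 1))

    protected: set[str] = set()  # genes whose planted signal masking would destroy
    for tid in tids:
        members = truth.triplet_members[tid]
        m = draw_module()
        mu_t, beta_t = draw_mu(), draw_beta()
        for s, g in members.items():
            module_of[g] = m
            mu[g] = mu_t
            beta[g] = beta_t
            delta[g] = 0.0
        if tid in diff_tids:
            odd = SUBGENOMES[int(rng.integers(0, 3))]
            alt = draw_module()
            while alt == m:
                alt = draw_module()
            module_of[members[odd]] = alt
            beta[members[odd]] = draw_beta()
            truth.differentiated_genes.add(members[odd])
            protected.update(members.values())
        if tid in bias_tids:
            up = SUBGENOMES[int(rng.integers(0, 3))]
            delta[members[up]] = math.log2(config.bias_fold)
            log_fold = math.log2(config.bias_fold)
            for s in SUBGENOMES:
                if s != up:
                    truth.biased_pairs.add((tid, (members[up], members[s]), log_fold))
            protected.update(members.values())

    for g in genes:
        if g not in module_of:  # doublet / unique / other genes
            module_of[g] = draw_module()
            mu[g] = draw_mu()
            beta[g] = draw_beta()
            delta[g] = 0.0
    truth.module_labels = dict(module_of)

    n_spat = int(round(config.frac_spatiotemporal * len(genes)))
    spat_eligible = [g for g in genes if g not in protected]
    spat_genes = _choose(rng, spat_eligible, n_spat)
    truth.spatiotemporal_genes = set(spat_genes)

    gene_order = genes
    log2mean = np.empty((len(gene_order), S))
    for i, g in enumerate(gene_order):
        log2mean[i] = mu[g] + beta[g] * latent[module_of[g]] + delta[g]
    if config.noise_sd > 0:
        log2mean += rng.normal(0.0, config.noise_sd, size=log2mean.shape)

    # spatiotemporal masking: detectable in 1 .. max(1, ceil(0.01 S) - 1)
    # samples (the native 1-7 range at S = 727), floored elsewhere
    hi_max = max(1, math.ceil(0.01 * S) - 1)
    spat_index = {g: i for i, g in enumerate(gene_order)}
    for g in spat_genes:
        i = spat_index[g]
        n_hi = int(rng.integers(1, hi_max + 1))
        keep = rng.choice(S, size=n_hi, replace=False)
        row = np.full(S, _SPAT_LO_LOG2RPM)
        row[keep] = np.maximum(log2mean[i, keep], _SPAT_HI_LOG2RPM)
        log2mean[i] = row

    target_libs = np.round(
        rng.uniform(0.85, 1.15, size=S) * config.mean_library_size
    ).astype(np.int64)
    # scale intended expression to an RPM scale (1e6 per sample) so that
    # RPM recomputed downstream from column sums matches the planted
    # levels and the detection thresholds they are calibrated to
    rel = np.exp2(log2mean)
    rel = rel / rel.sum(axis=0, keepdims=True) * 1e6
    rate = rel * (target_libs / 1e6)[np.newaxis, :]
    if config.noise_sd > 0:
        counts = rng.poisson(rate).astype(float)
    else:
        counts = rate  # deterministic mode: expected counts, exact ratios
    values = pd.DataFrame(counts, index=gene_order, columns=samples)
    library_sizes = values.sum(axis=0)
    matrix = ExpressionMatrix(values, kind="counts", library_sizes=library_sizes)
    return matrix, library_sizes, truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[SimilarityHit], ExpressionMatrix, GroundTruth]:
    """Catalog, hits and counts in one call."""
    catalog, hits, truth = simulate_catalog(config)
    matrix, _libs, truth = simulate_expression(catalog, truth, config)
    return catalog, hits, matrix, truth


# ---------------------------------------------------------------- writers

def write_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.identity}\t{h.alignment_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.qstart}\t{h.qend}\t"
                f"{h.sstart}\t{h.send}\t{h.evalue:.3e}\t{h.bitscore}\n"
            )


def write_catalog(catalog: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, s in catalog.items():
            fh.write(f"{g}\t{s}\n")


def write_counts(matrix: ExpressionMatrix, counts_path: str | Path,
                 libsizes_path: str | Path) -> None:
    matrix.values.to_csv(counts_path, sep="\t", index_label="gene_id")
    with open(libsizes_path, "w") as fh:
        fh.write("sample_id\tmapped_reads\n")
        for s, v in matrix.library_sizes.items():
            fh.write(f"{s}\t{v:.6g}\n")


def write_truth(truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    with open(outdir / "truth_groups.tsv", "w") as fh:
        fh.write("gene_id\tgroup_label\n")
        for g in sorted(truth.group_labels):
            fh.write(f"{g}\t{truth.group_labels[g]}\n")
    with open(outdir / "truth_modules.tsv", "w") as fh:
        fh.write("gene_id\tmodule\n")
        for g in sorted(truth.module_labels):
            fh.write(f"{g}\t{truth.module_labels[g]}\n")
    with open(outdir / "truth_differentiated.tsv", "w") as fh:
        fh.write("gene_id\n")
        for g in sorted(truth.differentiated_genes):
            fh.write(f"{g}\n")
    with open(outdir / "truth_spatiotemporal.tsv", "w") as fh:
        fh.write("gene_id\n")
        for g in sorted(truth.spatiotemporal_genes):
            fh.write(f"{g}\n")
    with open(outdir / "truth_biased_pairs.tsv", "w") as fh:
        fh.write("triplet_id\tgene_high\tgene_low\tlog2_fold\n")
        for tid, (hi, lo), lf in sorted(truth.biased_pairs):
            fh.write(f"{tid}\t{hi}\t{lo}\t{lf:.6g}\n")


def read_config_file(path: str | Path) -> SimulationConfig:
    """Parse a flat key-value config file (``key = value`` or ``key: value``)."""
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":", "\t"):
                if sep in line:
                    key, val = line.split(sep, 1)
                    raw[key.strip()] = val.strip()
                    break
            else:
                raise ValueError(f"cannot parse config line: {line!r}")
    kwargs = {}
    valid = {f.name: f.type for f in dc_fields(SimulationConfig)}
    for key, val in raw.items():
        if key not in valid:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[key] = float(val) if "." in val or "e" in val.lower() else int(val)
    return SimulationConfig(**kwargs)
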