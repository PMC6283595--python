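"""Synthetic two-TAD locus generator with known ground truth.

The generator emulates the data structure of a gene cluster sitting at the
boundary between two regulatory TADs (a centromeric "cdom" and a telomeric
"tdom"): a random locus sequence carrying restriction sites at a target
fragment density, distance-decaying viewpoint contacts whose allocation
between the two TADs switches with the cell condition, an insulated
block-structured contact matrix, and ChIP/input read sets with enrichment
blocks over active regions. Every draw is seeded; identical config + seed
give byte-identical outputs.

Default conditions mirror a proximal/distal limb regulatory switch: the
viewpoint directs 26% of its domain contacts to cdom in the "proximal"
condition and 51% in the "distal" condition (telomeric fractions 0.74 and
0.49, a reallocation of 0.25), at an expected 4C depth of 1e5 counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from zlib import crc32

from .chic import PAIR_COLUMNS
from .locus import (
    DomainAnnotation,
    FragmentMap,
    GenomicInterval,
    assign_fragments,
    digest_genome,
    midpoint_mask,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Synthetic CTCF-like position weight matrix: asymmetric 13-bp core with a
# dominant consensus base per column. A stand-in constructed for this
# package's simulations, not derived from any curated motif database.
CTCF_CONSENSUS = "CCACCAGGGGGCG"


def default_ctcf_pwm(strength: float = 0.85) -> np.ndarray:
    """Column-stochastic 4 x 13 PWM concentrated on the synthetic consensus."""
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    pwm = np.full((4, len(CTCF_CONSENSUS)), (1 - strength) / 3)
    for j, base in enumerate(CTCF_CONSENSUS):
        pwm[order[base], j] = strength
    return pwm


@dataclass(frozen=True)
class EnhancerSpec:
    """A named regulatory region with per-condition activity multipliers."""

    interval: GenomicInterval
    strength: Mapping[str, float]  # condition -> multiplier (1.0 = inactive)


def _default_enhancers(
    cdom: GenomicInterval, tdom: GenomicInterval
) -> dict[str, EnhancerSpec]:
    """Enhancer regions at fixed relative positions within the domains.

    Telomeric-domain enhancers are active proximally, centromeric ones
    distally; region_a sits at the cluster-proximal edge of tdom.
    """

    def at(dom: GenomicInterval, frac: float, width: int,
           label: str) -> GenomicInterval:
        width = min(width, dom.length // 10)
        start = dom.start + int(frac * dom.length)
        return GenomicInterval(dom.chrom, start, start + width, label)

    return {
        "CS39": EnhancerSpec(at(tdom, 0.47, 10_000, "CS39"),
                             {"proximal": 4.0, "distal": 2.0}),
        "CS93": EnhancerSpec(at(tdom, 0.73, 8_000, "CS93"),
                             {"proximal": 3.0, "distal": 1.2}),
        "island_III": EnhancerSpec(at(cdom, 0.33, 8_000, "island_III"),
                                   {"proximal": 1.0, "distal": 3.0}),
        "Prox": EnhancerSpec(at(cdom, 0.58, 8_000, "Prox"),
                             {"proximal": 1.0, "distal": 4.0}),
        "region_a": EnhancerSpec(at(tdom, 0.008, 5_000, "region_a"),
                                 {"proximal": 4.0, "distal": 1.0}),
    }


@dataclass
class SyntheticLocusConfig:
    """Full generative parameterization of the synthetic locus.

    ``rho`` is the per-condition fraction of domain-directed viewpoint
    contacts allocated to cdom (the remainder goes to tdom), so the
    telomeric contact fraction is 1 - rho. ``decay_exponent`` is the
    contact-probability distance exponent (P ~ d^-alpha);
    ``insulation_factor`` attenuates contacts straddling the planted
    boundary. Depths are expected total counts per assay.
    """

    chrom: str = "chrS"
    locus_length: int = 3_000_000
    enzyme_site: str = "CATG"
    median_fragment_bp: int = 1_500
    cdom: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chrS", 200_000, 1_400_000, "cdom")
    )
    cluster: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chrS", 1_410_000, 1_460_000, "cluster")
    )
    tdom: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chrS", 1_470_000, 2_600_000, "tdom")
    )
    next_tad: Optional[GenomicInterval] = field(
        default_factory=lambda: GenomicInterval("chrS", 2_600_000, 3_000_000, "next_tad")
    )
    enhancer_regions: dict[str, EnhancerSpec] = field(default_factory=dict)
    decay_exponent: float = 1.0
    rho: dict[str, float] = field(
        default_factory=lambda: {"proximal": 0.26, "distal": 0.51}
    )
    cluster_signal_frac: float = 0.05
    next_tad_signal_frac: float = 0.05
    boundary_pos: Optional[int] = None  # default: cluster midpoint
    insulation_factor: float = 0.2
    depth: int = 100_000
    chic_depth: int = 400_000
    chip_depth: int = 200_000
    low_mapq_frac: float = 0.05
    noise: str = "poisson"  # poisson | negative_binomial
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.enhancer_regions:
            self.enhancer_regions = _default_enhancers(self.cdom, self.tdom)
        if self.boundary_pos is None:
            self.boundary_pos = self.cluster.midpoint
        for name, iv in [("cdom", self.cdom), ("tdom", self.tdom),
                         ("cluster", self.cluster), ("next_tad", self.next_tad)]:
            if iv is not None and iv.end > self.locus_length:
                raise ValueError(f"{name} exceeds the locus length")
        for label, spec in self.enhancer_regions.items():
            if spec.interval.end > self.locus_length:
                raise ValueError(f"enhancer {label} exceeds the locus length")
        for cond, r in self.rho.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rho[{cond}] must be in [0, 1]")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not 0.0 < self.insulation_factor <= 1.0:
            raise ValueError("insulation_factor must be in (0, 1]")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, 0, self.locus_length, "locus")

    def annotation(self) -> DomainAnnotation:
        return DomainAnnotation(
            cdom=self.cdom,
            tdom=self.tdom,
            cluster=self.cluster,
            next_tad=self.next_tad,
            named_regions={l: s.interval for l, s in self.enhancer_regions.items()},
        )

    def bait(self) -> GenomicInterval:
        mid = self.cluster.midpoint
        return GenomicInterval(self.chrom, mid - 500, mid + 500, "viewpoint")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    fractions: dict[str, dict[str, float]]  # condition -> {cdom, tdom} shares
    boundary_pos: int
    enhancer_strengths: dict[str, Mapping[str, float]]
    ctcf_sites: list[tuple[int, str]]
    seed: int

    def boundary_bin(self, bin_size: int, span_start: int = 0) -> int:
        return (self.boundary_pos - span_start) // bin_size


@dataclass
class SyntheticLocus:
    config: SyntheticLocusConfig
    sequences: dict[str, str]
    fragment_map: FragmentMap
    annotation: DomainAnnotation
    truth: GroundTruth


def _mutate_out_sites(arr: np.ndarray, site: np.ndarray,
                      rng: np.random.Generator) -> None:
    """Destroy every occurrence of the site in-place (iterates to fixpoint)."""
    m = len(site)
    for _ in range(20):
        hits = np.ones(len(arr) - m + 1, dtype=bool)
        for j in range(m):
            hits &= arr[j: len(arr) - m + 1 + j] == site[j]
        idx = np.flatnonzero(hits)
        if len(idx) == 0:
            return
        # overlapping occurrences share mutated positions; that is fine
        alternatives = _BASES[_BASES != site[1]]
        arr[idx + 1] = rng.choice(alternatives, size=len(idx))
    raise RuntimeError("failed to clear restriction sites from random sequence")


def generate_locus(config: SyntheticLocusConfig,
                   seed: Optional[int] = None) -> SyntheticLocus:
    """Random locus sequence with restriction sites at a target density.

    Fragment lengths are drawn uniformly in [0.5, 1.5] x the target median,
    so the expected fragment count is locus_length / median. Accidental
    occurrences of the recognition site in the random background are
    mutated away before the planned sites are stamped in, and synthetic
    CTCF motifs are planted convergently around the cluster. The fragment
    map is obtained by digesting the finished sequence, so it is consistent
    with the sequence by construction.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    L = config.locus_length
    site = np.frombuffer(config.enzyme_site.upper().encode(), dtype=np.uint8)
    arr = rng.choice(_BASES, size=L)
    _mutate_out_sites(arr, site, rng)
    # plan cut positions from fragment-length draws
    target = config.median_fragment_bp
    n_draw = int(2.5 * L / target) + 10
    lengths = rng.uniform(0.5 * target, 1.5 * target, size=n_draw)
    cuts = np.cumsum(lengths).astype(np.int64)
    cuts = cuts[cuts < L - len(site)]
    for c in cuts:
        arr[c: c + len(site)] = site
    # plant convergent CTCF motifs flanking the cluster
    motif = np.frombuffer(CTCF_CONSENSUS.encode(), dtype=np.uint8)
    rc = np.frombuffer(_revcomp_str(CTCF_CONSENSUS).encode(), dtype=np.uint8)
    ctcf_sites = [
        (config.cluster.start - 5_000, "+"),
        (config.cluster.end + 5_000, "-"),
    ]
    for pos, strand in ctcf_sites:
        arr[pos: pos + len(motif)] = motif if strand == "+" else rc
    sequence = arr.tobytes().decode()
    sequences = {config.chrom: sequence}
    fragment_map = digest_genome(sequences, config.enzyme_site)
    truth = GroundTruth(
        fractions={
            cond: {"cdom": r, "tdom": 1.0 - r} for cond, r in config.rho.items()
        },
        boundary_pos=int(config.boundary_pos),
        enhancer_strengths={
            l: dict(s.strength) for l, s in config.enhancer_regions.items()
        },
        ctcf_sites=ctcf_sites,
        seed=seed,
    )
    return SyntheticLocus(
        config=config,
        sequences=sequences,
        fragment_map=fragment_map,
        annotation=config.annotation(),
        truth=truth,
    )


def _revcomp_str(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _draw_counts(rng: np.random.Generator, mu: np.ndarray,
                 config: SyntheticLocusConfig) -> np.ndarray:
    if config.noise == "poisson":
        return rng.poisson(mu)
    # gamma-Poisson mixture: Var = mu + dispersion * mu^2
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu * config.dispersion)
    return rng.poisson(lam)


def simulate_fourc(locus: SyntheticLocus, condition: str,
                   seed: Optional[int] = None) -> np.ndarray:
    """Raw per-fragment 4C counts for one condition.

    Expected counts decay with distance from the bait (d^-alpha, softened
    within 1 kb), are multiplied by the condition's enhancer strengths, and
    are budgeted so the cdom : tdom split of domain-directed signal is
    exactly rho : 1-rho; small fixed budgets go to the cluster itself and
    to the next TAD. Counts are then drawn per fragment from the configured
    noise model.
    """
    config = locus.config
    if condition not in config.rho:
        raise KeyError(f"unknown condition {condition!r}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, 1, crc32(condition.encode())])
    fm = locus.fragment_map
    annotation = locus.annotation
    bait_mid = config.bait().midpoint
    mids = fm.midpoints
    decay = 1.0 / np.maximum(np.abs(mids - bait_mid), 1_000.0) ** config.decay_exponent
    mult = np.ones(len(fm))
    for label, spec in config.enhancer_regions.items():
        mask = midpoint_mask(fm, spec.interval)
        mult[mask] *= spec.strength.get(condition, 1.0)
    weight = decay * mult
    masks = assign_fragments(fm, annotation)
    cluster_mask = midpoint_mask(fm, config.cluster)
    rho = config.rho[condition]
    p_next = config.next_tad_signal_frac if config.next_tad is not None else 0.0
    p_cluster = config.cluster_signal_frac
    p_main = 1.0 - p_next - p_cluster
    budgets = {
        "cdom": p_main * rho,
        "tdom": p_main * (1.0 - rho),
    }
    if config.next_tad is not None:
        budgets["next_tad"] = p_next
    mu = np.zeros(len(fm))
    for label, budget in budgets.items():
        m = masks[label]
        total = weight[m].sum()
        if total > 0:
            mu[m] = config.depth * budget * weight[m] / total
    if cluster_mask.any():
        total = weight[cluster_mask].sum()
        mu[cluster_mask] = config.depth * p_cluster * weight[cluster_mask] / total
    return _draw_counts(rng, mu, config).astype(float)


def simulate_chic(locus: SyntheticLocus, condition: str,
                  seed: Optional[int] = None, cell_bp: int = 10_000,
                  depth: Optional[int] = None) -> pd.DataFrame:
    """Contact-pair table for one condition.

    Pair probability over a coarse position grid decays with distance
    (d^-alpha), is attenuated by the insulation factor across the planted
    boundary, and carries symmetric enhancer-cluster stripes scaled by the
    condition's strengths. Cell counts are Poisson; mate positions are
    uniform within their cell. A configured fraction of pairs receives a
    sub-threshold mapping quality on one mate.
    """
    config = locus.config
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, 2, crc32(condition.encode())])
    if depth is None:
        depth = config.chic_depth
    n = config.locus_length // cell_bp
    centers = (np.arange(n) + 0.5) * cell_bp
    d = np.abs(centers[:, None] - centers[None, :])
    mu = 1.0 / np.maximum(d, cell_bp) ** config.decay_exponent
    straddle = (centers[:, None] < config.boundary_pos) != (
        centers[None, :] < config.boundary_pos
    )
    mu = np.where(straddle, mu * config.insulation_factor, mu)
    cluster_cells = (centers >= config.cluster.start) & (centers < config.cluster.end)
    for label, spec in config.enhancer_regions.items():
        s = spec.strength.get(condition, 1.0)
        if s == 1.0:
            continue
        enh_cells = (centers >= spec.interval.start) & (centers < spec.interval.end)
        block = np.ix_(enh_cells, cluster_cells)
        mu[block] *= s
        mu[np.ix_(cluster_cells, enh_cells)] *= s
    iu = np.triu_indices(n)
    probs = mu[iu] / mu[iu].sum()
    counts = rng.poisson(depth * probs)
    ci = np.repeat(iu[0], counts)
    cj = np.repeat(iu[1], counts)
    m = len(ci)
    pos1 = ci * cell_bp + rng.integers(0, cell_bp, size=m)
    pos2 = cj * cell_bp + rng.integers(0, cell_bp, size=m)
    mapq1 = rng.integers(30, 61, size=m)
    mapq2 = rng.integers(30, 61, size=m)
    low = rng.random(m) < config.low_mapq_frac
    which = rng.random(m) < 0.5
    bad_q = rng.integers(0, 30, size=m)
    mapq1 = np.where(low & which, bad_q, mapq1)
    mapq2 = np.where(low & ~which, bad_q, mapq2)
    swap = pos1 > pos2
    p1 = np.where(swap, pos2, pos1)
    p2 = np.where(swap, pos1, pos2)
    q1 = np.where(swap, mapq2, mapq1)
    q2 = np.where(swap, mapq1, mapq2)
    return pd.DataFrame(
        {
            "chrom1": config.chrom,
            "pos1": p1,
            "chrom2": config.chrom,
            "pos2": p2,
            "mapq1": q1,
            "mapq2": q2,
        },
        columns=PAIR_COLUMNS,
    )


def simulate_chip(locus: SyntheticLocus, state: Mapping[str, float],
                  seed: Optional[int] = None, n_reads: Optional[int] = None,
                  read_length: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ChIP and input read intervals for a given enrichment state.

    ``state`` maps region labels to fold enrichments. Input reads are
    uniform over the locus; ChIP reads are a mixture of a uniform
    background and region-concentrated components so the read density
    inside a region is fold x the background density. Because libraries
    are later scaled to their own totals, realized enrichments sit at
    log2(fold) minus a small compression term that vanishes as the
    enriched area fraction goes to zero.
    """
    config = locus.config
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([seed, 3, crc32(repr(sorted(state.items())).encode())])
    if n_reads is None:
        n_reads = config.chip_depth
    L = config.locus_length

    def _uniform_reads(count: int, lo: int, hi: int) -> pd.DataFrame:
        starts = rng.integers(lo, max(lo + 1, hi - read_length), size=count)
        strands = np.where(rng.random(count) < 0.5, "+", "-")
        return pd.DataFrame(
            {
                "chrom": config.chrom,
                "start": starts,
                "end": starts + read_length,
                "strand": strands,
            }
        )

    input_df = _uniform_reads(n_reads, 0, L)
    components: list[tuple[float, int, int]] = [(float(L), 0, L)]
    for label, fold in state.items():
        iv = config.enhancer_regions[label].interval
        if fold < 1.0:
            raise ValueError("fold enrichment must be >= 1 in this generator")
        if fold > 1.0:
            components.append(((fold - 1.0) * iv.length, iv.start, iv.end))
    weights = np.array([c[0] for c in components])
    alloc = rng.multinomial(n_reads, weights / weights.sum())
    parts = [
        _uniform_reads(count, lo, hi)
        for count, (_, lo, hi) in zip(alloc, components)
        if count > 0
    ]
    chip_df = pd.concat(parts, ignore_index=True)
    order = np.argsort(chip_df["start"].to_numpy(), kind="stable")
    return chip_df.iloc[order].reset_index(drop=True), input_df
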