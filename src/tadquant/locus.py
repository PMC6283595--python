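"""Genomic coordinate backbone: intervals, restriction fragment maps, domain annotation.

All coordinates are 0-based half-open internally (BED convention). 1-based
coordinates appear only in log messages.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np

_VALID_SITE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        """Half-open containment: start inclusive, end exclusive."""
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def pad_region(region: GenomicInterval, pad_bp: int) -> GenomicInterval:
    """Symmetric padding, clamped at position 0.

    Mirrors the convention of quantifying a named region plus/minus a fixed
    margin (default 10 kb elsewhere in this package).
    """
    if pad_bp < 0:
        raise ValueError("pad_bp must be >= 0")
    return GenomicInterval(
        region.chrom, max(0, region.start - pad_bp), region.end + pad_bp, region.name
    )


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling one or more chromosomes.

    Fragments are sorted by (chrom, start), tile each chromosome without gaps
    or overlaps, and are indexed by a dense integer fragment id equal to the
    list position.
    """

    fragments: list[GenomicInterval]
    enzyme_site: str = ""

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for frag in self.fragments:
            by_chrom.setdefault(frag.chrom, []).append(frag)
        for chrom, frags in by_chrom.items():
            prev_end = frags[0].start
            for frag in frags:
                if frag.start != prev_end:
                    raise ValueError(
                        f"fragments do not tile {chrom}: gap/overlap at {frag.start}"
                    )
                prev_end = frag.end

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for frag in self.fragments:
            seen.setdefault(frag.chrom, None)
        return list(seen)

    @property
    def midpoints(self) -> np.ndarray:
        return np.array([f.midpoint for f in self.fragments], dtype=np.int64)

    @property
    def chrom_array(self) -> np.ndarray:
        return np.array([f.chrom for f in self.fragments])

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of the fragments on one chromosome."""
        idx = [i for i, f in enumerate(self.fragments) if f.chrom == chrom]
        if not idx:
            raise KeyError(f"no fragments on {chrom}")
        return slice(idx[0], idx[-1] + 1)

    def locate(self, chrom: str, pos: int) -> int:
        """Fragment id containing a position (half-open containment)."""
        for i, frag in enumerate(self.fragments):
            if frag.contains(chrom, pos):
                return i
        raise KeyError(f"position {chrom}:{pos} not covered by fragment map")


def digest_genome(
    sequences: Mapping[str, str], site: str
) -> FragmentMap:
    """In-silico restriction digestion.

    A cut is placed at the start coordinate of every occurrence of the
    recognition ``site`` (overlapping occurrences each cut). The first
    fragment starts at 0 and the last ends at the chromosome length;
    zero-length fragments arising from a terminal site occurrence are
    dropped.
    """
    site = site.upper()
    if len(site) < 2 or not _VALID_SITE.match(site):
        raise ValueError(f"invalid recognition site {site!r}: need >=2 bases of ACGT")
    pattern = re.compile(f"(?={re.escape(site)})")
    fragments: list[GenomicInterval] = []
    for chrom, seq in sequences.items():
        if not seq:
            raise ValueError(f"empty sequence for {chrom}")
        seq_u = seq.upper()
        if not set(seq_u) <= set("ACGTN"):
            raise ValueError(f"sequence for {chrom} contains non-ACGTN characters")
        cuts = [m.start() for m in pattern.finditer(seq_u)]
        edges = [0] + cuts + [len(seq_u)]
        for a, b in zip(edges, edges[1:]):
            if b > a:
                fragments.append(GenomicInterval(chrom, a, b))
    return FragmentMap(fragments=fragments, enzyme_site=site)


@dataclass
class DomainAnnotation:
    """Named regulatory-domain intervals around a gene cluster.

    ``cdom`` and ``tdom`` are the two flanking TADs (centromeric and
    telomeric regulatory domains); ``next_tad`` is the optional further TAD
    used by the three-domain normalization; ``cluster`` is the gene cluster,
    excludable from fraction sums. ``named_regions`` map labels (enhancer
    regions, borders, ...) to intervals quantified with +/- ``pad_bp``
    padding.
    """

    cdom: GenomicInterval
    tdom: GenomicInterval
    cluster: GenomicInterval
    next_tad: Optional[GenomicInterval] = None
    named_regions: dict[str, GenomicInterval] = field(default_factory=dict)
    pad_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.pad_bp < 0:
            raise ValueError("pad_bp must be >= 0")
        domains = self.domains()
        labels = list(domains)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if domains[a].overlaps(domains[b]):
                    raise ValueError(f"domains {a} and {b} overlap")

    def domains(self) -> dict[str, GenomicInterval]:
        out = {"cdom": self.cdom, "tdom": self.tdom}
        if self.next_tad is not None:
            out["next_tad"] = self.next_tad
        return out

    def padded_region(self, label: str) -> GenomicInterval:
        return pad_region(self.named_regions[label], self.pad_bp)


def assign_domain(
    item: Union[GenomicInterval, int],
    annotation: DomainAnnotation,
    chrom: Optional[str] = None,
) -> Optional[str]:
    """Assign a fragment or point to the unique domain containing it.

    Fragments are assigned by their midpoint (mirroring fragment-middle read
    assignment and preventing double counting of boundary-straddling
    fragments); point inputs by half-open containment. Returns None outside
    all domains.
    """
    if isinstance(item, GenomicInterval):
        chrom, pos = item.chrom, item.midpoint
    else:
        if chrom is None:
            raise ValueError("point assignment requires a chromosome name")
        pos = int(item)
    for label, dom in annotation.domains().items():
        if dom.contains(chrom, pos):
            return label
    return None


def assign_fragments(
    fragment_map: FragmentMap, annotation: DomainAnnotation
) -> dict[str, np.ndarray]:
    """Boolean mask per domain label over all fragments (midpoint rule)."""
    masks = {label: np.zeros(len(fragment_map), dtype=bool)
             for label in annotation.domains()}
    for i, frag in enumerate(fragment_map.fragments):
        label = assign_domain(frag, annotation)
        if label is not None:
            masks[label][i] = True
    return masks


def midpoint_mask(
    fragment_map: FragmentMap, region: GenomicInterval
) -> np.ndarray:
    """Boolean mask of fragments whose midpoint falls inside ``region``."""
    mask = np.zeros(len(fragment_map), dtype=bool)
    for i, frag in enumerate(fragment_map.fragments):
        if region.contains(frag.chrom, frag.midpoint):
            mask[i] = True
    return mask
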