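"""ChIP-seq quantification: binned coverage, log2 ChIP/input ratios,
region enrichment, 1x-depth scaling, and CTCF motif orientation.

Reads enter as interval tables (chrom, start, end, strand). Following the
binned-comparison convention, each read is first extended to a fixed
fragment length from its 5' end (default 300 bp), coverage is binned
(default 25 bp), each library is scaled to reads per million (RPM), and the
per-bin ratio is log2((chip + eps) / (input + eps)) with pseudocount
eps = 0.5 applied on the RPM scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .locus import GenomicInterval

DEFAULT_BIN_SIZE = 25
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_READ_EXTENSION = 300

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class BinnedTrack:
    span: GenomicInterval
    bin_size: int
    values: np.ndarray
    scale_mode: str = "counts"  # counts | rpm | one_x | log2_ratio
    n_reads: int = 0
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    read_extension: int = DEFAULT_READ_EXTENSION

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.values = np.asarray(self.values, dtype=float)
        n_bins = -(-self.span.length // self.bin_size)
        if len(self.values) != n_bins:
            raise ValueError(f"expected {n_bins} bins, got {len(self.values)}")

    @property
    def n_bins(self) -> int:
        return len(self.values)


def extend_reads(reads: pd.DataFrame, read_extension: int) -> pd.DataFrame:
    """Extend each read to ``read_extension`` bp from its 5' end.

    Plus-strand reads extend rightward from start, minus-strand leftward
    from end (clamped at 0). Extension 0 leaves reads untouched. Reads
    without a strand column are treated as plus-strand.
    """
    if read_extension < 0:
        raise ValueError("read_extension must be >= 0")
    out = reads.copy()
    if read_extension == 0:
        return out
    strand = out["strand"].to_numpy() if "strand" in out else np.full(len(out), "+")
    start = out["start"].to_numpy(dtype=np.int64)
    end = out["end"].to_numpy(dtype=np.int64)
    plus = strand != "-"
    out["start"] = np.where(plus, start, np.maximum(0, end - read_extension))
    out["end"] = np.where(plus, start + read_extension, end)
    return out


def bin_coverage(
    reads: pd.DataFrame,
    span: GenomicInterval,
    bin_size: int = DEFAULT_BIN_SIZE,
    read_extension: int = DEFAULT_READ_EXTENSION,
) -> BinnedTrack:
    """Count, per bin, the reads whose extended interval overlaps the bin."""
    n_bins = -(-span.length // bin_size)
    ext = extend_reads(reads, read_extension)
    ext = ext[ext["chrom"] == span.chrom]
    start = np.maximum(ext["start"].to_numpy(dtype=np.int64), span.start)
    end = np.minimum(ext["end"].to_numpy(dtype=np.int64), span.end)
    keep = start < end
    start, end = start[keep], end[keep]
    first = (start - span.start) // bin_size
    last = -(-(end - span.start) // bin_size) - 1
    delta = np.zeros(n_bins + 1, dtype=float)
    np.add.at(delta, first, 1.0)
    np.add.at(delta, last + 1, -1.0)
    values = np.cumsum(delta[:-1])
    return BinnedTrack(
        span=span,
        bin_size=bin_size,
        values=values,
        scale_mode="counts",
        n_reads=len(reads),
        read_extension=read_extension,
    )


def _to_rpm(track: BinnedTrack) -> np.ndarray:
    if track.n_reads <= 0:
        raise ValueError("track has zero total reads")
    return track.values * (1e6 / track.n_reads)


def log2_ratio_track(
    chip: BinnedTrack,
    input_: BinnedTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BinnedTrack:
    """Per-bin log2 ratio of RPM-scaled ChIP over input.

    Each library is scaled to reads per million of its own total first, so
    the track is invariant to sequencing depth up to pseudocount effects;
    the pseudocount keeps every bin finite.
    """
    if chip.bin_size != input_.bin_size or chip.span != input_.span:
        raise ValueError("chip and input tracks must share span and binning")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    ratio = np.log2((_to_rpm(chip) + pseudocount) / (_to_rpm(input_) + pseudocount))
    return BinnedTrack(
        span=chip.span,
        bin_size=chip.bin_size,
        values=ratio,
        scale_mode="log2_ratio",
        n_reads=chip.n_reads,
        pseudocount=pseudocount,
        read_extension=chip.read_extension,
    )


@dataclass
class RegionEnrichment:
    region: str
    enrichment: float
    chip_reads: float  # RPM over the region
    input_reads: float


def region_enrichment(
    chip_reads: pd.DataFrame,
    input_reads: pd.DataFrame,
    region: GenomicInterval,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    read_extension: int = DEFAULT_READ_EXTENSION,
) -> RegionEnrichment:
    """log2 enrichment of ChIP over input within one region.

    Reads are assigned by extended-interval overlap; each library's count is
    scaled to RPM before the ratio.
    """

    def _rpm(reads: pd.DataFrame) -> float:
        total = len(reads)
        if total == 0:
            raise ValueError("library has zero reads")
        ext = extend_reads(reads, read_extension)
        hit = (
            (ext["chrom"] == region.chrom)
            & (ext["start"] < region.end)
            & (ext["end"] > region.start)
        )
        return float(hit.sum()) * 1e6 / total

    chip_rpm = _rpm(chip_reads)
    input_rpm = _rpm(input_reads)
    enr = float(np.log2((chip_rpm + pseudocount) / (input_rpm + pseudocount)))
    return RegionEnrichment(
        region=region.name or str(region),
        enrichment=enr,
        chip_reads=chip_rpm,
        input_reads=input_rpm,
    )


def normalize_1x(
    track: BinnedTrack, read_length: int, effective_genome_size: int
) -> BinnedTrack:
    """Scale binned counts so genome-wide mean coverage equals 1x.

    The scale factor is effective_genome_size / (total reads x read length);
    the effective genome size is a required input, never guessed.
    """
    if effective_genome_size <= 0:
        raise ValueError("effective_genome_size must be > 0")
    if track.n_reads <= 0:
        raise ValueError("track has zero total reads")
    factor = effective_genome_size / (track.n_reads * read_length)
    return BinnedTrack(
        span=track.span,
        bin_size=track.bin_size,
        values=track.values * factor,
        scale_mode="one_x",
        n_reads=track.n_reads,
        read_extension=track.read_extension,
    )


@dataclass
class MotifOrientationCall:
    peak: Optional[GenomicInterval]
    strand: str  # "+", "-" or "ambiguous"
    score: float
    position: int


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _scan_log_odds(seq: str, logodds: np.ndarray) -> tuple[float, int]:
    m = logodds.shape[1]
    best, best_pos = -np.inf, -1
    for i in range(len(seq) - m + 1):
        score = 0.0
        for j in range(m):
            idx = _BASE_INDEX.get(seq[i + j])
            if idx is None:  # N or other ambiguity: neutral contribution
                continue
            score += logodds[idx, j]
        if score > best:
            best, best_pos = score, i
    return best, best_pos


def call_motif_orientation(
    sequence: str,
    pwm: np.ndarray,
    tie_tolerance: float = 1e-6,
    peak: Optional[GenomicInterval] = None,
) -> MotifOrientationCall:
    """Orient a motif (e.g. the CTCF site) under a peak by best PWM hit.

    The PWM is a 4 x m column-stochastic matrix (rows A, C, G, T). Both
    strands are scanned with log2-odds scores against a uniform background;
    the strand with the larger best score wins, and calls within
    ``tie_tolerance`` are "ambiguous". Positions are starts on the forward
    sequence.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape[0] != 4:
        raise ValueError("pwm must have 4 rows (A, C, G, T)")
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("pwm columns must each sum to 1")
    m = pwm.shape[1]
    seq = sequence.upper()
    if len(seq) < m:
        raise ValueError("sequence shorter than motif")
    logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    fwd_score, fwd_pos = _scan_log_odds(seq, logodds)
    rev_score, rev_pos_rc = _scan_log_odds(revcomp(seq), logodds)
    rev_pos = len(seq) - m - rev_pos_rc
    if abs(fwd_score - rev_score) < tie_tolerance:
        return MotifOrientationCall(peak, "ambiguous", fwd_score, fwd_pos)
    if fwd_score > rev_score:
        return MotifOrientationCall(peak, "+", fwd_score, fwd_pos)
    return MotifOrientationCall(peak, "-", rev_score, rev_pos)
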