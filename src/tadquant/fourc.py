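"""4C-seq viewpoint profile quantification.

A viewpoint (bait) profile is a nonnegative score per restriction fragment.
Processing follows the standard viewpoint pipeline: per-fragment scores are
normalized to the mean score of fragments within a window around the bait
(default +/- 1 Mb; +/- 2 Mb is the convention for deletion alleles whose
window would otherwise be dominated by the rearrangement), then smoothed
with an 11-fragment running mean for display. Domain contact fractions and
paired differential tests operate on the normalized, unsmoothed scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .locus import (
    DomainAnnotation,
    FragmentMap,
    GenomicInterval,
    assign_fragments,
    midpoint_mask,
)
from .stats import PairedTestResult, wilcoxon_signed_rank

DEFAULT_NORM_WINDOW_BP = 1_000_000
DELETION_NORM_WINDOW_BP = 2_000_000
DEFAULT_SMOOTH_FRAGS = 11


@dataclass
class FourCProfile:
    fragment_map: FragmentMap
    bait: GenomicInterval
    raw: np.ndarray
    normalized: Optional[np.ndarray] = None
    smoothed: Optional[np.ndarray] = None
    excluded: frozenset[int] = frozenset()
    norm_window_bp: int = DEFAULT_NORM_WINDOW_BP
    smooth_window_frags: int = DEFAULT_SMOOTH_FRAGS

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != len(self.fragment_map):
            raise ValueError("raw score length does not match fragment map")
        if np.any(self.raw < 0):
            raise ValueError("raw scores must be nonnegative")
        if self.smooth_window_frags < 1 or self.smooth_window_frags % 2 == 0:
            raise ValueError("smoothing window must be an odd integer >= 1")

    @property
    def excluded_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.fragment_map), dtype=bool)
        if self.excluded:
            mask[list(self.excluded)] = True
        return mask


def default_bait_exclusion(
    fragment_map: FragmentMap, bait: GenomicInterval
) -> frozenset[int]:
    """Bait fragment plus its two flanking fragments.

    These carry self-ligation and undigested-template artifacts, so they are
    masked by default; an explicit exclusion list overrides this.
    """
    bait_id = fragment_map.locate(bait.chrom, bait.midpoint)
    ids = {bait_id}
    chrom_range = fragment_map.chrom_slice(bait.chrom)
    if bait_id - 1 >= chrom_range.start:
        ids.add(bait_id - 1)
    if bait_id + 1 < chrom_range.stop:
        ids.add(bait_id + 1)
    return frozenset(ids)


def normalize_profile(
    fragment_map: FragmentMap,
    raw: Sequence[float] | np.ndarray,
    bait: GenomicInterval,
    norm_window_bp: int = DEFAULT_NORM_WINDOW_BP,
    excluded: Optional[Iterable[int]] = None,
    smooth_window_frags: int = DEFAULT_SMOOTH_FRAGS,
) -> FourCProfile:
    """Normalize fragment scores to the mean score near the bait.

    The window holds fragments whose midpoint lies within
    ``bait midpoint +/- norm_window_bp`` on the bait chromosome, excluded
    fragments removed. Every fragment — inside the window or not — is
    divided by that window mean, so the normalized profile has unit mean
    over in-window, non-excluded fragments.
    """
    if excluded is None:
        excl = default_bait_exclusion(fragment_map, bait)
    else:
        excl = frozenset(int(i) for i in excluded)
    profile = FourCProfile(
        fragment_map=fragment_map,
        bait=bait,
        raw=np.asarray(raw, dtype=float),
        excluded=excl,
        norm_window_bp=norm_window_bp,
        smooth_window_frags=smooth_window_frags,
    )
    bait_mid = bait.midpoint
    window = GenomicInterval(
        bait.chrom, max(0, bait_mid - norm_window_bp), bait_mid + norm_window_bp
    )
    in_window = midpoint_mask(fragment_map, window) & ~profile.excluded_mask
    if not in_window.any():
        raise ValueError("no non-excluded fragment in normalization window")
    window_mean = profile.raw[in_window].mean()
    if window_mean == 0:
        raise ValueError("no signal in normalization window")
    normalized = profile.raw / window_mean
    normalized[profile.excluded_mask] = 0.0
    profile.normalized = normalized
    profile.smoothed = smooth_profile(profile, smooth_window_frags)
    return profile


def smooth_profile(profile: FourCProfile, k: Optional[int] = None) -> np.ndarray:
    """Running mean over up-to-k fragments centered on each fragment.

    The window is truncated at chromosome ends rather than emitting missing
    values; excluded fragments are omitted from both numerator and count.
    Windows never cross a chromosome boundary.
    """
    if k is None:
        k = profile.smooth_window_frags
    if k < 1 or k % 2 == 0:
        raise ValueError("smoothing window must be an odd integer >= 1")
    if profile.normalized is None:
        raise ValueError("profile must be normalized before smoothing")
    half = k // 2
    values = np.where(profile.excluded_mask, 0.0, profile.normalized)
    weight = (~profile.excluded_mask).astype(float)
    out = np.zeros_like(values)
    for chrom in profile.fragment_map.chroms:
        sl = profile.fragment_map.chrom_slice(chrom)
        v, w = values[sl], weight[sl]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        cw = np.concatenate([[0.0], np.cumsum(w)])
        n = len(v)
        idx = np.arange(n)
        lo = np.maximum(0, idx - half)
        hi = np.minimum(n, idx + half + 1)
        num = csum[hi] - csum[lo]
        den = cw[hi] - cw[lo]
        with np.errstate(invalid="ignore"):
            out[sl] = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
    return out


@dataclass
class ContactFractionReport:
    """Per-domain contact fractions of one viewpoint profile.

    ``fractions`` sum to 1 over ``domain_set``; ``region_fractions`` hold
    named-region sums (with padding) over the same denominator, so they are
    comparable to the domain fractions but do not themselves sum to 1.
    """

    fractions: dict[str, float]
    denominator: float
    domain_set: tuple[str, ...]
    cluster_excluded: bool
    region_fractions: dict[str, float] = field(default_factory=dict)


def domain_fractions(
    profile: FourCProfile,
    annotation: DomainAnnotation,
    domain_set: Sequence[str] = ("cdom", "tdom"),
    exclude_cluster: bool = False,
    use_raw: bool = False,
    named_regions: bool = True,
) -> ContactFractionReport:
    """Contact fraction of each domain, normalized over ``domain_set``.

    The signal summed is the normalized, unsmoothed per-fragment score
    (``use_raw=True`` switches to raw scores). The denominator is the total
    over the listed domains — {cdom, tdom} by default, {cdom, tdom,
    next_tad} for the three-domain convention used with deletion alleles.
    Cluster fragments can be excluded from every sum.
    """
    signal = profile.raw if use_raw else profile.normalized
    if signal is None:
        raise ValueError("profile must be normalized first")
    signal = np.where(profile.excluded_mask, 0.0, signal)
    if exclude_cluster:
        signal = np.where(
            midpoint_mask(profile.fragment_map, annotation.cluster), 0.0, signal
        )
    masks = assign_fragments(profile.fragment_map, annotation)
    missing = [d for d in domain_set if d not in masks]
    if missing:
        raise ValueError(f"domains not annotated: {missing}")
    sums = {d: float(signal[masks[d]].sum()) for d in domain_set}
    denominator = sum(sums.values())
    if denominator <= 0:
        raise ValueError("zero total signal over the requested domain set")
    fractions = {d: s / denominator for d, s in sums.items()}
    region_fracs: dict[str, float] = {}
    if named_regions:
        for label in annotation.named_regions:
            region = annotation.padded_region(label)
            mask = midpoint_mask(profile.fragment_map, region)
            region_fracs[label] = float(signal[mask].sum()) / denominator
    return ContactFractionReport(
        fractions=fractions,
        denominator=denominator,
        domain_set=tuple(domain_set),
        cluster_excluded=exclude_cluster,
        region_fractions=region_fracs,
    )


def _resolve_region(
    region: Union[str, GenomicInterval], annotation: Optional[DomainAnnotation]
) -> tuple[str, GenomicInterval]:
    if isinstance(region, GenomicInterval):
        return region.name or str(region), region
    if annotation is None:
        raise ValueError("a region label requires an annotation")
    if region in annotation.named_regions:
        return region, annotation.padded_region(region)
    domains = annotation.domains()
    if region in domains:
        return region, domains[region]
    raise KeyError(f"unknown region {region!r}")


def compare_region_signal(
    profile_a: FourCProfile,
    profile_b: FourCProfile,
    region: Union[str, GenomicInterval],
    annotation: Optional[DomainAnnotation] = None,
) -> PairedTestResult:
    """Paired two-sided signed-rank test of per-fragment signal in a region.

    Both profiles must share one fragment map. Fragments pair by identity;
    fragments excluded in either profile are dropped. When an annotation is
    supplied, ``delta_fraction`` reports the change of the region's contact
    fraction (condition B minus condition A) over the two-domain
    denominator.
    """
    if profile_a.fragment_map is not profile_b.fragment_map and [
        (f.chrom, f.start, f.end) for f in profile_a.fragment_map.fragments
    ] != [(f.chrom, f.start, f.end) for f in profile_b.fragment_map.fragments]:
        raise ValueError("profiles must share one fragment map")
    if profile_a.normalized is None or profile_b.normalized is None:
        raise ValueError("profiles must be normalized first")
    label, interval = _resolve_region(region, annotation)
    mask = midpoint_mask(profile_a.fragment_map, interval)
    mask &= ~profile_a.excluded_mask & ~profile_b.excluded_mask
    stat, p, n = wilcoxon_signed_rank(
        profile_b.normalized[mask], profile_a.normalized[mask]
    )
    delta = float("nan")
    if annotation is not None:
        rep_a = domain_fractions(profile_a, annotation, named_regions=False)
        rep_b = domain_fractions(profile_b, annotation, named_regions=False)
        frac_a = float(
            np.where(profile_a.excluded_mask, 0.0, profile_a.normalized)[mask].sum()
        ) / rep_a.denominator
        frac_b = float(
            np.where(profile_b.excluded_mask, 0.0, profile_b.normalized)[mask].sum()
        ) / rep_b.denominator
        delta = frac_b - frac_a
    return PairedTestResult(
        region=label, n_pairs=n, statistic=stat, p_value=p, delta_fraction=delta
    )
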