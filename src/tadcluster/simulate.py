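"""Synthetic block-structured contact matrices with planted domains.

A TAD appears in a contact matrix as a square block of elevated contact
frequency on the diagonal. The generator plants such blocks at chosen bin
ranges: cells whose two bins fall in the same domain are drawn around
``intra_mean``, all other cells around ``inter_mean``, optionally damped by
a power-law distance decay, perturbed with truncated Gaussian (or Poisson)
noise, symmetrized, and zeroed at gap bins. The planted domain ranges are
returned as a ground-truth TadSet so recovery can be measured exactly.

Defaults (intra_mean 10, inter_mean 2, noise_sd 1 over 30 bins) emulate a
small simulated benchmark chromosome with five domains whose boundaries
every clustering algorithm should recover at K = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .domains import GAP, SegmentClass, TadSet, segments_from_labels
from .matrix import ContactMatrix, PeakSet

__all__ = [
    "PlantedSpec",
    "TABLE_DOMAINS_1BASED",
    "default_benchmark_spec",
    "generate_block_matrix",
    "generate_nested_matrix",
    "generate_boundary_peaks",
]

#: The five-domain truth of the 30-bin benchmark, 1-based inclusive ranges.
TABLE_DOMAINS_1BASED: tuple[tuple[int, int], ...] = (
    (1, 8), (9, 14), (15, 20), (21, 25), (26, 30),
)


@dataclass
class PlantedSpec:
    """Parameters of a planted-domain contact matrix."""

    n_bins: int
    domains: Sequence[tuple[int, int]]  # 0-based inclusive, sorted, disjoint
    intra_mean: float = 10.0
    inter_mean: float = 2.0
    noise_sd: float = 1.0
    gap_bins: frozenset[int] = field(default_factory=frozenset)
    distance_decay: float = 0.0
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        doms = sorted(self.domains)
        for (s1, e1), (s2, e2) in zip(doms, doms[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping domains ({s1},{e1}) and ({s2},{e2})")
        for s, e in doms:
            if not (0 <= s <= e < self.n_bins):
                raise ValueError(f"domain ({s},{e}) outside [0, {self.n_bins - 1}]")
        if self.intra_mean <= self.inter_mean:
            raise ValueError("intra_mean must exceed inter_mean")
        if self.noise_sd < 0 or self.distance_decay < 0:
            raise ValueError("noise_sd and distance_decay must be non-negative")
        self.domains = tuple(doms)


def default_benchmark_spec(seed: int = 0, noise_sd: float = 1.0) -> PlantedSpec:
    """The 30-bin five-domain benchmark (0-based conversion of the 1-based truth)."""
    domains = tuple((s - 1, e - 1) for s, e in TABLE_DOMAINS_1BASED)
    return PlantedSpec(n_bins=30, domains=domains, noise_sd=noise_sd, seed=seed)


def _truth_tadset(spec: PlantedSpec, chrom: str) -> TadSet:
    labels: list = [GAP if i in spec.gap_bins else -1 for i in range(spec.n_bins)]
    for d, (s, e) in enumerate(spec.domains):
        for i in range(s, e + 1):
            if labels[i] != GAP:
                labels[i] = d
    segs = segments_from_labels(labels, spec.n_bins)
    for seg in segs:
        if seg.label == GAP:
            seg.klass = SegmentClass.GAP
        elif seg.label == -1:
            seg.klass = SegmentClass.BOUNDARY
        else:
            seg.klass = SegmentClass.TAD
    return TadSet(segments=segs, chrom=chrom, provenance={"planted": True})


def generate_block_matrix(
    spec: PlantedSpec, chrom: str = "chrS", resolution_bp: Optional[int] = None
) -> tuple[ContactMatrix, TadSet]:
    """Generate a planted-domain matrix and its ground-truth TadSet."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bins
    base = np.full((n, n), spec.inter_mean)
    for s, e in spec.domains:
        base[s : e + 1, s : e + 1] = spec.intra_mean
    if spec.distance_decay > 0:
        ii, jj = np.indices((n, n))
        base = base * (1.0 + np.abs(ii - jj)) ** (-spec.distance_decay)
    if spec.noise_model == "poisson":
        m = rng.poisson(np.maximum(base, 0)).astype(float)
    elif spec.noise_model == "gaussian":
        m = base + rng.normal(0.0, spec.noise_sd, size=(n, n)) if spec.noise_sd else base.copy()
    else:
        raise ValueError(f"unknown noise model {spec.noise_model!r}")
    m = (m + m.T) / 2.0
    m = np.clip(m, 0.0, None)
    for g in spec.gap_bins:
        m[g, :] = 0.0
        m[:, g] = 0.0
    cm = ContactMatrix(m, resolution_bp=resolution_bp, chrom=chrom)
    return cm, _truth_tadset(spec, chrom)


def generate_nested_matrix(
    n_bins: int,
    outer_domains: Sequence[tuple[int, int]],
    sub_domains: Sequence[tuple[int, int]],
    sub_mean: float = 14.0,
    outer_mean: float = 8.0,
    background_mean: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    chrom: str = "chrS",
    resolution_bp: Optional[int] = None,
) -> tuple[ContactMatrix, dict[str, TadSet]]:
    """Two-level block matrix: sub-domain blocks nested inside outer domains.

    Cell means are three-valued: ``sub_mean`` inside a sub-domain,
    ``outer_mean`` elsewhere inside an outer domain, ``background_mean``
    outside. Returns the matrix and the truth TadSet at each level
    (keys ``"outer"`` and ``"sub"``).
    """
    if not sub_mean > outer_mean > background_mean:
        raise ValueError("need sub_mean > outer_mean > background_mean")
    outer = sorted(outer_domains)
    subs = sorted(sub_domains)
    for s, e in subs:
        if not any(os <= s and e <= oe for os, oe in outer):
            raise ValueError(f"sub-domain ({s},{e}) not nested in any outer domain")
    rng = np.random.default_rng(seed)
    m = np.full((n_bins, n_bins), background_mean)
    for s, e in outer:
        m[s : e + 1, s : e + 1] = outer_mean
    for s, e in subs:
        m[s : e + 1, s : e + 1] = sub_mean
    if noise_sd:
        m = m + rng.normal(0.0, noise_sd, size=m.shape)
    m = np.clip((m + m.T) / 2.0, 0.0, None)
    cm = ContactMatrix(m, resolution_bp=resolution_bp, chrom=chrom)
    truths = {
        "outer": _truth_tadset(
            PlantedSpec(n_bins, outer, intra_mean=outer_mean, inter_mean=background_mean),
            chrom,
        ),
        "sub": _truth_tadset(
            PlantedSpec(n_bins, subs, intra_mean=sub_mean, inter_mean=background_mean),
            chrom,
        ),
    }
    return cm, truths


def generate_boundary_peaks(
    truth: TadSet,
    resolution_bp: int,
    peaks_per_boundary: int = 2,
    background_rate: float = 0.0,
    seed: int = 0,
    peak_width_bp: int = 200,
    n_bins: Optional[int] = None,
) -> PeakSet:
    """Plant peaks at TAD border bins plus Poisson background elsewhere.

    Each border bin (start and end of each TAD) receives exactly
    ``peaks_per_boundary`` peaks with midpoints inside the bin; every other
    bin receives Poisson(``background_rate``) peaks at random positions.
    """
    rng = np.random.default_rng(seed)
    borders = {b for t in truth.tads for b in (t.start_bin, t.end_bin)}
    if n_bins is None:
        n_bins = max((s.end_bin for s in truth.segments), default=-1) + 1
    half = peak_width_bp // 2
    intervals: list[tuple[str, int, int]] = []

    def add_peak(bin_i: int) -> None:
        lo = bin_i * resolution_bp + half
        hi = (bin_i + 1) * resolution_bp - half - 1
        mid = int(rng.integers(lo, max(hi, lo + 1)))
        intervals.append((truth.chrom, mid - half, mid + half))

    for b in sorted(borders):
        for _ in range(peaks_per_boundary):
            add_peak(b)
    if background_rate > 0:
        for bin_i in range(n_bins):
            if bin_i in borders:
                continue
            for _ in range(rng.poisson(background_rate)):
                add_peak(bin_i)
    return PeakSet(intervals)
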