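"""Comparing TAD annotations and boundary peak enrichment.

Two TAD sets are compared per-TAD with a four-way scheme: a TAD of method A
exactly matches a TAD of method B (case A), contains two or more B-TADs as
sub-TADs (case B), overlaps without matching or containing (case C), or a
region is a TAD only under method B (case D, assessed from B's side by
swapping the arguments). A TAD is "also detected" if it falls in case A or
B; the percentage of such TADs summarises the consistency of two methods.

Boundary enrichment profiles count ChIP-Seq peaks (e.g. CTCF, H3K4me3) in
bins around every TAD border; architectural proteins are expected to pile
up at offset zero if the called boundaries are biologically real.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .domains import Segment, TadSet
from .matrix import PeakSet

__all__ = [
    "CASE_A",
    "CASE_B",
    "CASE_C",
    "NO_OVERLAP",
    "ConsistencyReport",
    "EnrichmentProfile",
    "match_case",
    "consistency_percentage",
    "boundary_peak_enrichment",
]

CASE_A = "A"  # exact boundary match (within tolerance)
CASE_B = "B"  # contains >= 2 sub-TADs of the other method
CASE_C = "C"  # overlap without match or containment
NO_OVERLAP = "no_overlap"  # complement of case D, which is judged from B's side


@dataclass
class ConsistencyReport:
    per_tad_case: list[tuple[Segment, str]]
    percent_detected: float
    tolerance_bins: int

    def case_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, case in self.per_tad_case:
            counts[case] = counts.get(case, 0) + 1
        return counts


@dataclass
class EnrichmentProfile:
    positions: np.ndarray  # offsets in bins relative to the border
    mean_peak_count: np.ndarray
    n_boundaries: int = 0

    def peak_offset(self) -> int:
        return int(self.positions[int(np.argmax(self.mean_peak_count))])


def _overlap(a: Segment, b: Segment) -> int:
    return max(0, min(a.end_bin, b.end_bin) - max(a.start_bin, b.start_bin) + 1)


def match_case(tad_a: Segment, tads_b: TadSet, tol: int = 0) -> str:
    """Classify one TAD of method A against method B's TAD set."""
    b_tads = tads_b.tads
    for b in b_tads:
        if abs(b.start_bin - tad_a.start_bin) <= tol and abs(b.end_bin - tad_a.end_bin) <= tol:
            return CASE_A
    contained = [
        b
        for b in b_tads
        if b.start_bin >= tad_a.start_bin - tol and b.end_bin <= tad_a.end_bin + tol
    ]
    if len(contained) >= 2:
        return CASE_B
    if any(_overlap(tad_a, b) > 0 for b in b_tads):
        return CASE_C
    return NO_OVERLAP


def consistency_percentage(tads_a: TadSet, tads_b: TadSet, tol: int = 0) -> ConsistencyReport:
    """Percentage of method-A TADs also detected by method B (case A or B)."""
    a_tads = tads_a.tads
    if not a_tads:
        raise ValueError("method A has no TADs to compare")
    per_tad = [(t, match_case(t, tads_b, tol)) for t in a_tads]
    detected = sum(1 for _, c in per_tad if c in (CASE_A, CASE_B))
    return ConsistencyReport(
        per_tad_case=per_tad,
        percent_detected=100.0 * detected / len(a_tads),
        tolerance_bins=tol,
    )


def boundary_peak_enrichment(
    tads: TadSet,
    peaks: PeakSet,
    resolution_bp: int,
    window_bins: int = 1,
) -> EnrichmentProfile:
    """Average number of peak midpoints per offset bin around TAD borders.

    Every TAD contributes two borders (its start and end bin). For each
    offset in [-window_bins, window_bins] the peaks whose midpoint falls in
    the bin at that offset from the border are counted, and counts are
    averaged over all borders. Peaks on other chromosomes are ignored.
    """
    offsets = np.arange(-window_bins, window_bins + 1)
    borders = [b for t in tads.tads for b in (t.start_bin, t.end_bin)]
    counts = np.zeros(offsets.size)
    if not peaks.intervals:
        warnings.warn("empty peak set: enrichment profile is all zero")
    if borders:
        midpoint_bins = np.array(
            [
                (start + end) // 2 // resolution_bp
                for chrom, start, end in peaks.intervals
                if chrom == tads.chrom
            ],
            dtype=int,
        )
        for border in borders:
            for oi, off in enumerate(offsets):
                counts[oi] += int(np.sum(midpoint_bins == border + off))
        counts /= len(borders)
    return EnrichmentProfile(
        positions=offsets, mean_peak_count=counts, n_boundaries=len(borders)
    )
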