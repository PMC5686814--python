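"""From per-bin cluster labels to scored topological domains.

Consecutive bins sharing a cluster label are joined into segments, which
are then classified: all-zero bins are gaps; segments reaching the minimum
domain size (about 180 kb in real data) are TADs; shorter ones are
boundaries. Each TAD i is scored as

    quality(i) = intra(i) - inter(i, j)

where intra(i) is the average contact frequency inside the TAD's diagonal
block (upper triangle, self-contacts excluded by default) and inter(i, j)
the average over the rectangle between TAD i and its adjacent TAD(s) j; a
TAD with two TAD neighbours averages the two inter values. The overall
quality of a TAD set is the mean per-TAD quality, and the K whose labelling
maximises it is chosen as the representative domain set.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cluster import ClusterAssignment, cluster_features
from .features import FeatureTable, build_diagonal_features
from .matrix import ContactMatrix

__all__ = [
    "GAP",
    "SegmentClass",
    "Segment",
    "TadSet",
    "ExtractionConfig",
    "segments_from_labels",
    "classify_segments",
    "tad_quality",
    "overall_quality",
    "extract_tads",
    "select_best_tadset",
]

#: Sentinel label for gap bins in a full per-bin label sequence.
GAP = "GAP"


class SegmentClass(enum.Enum):
    TAD = "TAD"
    BOUNDARY = "BOUNDARY"
    GAP = "GAP"


@dataclass
class Segment:
    """A maximal run of equal labels: inclusive bin range [start_bin, end_bin]."""

    start_bin: int
    end_bin: int
    label: object  # cluster id or GAP
    klass: Optional[SegmentClass] = None

    def __post_init__(self) -> None:
        if self.start_bin > self.end_bin:
            raise ValueError("start_bin must be <= end_bin")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class ExtractionConfig:
    """Size thresholds and quality-score options for TAD extraction.

    min_tad_bp applies when the matrix has a bp resolution; min_tad_bins is
    the fallback for unitless (e.g. simulated) matrices. A segment at least
    this large is a TAD; smaller non-gap segments are boundaries.
    """

    min_tad_bp: int = 180_000
    min_tad_bins: int = 3
    include_diagonal_in_intra: bool = False

    def __post_init__(self) -> None:
        if self.min_tad_bp <= 0:
            raise ValueError("min_tad_bp must be positive")

    def min_bins(self, resolution_bp: Optional[int]) -> int:
        if resolution_bp is not None:
            return int(np.ceil(self.min_tad_bp / resolution_bp))
        if self.min_tad_bins is None:
            raise ValueError("unitless matrix needs min_tad_bins")
        return self.min_tad_bins


@dataclass
class TadSet:
    """An ordered tiling of the chromosome into TAD/boundary/gap segments."""

    segments: list[Segment]
    tad_qualities: list[float] = field(default_factory=list)
    k_used: Optional[int] = None
    chrom: str = "chr?"
    provenance: dict = field(default_factory=dict)
    assignment: Optional[ClusterAssignment] = None

    @property
    def tads(self) -> list[Segment]:
        return [s for s in self.segments if s.klass is SegmentClass.TAD]

    @property
    def n_tads(self) -> int:
        return len(self.tads)

    @property
    def overall_quality(self) -> float:
        if not self.tad_qualities:
            return float("-inf")
        return float(np.mean(self.tad_qualities))

    def mean_tad_size_bins(self) -> float:
        tads = self.tads
        if not tads:
            return float("nan")
        return float(np.mean([t.n_bins for t in tads]))

    def tad_ranges(self, one_based: bool = False) -> list[tuple[int, int]]:
        off = 1 if one_based else 0
        return [(t.start_bin + off, t.end_bin + off) for t in self.tads]


def segments_from_labels(labels: Sequence, n_bins: int) -> list[Segment]:
    """Join consecutive equal labels (including GAP marks) into segments."""
    if len(labels) != n_bins:
        raise ValueError("need one label per bin")
    segs: list[Segment] = []
    start = 0
    for i in range(1, n_bins + 1):
        if i == n_bins or labels[i] != labels[start]:
            segs.append(Segment(start, i - 1, labels[start]))
            start = i
    return segs


def classify_segments(
    segs: list[Segment],
    cfg: ExtractionConfig,
    resolution_bp: Optional[int] = None,
) -> list[Segment]:
    """Assign TAD/BOUNDARY/GAP classes by the minimum-size rule (in place)."""
    min_bins = cfg.min_bins(resolution_bp)
    for seg in segs:
        if seg.label == GAP:
            seg.klass = SegmentClass.GAP
        elif seg.n_bins >= min_bins:
            seg.klass = SegmentClass.TAD
        else:
            seg.klass = SegmentClass.BOUNDARY
    return segs


def _intra_mean(m: np.ndarray, tad: Segment, include_diagonal: bool) -> float:
    block = m[tad.start_bin : tad.end_bin + 1, tad.start_bin : tad.end_bin + 1]
    n = block.shape[0]
    iu = np.triu_indices(n, k=0 if include_diagonal else 1)
    if iu[0].size == 0:
        raise ValueError(
            "single-bin TAD has no off-diagonal cells; enable "
            "include_diagonal_in_intra or raise the minimum TAD size"
        )
    return float(block[iu].mean())


def _inter_mean(m: np.ndarray, a: Segment, b: Segment) -> float:
    rect = m[a.start_bin : a.end_bin + 1, b.start_bin : b.end_bin + 1]
    return float(rect.mean())


def tad_quality(
    m: ContactMatrix,
    tads: Sequence[Segment],
    i: int,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> float:
    """Quality of the i-th TAD: intra(i) minus the mean inter with adjacent TADs.

    ``tads`` is the ordered list of TAD segments only (boundaries and gaps
    between them are skipped; the inter rectangle uses TAD rows x TAD
    columns). Terminal TADs have one neighbour; a lone TAD has none and its
    inter term is zero.
    """
    tad = tads[i]
    if tad.klass is not None and tad.klass is not SegmentClass.TAD:
        raise ValueError("index does not point at a TAD segment")
    intra = _intra_mean(m.values, tad, cfg.include_diagonal_in_intra)
    inters = []
    if i > 0:
        inters.append(_inter_mean(m.values, tads[i - 1], tad))
    if i < len(tads) - 1:
        inters.append(_inter_mean(m.values, tad, tads[i + 1]))
    inter = float(np.mean(inters)) if inters else 0.0
    return intra - inter


def overall_quality(
    m: ContactMatrix, tadset: TadSet, cfg: ExtractionConfig = ExtractionConfig()
) -> float:
    """Mean per-TAD quality; -inf sentinel for a set with no TADs."""
    tads = tadset.tads
    if not tads:
        return float("-inf")
    return float(np.mean([tad_quality(m, tads, i, cfg) for i in range(len(tads))]))


def _full_label_sequence(m: ContactMatrix, assignment: ClusterAssignment) -> list:
    """Interleave cluster labels with GAP marks into one label per bin."""
    gaps = m.gap_bins()
    non_gap = [i for i in range(m.n_bins) if i not in gaps]
    if len(assignment.labels) != len(non_gap):
        raise ValueError(
            f"assignment covers {len(assignment.labels)} bins but matrix has "
            f"{len(non_gap)} non-gap bins"
        )
    labels: list = [GAP] * m.n_bins
    for bin_i, lab in zip(non_gap, assignment.labels):
        labels[bin_i] = int(lab)
    return labels


def extract_tads(
    m: ContactMatrix,
    assignment: ClusterAssignment,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> TadSet:
    """Segment, classify and score a labelling into a TadSet."""
    labels = _full_label_sequence(m, assignment)
    segs = classify_segments(segments_from_labels(labels, m.n_bins), cfg, m.resolution_bp)
    tadset = TadSet(
        segments=segs,
        k_used=assignment.k,
        chrom=m.chrom,
        provenance={
            "algorithm": assignment.algorithm,
            "metric": assignment.metric,
            "seed": assignment.seed,
        },
        assignment=assignment,
    )
    tads = tadset.tads
    tadset.tad_qualities = [tad_quality(m, tads, i, cfg) for i in range(len(tads))]
    return tadset


def select_best_tadset(
    m: ContactMatrix,
    cfg: ExtractionConfig = ExtractionConfig(),
    k_range: tuple[int, int] = (2, 10),
    algorithm: str = "KM",
    metric: str = "euclidean",
    seed: int = 0,
    features: Optional[FeatureTable] = None,
) -> tuple[TadSet, list[tuple[int, float]]]:
    """Cluster and extract for every K in the range; keep the highest-quality set.

    Returns the best TadSet (ties broken toward smaller K) and the per-K
    table of overall qualities. If no K yields a TAD, the smallest-K empty
    set is returned with quality -inf.
    """
    lo, hi = k_range
    if lo < 2:
        raise ValueError("k range must start at >= 2")
    f = features if features is not None else build_diagonal_features(m)
    hi = min(hi, f.n_rows)
    best: Optional[TadSet] = None
    per_k: list[tuple[int, float]] = []
    for k in range(lo, hi + 1):
        a = cluster_features(f, k, algorithm=algorithm, metric=metric, seed=seed)
        ts = extract_tads(m, a, cfg)
        q = ts.overall_quality
        per_k.append((k, q))
        if best is None or q > best.overall_quality + 1e-12:
            best = ts
    if best is None:
        raise ValueError("empty K range")
    best.provenance["k_range"] = (lo, hi)
    return best, per_k
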