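"""Contact-matrix and peak-file I/O.

A Hi-C experiment summarises chromosome conformation as an N x N symmetric
matrix of normalized contact frequencies between equal-sized genomic bins.
This module reads such matrices from plain-text files (dense or sparse
triples), validates them, and writes domain calls back out as BED tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ContactMatrix",
    "PeakSet",
    "MatrixFormatError",
    "read_dense_matrix",
    "read_sparse_triples",
    "write_dense_matrix",
    "write_tads_bed",
    "read_peaks_bed",
]

#: Relative asymmetry above which a matrix is rejected instead of symmetrized.
ASYMMETRY_TOL = 1e-6


class MatrixFormatError(ValueError):
    """Raised when an input file cannot be interpreted as a contact matrix."""


@dataclass
class ContactMatrix:
    """A symmetric, non-negative intra-chromosomal contact matrix.

    Parameters
    ----------
    values : ndarray
        N x N matrix of contact frequencies. Symmetrized on construction
        when the asymmetry is within tolerance.
    resolution_bp : int, optional
        Bin width in base pairs. ``None`` marks a unitless matrix (e.g. a
        simulated one), in which case size thresholds are given in bins.
    chrom : str
        Chromosome label used in BED output.
    """

    values: np.ndarray
    resolution_bp: Optional[int] = None
    chrom: str = "chr?"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixFormatError(f"contact matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("contact matrix contains NaN or Inf entries")
        if np.any(v < 0):
            raise ValueError("contact matrix contains negative entries")
        scale = v.max() if v.size and v.max() > 0 else 1.0
        asym = np.abs(v - v.T).max() if v.size else 0.0
        if asym > ASYMMETRY_TOL * scale:
            raise ValueError(
                f"matrix asymmetry {asym:g} exceeds tolerance {ASYMMETRY_TOL * scale:g}"
            )
        self.values = (v + v.T) / 2.0
        if self.resolution_bp is not None and self.resolution_bp <= 0:
            raise ValueError("resolution_bp must be positive")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def gap_bins(self) -> set[int]:
        """Bins with no recorded interactions (all-zero rows)."""
        return set(np.flatnonzero(~self.values.any(axis=1)).tolist())


@dataclass
class PeakSet:
    """Genomic intervals (e.g. ChIP-Seq peaks), 0-based half-open, sorted."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise MatrixFormatError(f"degenerate interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def read_dense_matrix(
    path: str | Path, resolution_bp: Optional[int] = None, chrom: str = "chr?"
) -> ContactMatrix:
    """Read a dense whitespace-delimited N x N matrix from a text file."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: non-numeric entry") from exc
    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")
    widths = {len(r) for r in rows}
    if len(widths) != 1 or widths.pop() != len(rows):
        raise MatrixFormatError(
            f"{path}: expected square matrix, got {len(rows)} rows of widths "
            f"{sorted({len(r) for r in rows})}"
        )
    return ContactMatrix(np.array(rows), resolution_bp=resolution_bp, chrom=chrom)


def read_sparse_triples(
    path: str | Path,
    n_bins: int,
    resolution_bp: Optional[int] = None,
    chrom: str = "chr?",
) -> ContactMatrix:
    """Read a sparse ``i j count`` triple file into a dense contact matrix.

    Indices are 0-based; each pair should appear once (either orientation);
    unlisted cells are zero.
    """
    m = np.zeros((n_bins, n_bins))
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 3:
                raise MatrixFormatError(f"{path}:{lineno}: expected 'i j count'")
            try:
                i, j, count = int(toks[0]), int(toks[1]), float(toks[2])
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: malformed triple") from exc
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise MatrixFormatError(
                    f"{path}:{lineno}: bin index out of range for n_bins={n_bins}"
                )
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MatrixFormatError(f"{path}:{lineno}: duplicate entry for pair {key}")
            seen.add(key)
            m[i, j] = count
            m[j, i] = count
    return ContactMatrix(m, resolution_bp=resolution_bp, chrom=chrom)


def write_dense_matrix(m: ContactMatrix, path: str | Path) -> None:
    """Write the dense matrix as whitespace-delimited text (full precision)."""
    np.savetxt(path, m.values, fmt="%.12g")


def write_tads_bed(tads, resolution_bp: Optional[int], path: str | Path) -> None:
    """Write TAD segments to a BED file; boundary/gap segments go to companion
    ``<path>.boundary.bed`` / ``<path>.gap.bed`` tracks with a name column.

    Bin ranges are inclusive internally; BED output is 0-based half-open bp.
    """
    from .domains import SegmentClass, TadSet  # local import avoids cycle

    if resolution_bp is None:
        raise ValueError("cannot write BED without a bin resolution")
    assert isinstance(tads, TadSet)
    path = Path(path)
    chrom = tads.chrom

    def bed_line(seg, name: str) -> str:
        start = seg.start_bin * resolution_bp
        end = (seg.end_bin + 1) * resolution_bp
        return f"{chrom}\t{start}\t{end}\t{name}\n"

    tracks = {
        SegmentClass.TAD: [],
        SegmentClass.BOUNDARY: [],
        SegmentClass.GAP: [],
    }
    for seg in tads.segments:
        tracks[seg.klass].append(bed_line(seg, seg.klass.name))

    with open(path, "w") as fh:
        fh.write("# TAD calls (0-based half-open bp)\n")
        fh.writelines(tracks[SegmentClass.TAD])
    for klass, suffix in ((SegmentClass.BOUNDARY, "boundary"), (SegmentClass.GAP, "gap")):
        if tracks[klass]:
            with open(path.with_suffix(path.suffix + f".{suffix}.bed"), "w") as fh:
                fh.writelines(tracks[klass])


def read_tads_bed(path: str | Path, resolution_bp: int):
    """Read a TAD BED file (as written by :func:`write_tads_bed`) into a TadSet.

    Only TAD segments are reconstructed; the regions between them are filled
    in as boundaries so the segment list tiles the covered range.
    """
    from .domains import Segment, SegmentClass, TadSet

    peaks = read_peaks_bed(path)  # same column contract
    segments = []
    chrom = "chr?"
    prev_end = -1
    for chrom, start, end in peaks.intervals:
        start_bin = start // resolution_bp
        end_bin = end // resolution_bp - 1
        if start_bin <= prev_end:
            raise MatrixFormatError(f"{path}: overlapping TAD intervals")
        if start_bin > prev_end + 1:
            segments.append(
                Segment(prev_end + 1, start_bin - 1, None, SegmentClass.BOUNDARY)
            )
        segments.append(Segment(start_bin, end_bin, None, SegmentClass.TAD))
        prev_end = end_bin
    return TadSet(segments=segments, chrom=chrom)


def read_peaks_bed(path: str | Path) -> PeakSet:
    """Read a BED file (>= 3 columns) of peak intervals; extra columns ignored."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) < 3:
                raise MatrixFormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                chrom, start, end = toks[0], int(toks[1]), int(toks[2])
            except ValueError as exc:
                raise MatrixFormatError(f"{path}:{lineno}: malformed coordinates") from exc
            if start >= end:
                raise MatrixFormatError(f"{path}:{lineno}: start >= end")
            intervals.append((chrom, start, end))
    return PeakSet(intervals)
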