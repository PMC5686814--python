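"""Per-bin contact-profile features.

Bins inside a domain share similar contact profiles, so each diagonal
contact (bin i with itself) is represented by the concatenation of row i
and column i of the contact matrix: a 2N-vector. Clustering these vectors
groups bins with similar genome-wide interaction patterns. All-zero rows
(gap bins, typically unmappable regions) receive no feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ContactMatrix

__all__ = ["FeatureTable", "build_diagonal_features"]


@dataclass
class FeatureTable:
    """Feature vectors for the non-gap diagonal bins of a contact matrix.

    Attributes
    ----------
    vectors : ndarray, shape (N - n_gaps, 2N)
        One row per non-gap bin, in bin order.
    bin_index : ndarray of int
        The original bin index of each row.
    excluded_bins : set of int
        Gap bins (all-zero matrix rows) that received no feature.
    """

    vectors: np.ndarray
    bin_index: np.ndarray
    excluded_bins: set[int] = field(default_factory=set)
    n_bins: int = 0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.bin_index = np.asarray(self.bin_index, dtype=int)
        if self.vectors.shape[0] != self.bin_index.shape[0]:
            raise ValueError("one bin index per feature row required")

    @property
    def n_rows(self) -> int:
        return self.vectors.shape[0]


def build_diagonal_features(m: ContactMatrix, log_transform: bool = False) -> FeatureTable:
    """Build the 2N-length feature vector (row_i, column_i) for each non-gap bin.

    Parameters
    ----------
    m : ContactMatrix
    log_transform : bool
        Apply log(1 + x) to contact counts first. Off by default; raw
        normalized counts are clustered as-is.
    """
    if m.n_bins < 2:
        raise ValueError("need at least 2 bins to build features")
    values = np.log1p(m.values) if log_transform else m.values
    gaps = m.gap_bins()
    keep = np.array([i for i in range(m.n_bins) if i not in gaps], dtype=int)
    # column i of a symmetrized matrix equals row i; both halves are kept so
    # the feature layout stays (row_i, col_i) regardless of symmetrization.
    vectors = np.hstack([values[keep, :], values.T[keep, :]])
    return FeatureTable(vectors=vectors, bin_index=keep, excluded_bins=gaps, n_bins=m.n_bins)
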