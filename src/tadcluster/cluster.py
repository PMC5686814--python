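"""Clustering of contact-profile features and cluster-number selection.

Three algorithm families are supported:

* ``KM`` — Lloyd-style K-means, generalised to three dissimilarities
  (euclidean, cityblock, pearson = 1 - r). The centroid update minimises the
  metric's within-cluster sum: coordinate-wise mean for euclidean and
  pearson, coordinate-wise median for cityblock.
* ``HC`` — agglomerative hierarchical clustering (scipy linkage) under the
  same three dissimilarities.
* ``EM`` — a diagonal-covariance Gaussian mixture with hard assignment by
  maximum posterior (no metric choice; the Gaussian model fixes the
  geometry).

The number of clusters K is the method's only free parameter. It can be
estimated from the data-size rule K = sqrt(n/2), searched in a +/-10 window
around that estimate, or picked by the elbow of the percent-variance curve.
Cluster quality is scored with the Davies-Bouldin index and the Silhouette
index, both averaged over clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import cdist, pdist
from sklearn.mixture import GaussianMixture

from .features import FeatureTable

__all__ = [
    "ClusterAssignment",
    "ClusterQualityReport",
    "METRICS",
    "distance",
    "kmeans_cluster",
    "hierarchical_cluster",
    "em_cluster",
    "estimate_k_han",
    "k_search_window",
    "elbow_k",
    "davies_bouldin",
    "silhouette",
]

METRICS = ("euclidean", "pearson", "cityblock")
#: scipy's name for the pearson correlation distance 1 - r
_SCIPY_METRIC = {"euclidean": "euclidean", "cityblock": "cityblock", "pearson": "correlation"}


@dataclass
class ClusterAssignment:
    """Labels from one clustering run, one label per non-gap bin in bin order."""

    labels: np.ndarray
    k: int
    algorithm: str  # KM | HC | EM
    metric: Optional[str] = None  # None for EM
    seed: Optional[int] = None
    within_cluster_variance: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(np.unique(self.labels)) > self.k:
            raise ValueError("more distinct labels than k")

    def cluster_sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))


@dataclass
class ClusterQualityReport:
    dbi: float
    si: float
    per_cluster_centroid_spread: list[float] = field(default_factory=list)
    centroid_distances: Optional[np.ndarray] = None
    per_point_silhouette: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# distances and centroids


def distance(u, v, metric: str = "euclidean") -> float:
    """Dissimilarity between two equal-length vectors.

    euclidean = L2 norm of the difference; cityblock = L1; pearson = 1 - r
    where r is the Pearson correlation coefficient (range [0, 2]).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if metric == "euclidean":
        return float(np.linalg.norm(u - v))
    if metric == "cityblock":
        return float(np.abs(u - v).sum())
    if metric == "pearson":
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            raise ValueError("pearson distance undefined for constant vectors")
        r = np.corrcoef(u, v)[0, 1]
        return float(1.0 - r)
    raise ValueError(f"unknown metric {metric!r}")


def _pairwise_to_centroids(x: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    d = cdist(x, centroids, metric=_SCIPY_METRIC[metric])
    # scipy returns nan for constant vectors under 'correlation'; treat a
    # constant profile as maximally uncorrelated rather than failing mid-run
    if metric == "pearson":
        d = np.nan_to_num(d, nan=1.0)
    return d


def _centroid(rows: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cityblock":
        return np.median(rows, axis=0)  # L1-optimal representative
    return rows.mean(axis=0)


# ---------------------------------------------------------------------------
# K-means


def kmeans_cluster(
    f: FeatureTable,
    k: int,
    metric: str = "euclidean",
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
) -> ClusterAssignment:
    """Metric-generalised K-means; returns the best of ``n_restarts`` runs.

    Runs are scored by within-cluster sum of distances. Deterministic for a
    given seed. A cluster that empties during iteration is re-seeded from
    the point farthest from its current centroid.
    """
    x = f.vectors
    n = x.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of feature rows {n}")
    rng = np.random.default_rng(seed)
    best_labels, best_obj = None, np.inf
    for _ in range(n_restarts):
        labels, obj = _kmeans_single(x, k, metric, rng, max_iter)
        if obj < best_obj - 1e-12:
            best_labels, best_obj = labels, obj
    return ClusterAssignment(
        labels=_canonical_labels(best_labels),
        k=k,
        algorithm="KM",
        metric=metric,
        seed=seed,
        within_cluster_variance=best_obj,
    )


def _kmeans_single(x, k, metric, rng, max_iter):
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d = _pairwise_to_centroids(x, centroids, metric)
        new_labels = d.argmin(axis=1)
        # farthest-point reseeding for empty clusters (each point used once)
        empty = [c for c in range(k) if not np.any(new_labels == c)]
        if empty:
            cur = d[np.arange(n), new_labels].copy()
            for c in empty:
                # steal the farthest point whose cluster keeps >= 2 members
                counts = np.bincount(new_labels, minlength=k)
                cand = np.where(counts[new_labels] > 1, cur, -np.inf)
                far = int(cand.argmax())
                centroids[c] = x[far]
                new_labels[far] = c
                cur[far] = -np.inf
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centroids[c] = _centroid(x[labels == c], metric)
    d = _pairwise_to_centroids(x, centroids, metric)
    obj = float(d[np.arange(n), labels].sum())
    return labels, obj


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first appearance (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# hierarchical


def hierarchical_cluster(
    f: FeatureTable,
    k: int,
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering cut at k clusters.

    Average linkage is the default: it is defined for arbitrary
    dissimilarities including 1 - r. Ward linkage requires euclidean.
    """
    x = f.vectors
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of feature rows {n}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    if n == 1 or k == n:
        labels = np.arange(n) if k == n else np.zeros(n, dtype=int)
    else:
        dvec = pdist(x, metric=_SCIPY_METRIC[metric])
        if metric == "pearson":
            dvec = np.nan_to_num(dvec, nan=1.0)
        z = scipy_linkage(dvec, method=linkage)
        labels = fcluster(z, t=k, criterion="maxclust") - 1
    labels = _canonical_labels(labels)
    wcv = _within_sum(x, labels, metric)
    return ClusterAssignment(
        labels=labels, k=k, algorithm="HC", metric=metric, within_cluster_variance=wcv
    )


# ---------------------------------------------------------------------------
# EM (Gaussian mixture)


def em_cluster(f: FeatureTable, k: int, seed: int = 0) -> ClusterAssignment:
    """Diagonal-covariance Gaussian-mixture EM with hard max-posterior labels.

    K-means initialisation; convergence at log-likelihood change < 1e-6 or
    300 iterations; component variances floored at 1e-8 of the data variance
    to survive duplicate points.
    """
    x = f.vectors
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of feature rows {x.shape[0]}")
    data_var = float(x.var())
    gm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        tol=1e-6,
        max_iter=300,
        reg_covar=max(1e-8 * data_var, 1e-12),
        init_params="kmeans",
        random_state=seed,
    )
    labels = _canonical_labels(gm.fit_predict(x))
    wcv = _within_sum(x, labels, "euclidean")
    return ClusterAssignment(
        labels=labels, k=k, algorithm="EM", metric=None, seed=seed,
        within_cluster_variance=wcv,
    )


def cluster_features(
    f: FeatureTable,
    k: int,
    algorithm: str = "KM",
    metric: str = "euclidean",
    seed: int = 0,
    **kwargs,
) -> ClusterAssignment:
    """Dispatch to the requested algorithm with a uniform signature."""
    if algorithm == "KM":
        return kmeans_cluster(f, k, metric=metric, seed=seed, **kwargs)
    if algorithm == "HC":
        return hierarchical_cluster(f, k, metric=metric, **kwargs)
    if algorithm == "EM":
        return em_cluster(f, k, seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected KM, HC or EM")


# ---------------------------------------------------------------------------
# choosing K


def estimate_k_han(n: int) -> int:
    """Rule-of-thumb cluster number K = sqrt(n/2), rounded to nearest, min 2.

    Assumes roughly sqrt(2n) points per cluster for a dataset of n points.
    """
    if n < 2:
        raise ValueError("need at least 2 points")
    return max(2, round(math.sqrt(n / 2.0)))


def k_search_window(k_est: int, n: int) -> tuple[int, int]:
    """The +/-10 search window around an estimated K, clipped to [2, n-1]."""
    if k_est < 2:
        raise ValueError("k_est must be >= 2")
    return max(2, k_est - 10), min(n - 1, k_est + 10)


def _within_sum(x: np.ndarray, labels: np.ndarray, metric: str) -> float:
    """Sum of squared member-to-centroid distances under the metric."""
    total = 0.0
    for c in np.unique(labels):
        rows = x[labels == c]
        cen = _centroid(rows, metric)
        d = _pairwise_to_centroids(rows, cen[None, :], metric)[:, 0]
        total += float((d**2).sum())
    return total


def elbow_k(
    f: FeatureTable,
    k_min: int = 2,
    k_max: int = 10,
    algorithm: str = "KM",
    metric: str = "euclidean",
    seed: int = 0,
) -> tuple[int, list[float]]:
    """Pick K at the elbow of the percent-variance-explained curve.

    For each K in [k_min, k_max] the data are clustered and the percentage
    of variance explained, 1 - within/total, is recorded. The elbow is the K
    after which adding a cluster stops paying: the K with the largest drop
    in marginal gain, 2*curve(K) - curve(K-1) - curve(K+1), with curve(1)
    defined as 0 (one cluster explains nothing). Ties go to the smallest K.

    Returns ``(k_elbow, variance_curve)`` with the curve indexed from k_min.
    """
    x = f.vectors
    n = x.shape[0]
    if k_min < 2 or k_max <= k_min:
        raise ValueError("need k_min >= 2 and k_max > k_min")
    if k_max >= n:
        import warnings

        warnings.warn(f"k_max clipped from {k_max} to {n - 1} (only {n} rows)")
        k_max = n - 1
    global_centroid = _centroid(x, metric)
    dglob = _pairwise_to_centroids(x, global_centroid[None, :], metric)[:, 0]
    total = float((dglob**2).sum())
    if total == 0:
        raise ValueError("zero total variance: all feature rows identical")
    curve = []
    for k in range(k_min, k_max + 1):
        a = cluster_features(f, k, algorithm=algorithm, metric=metric, seed=seed)
        within = _within_sum(x, a.labels, metric)
        curve.append(100.0 * (1.0 - within / total))
    padded = [0.0] + curve  # curve(k_min - 1 .. k_max) with k=1 convention
    best_k, best_drop = k_min, -np.inf
    for idx in range(1, len(padded) - 1):
        drop = 2 * padded[idx] - padded[idx - 1] - padded[idx + 1]
        if drop > best_drop + 1e-12:
            best_k, best_drop = k_min + idx - 1, drop
    return best_k, curve


# ---------------------------------------------------------------------------
# cluster-quality indices


def _clusters_of(labels: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(labels == c) for c in np.unique(labels)]


def davies_bouldin(
    f: FeatureTable, a: ClusterAssignment, metric: str = "euclidean"
) -> float:
    """Davies-Bouldin index: mean over clusters of the worst spread-to-
    separation ratio max_j (d_i + d_j) / d_ij. Lower is better.

    d_i is the mean distance of cluster i's members to its centroid and
    d_ij the distance between the centroids of clusters i and j.
    """
    report = cluster_quality_report(f, a, metric)
    return report.dbi


def silhouette(
    f: FeatureTable, a: ClusterAssignment, metric: str = "euclidean"
) -> tuple[float, np.ndarray]:
    """Silhouette index averaged over clusters; higher is better, range [-1, 1].

    s_j = (b_j - a_j) / max(a_j, b_j) with a_j the mean distance to the other
    members of j's cluster and b_j the smallest mean distance to another
    cluster. Singletons get s_j = 0. The index is the mean over clusters of
    the per-cluster mean s_j.
    """
    report = cluster_quality_report(f, a, metric)
    return report.si, report.per_point_silhouette


def cluster_quality_report(
    f: FeatureTable, a: ClusterAssignment, metric: str = "euclidean"
) -> ClusterQualityReport:
    x = f.vectors
    labels = a.labels
    clusters = _clusters_of(labels)
    k = len(clusters)
    if k < 2:
        raise ValueError("quality indices need at least 2 non-empty clusters")

    # Davies-Bouldin
    centroids = np.vstack([_centroid(x[idx], metric) for idx in clusters])
    spreads = []
    for idx, cen in zip(clusters, centroids):
        d = _pairwise_to_centroids(x[idx], cen[None, :], metric)[:, 0]
        spreads.append(float(d.mean()))
    cen_d = _pairwise_to_centroids(centroids, centroids, metric)
    if np.any(cen_d[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("coincident centroids: Davies-Bouldin ratio undefined")
    d_sum = np.add.outer(spreads, spreads)
    safe_cen_d = np.where(np.eye(k, dtype=bool), 1.0, cen_d)  # diagonal unused
    ratio = np.where(np.eye(k, dtype=bool), -np.inf, d_sum / safe_cen_d)
    dbi = float(ratio.max(axis=1).mean())

    # Silhouette
    full_d = _pairwise_to_centroids(x, x, metric)
    np.fill_diagonal(full_d, 0.0)
    s = np.zeros(x.shape[0])
    for ci, idx in enumerate(clusters):
        for j in idx:
            if len(idx) == 1:
                s[j] = 0.0
                continue
            a_j = full_d[j, idx].sum() / (len(idx) - 1)
            b_j = min(
                full_d[j, other].mean()
                for co, other in enumerate(clusters)
                if co != ci
            )
            denom = max(a_j, b_j)
            s[j] = 0.0 if denom == 0 else (b_j - a_j) / denom
    si = float(np.mean([s[idx].mean() for idx in clusters]))

    return ClusterQualityReport(
        dbi=dbi,
        si=si,
        per_cluster_centroid_spread=spreads,
        centroid_distances=cen_d,
        per_point_silhouette=s,
    )
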