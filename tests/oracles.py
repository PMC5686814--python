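"""Brute-force reference implementations used only as test oracles.

Deliberately written with plain loops and no shared code with the package
so they can disagree with it if either side is wrong.
"""

import numpy as np


def brute_distance(u, v, metric):
    u, v = np.asarray(u, float), np.asarray(v, float)
    if metric == "euclidean":
        return float(sum((a - b) ** 2 for a, b in zip(u, v)) ** 0.5)
    if metric == "cityblock":
        return float(sum(abs(a - b) for a, b in zip(u, v)))
    if metric == "pearson":
        um, vm = u - u.mean(), v - v.mean()
        r = (um * vm).sum() / np.sqrt((um**2).sum() * (vm**2).sum())
        return float(1.0 - r)
    raise ValueError(metric)


def _centroid(rows, metric):
    return np.median(rows, axis=0) if metric == "cityblock" else rows.mean(axis=0)


def brute_dbi(x, labels, metric="euclidean"):
    """Davies-Bouldin: mean over clusters of max_j (d_i + d_j) / d_ij."""
    ids = sorted(set(labels.tolist()))
    cents = {c: _centroid(x[labels == c], metric) for c in ids}
    spread = {
        c: np.mean([brute_distance(p, cents[c], metric) for p in x[labels == c]])
        for c in ids
    }
    worst = []
    for i in ids:
        ratios = [
            (spread[i] + spread[j]) / brute_distance(cents[i], cents[j], metric)
            for j in ids
            if j != i
        ]
        worst.append(max(ratios))
    return float(np.mean(worst))


def brute_silhouette(x, labels, metric="euclidean"):
    """Silhouette averaged over clusters of per-cluster mean s_j."""
    ids = sorted(set(labels.tolist()))
    per_cluster = []
    for c in ids:
        members = np.flatnonzero(labels == c)
        s_vals = []
        for j in members:
            if len(members) == 1:
                s_vals.append(0.0)
                continue
            a_j = np.mean(
                [brute_distance(x[j], x[o], metric) for o in members if o != j]
            )
            b_j = min(
                np.mean(
                    [brute_distance(x[j], x[o], metric) for o in np.flatnonzero(labels == c2)]
                )
                for c2 in ids
                if c2 != c
            )
            s_vals.append(0.0 if max(a_j, b_j) == 0 else (b_j - a_j) / max(a_j, b_j))
        per_cluster.append(np.mean(s_vals))
    return float(np.mean(per_cluster))


def brute_tad_quality(m, tad_ranges, i, include_diagonal=False):
    """intra - inter by explicit cell enumeration over 0-based inclusive ranges."""
    s, e = tad_ranges[i]
    intra_cells = [
        m[a, b]
        for a in range(s, e + 1)
        for b in range(s, e + 1)
        if (a < b) or (include_diagonal and a == b)
    ]
    intra = float(np.mean(intra_cells))
    inters = []
    for j in (i - 1, i + 1):
        if 0 <= j < len(tad_ranges):
            s2, e2 = tad_ranges[j]
            cells = [m[a, b] for a in range(s, e + 1) for b in range(s2, e2 + 1)]
            inters.append(float(np.mean(cells)))
    return intra - (float(np.mean(inters)) if inters else 0.0)
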