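"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the textbook definitions (pair counting for ARI,
explicit per-point loops for silhouette, per-cluster scatter ratios for
Davies-Bouldin, exhaustive O(n^2) neighbor search) so they share no code
with the package paths they check.
"""

from math import comb

import numpy as np


def ari_contingency(a, b) -> float:
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    ua, ub = np.unique(a), np.unique(b)
    nij = np.zeros((ua.size, ub.size), dtype=int)
    for i, va in enumerate(ua):
        for j, vb in enumerate(ub):
            nij[i, j] = np.sum((a == va) & (b == vb))
    sum_ij = sum(comb(int(v), 2) for v in nij.ravel())
    sum_a = sum(comb(int(v), 2) for v in nij.sum(axis=1))
    sum_b = sum(comb(int(v), 2) for v in nij.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def silhouette_mean(points, labels) -> float:
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = points.shape[0]
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    scores = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        n_same = same.sum()
        if n_same == 1:
            scores[i] = 0.0
            continue
        a = dist[i, same].sum() / (n_same - 1)
        b = min(dist[i, labels == other].mean()
                for other in np.unique(labels) if other != labels[i])
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def davies_bouldin(points, labels) -> float:
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    centroids = np.array([points[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array([
        np.linalg.norm(points[labels == u] - centroids[i], axis=1).mean()
        for i, u in enumerate(uniq)])
    k = uniq.size
    total = 0.0
    for i in range(k):
        worst = 0.0
        for j in range(k):
            if i == j:
                continue
            d = np.linalg.norm(centroids[i] - centroids[j])
            worst = max(worst, (scatter[i] + scatter[j]) / d)
        total += worst
    return total / k


def knn_adjacency(pos, k) -> np.ndarray:
    """Exhaustive symmetrized k-NN adjacency; ties broken by lower index."""
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        d = np.linalg.norm(pos - pos[i], axis=1)
        order = sorted((float(d[j]), j) for j in range(n) if j != i)
        for _, j in order[:k]:
            a[i, j] = 1
    return np.maximum(a, a.T)


def normalized_adjacency_dense(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    al = a + np.eye(a.shape[0])
    d = al.sum(axis=1)
    dinv = np.diag(d ** -0.5)
    return dinv @ al @ dinv
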