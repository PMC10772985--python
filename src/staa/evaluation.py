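"""Downstream clustering of the learned embedding and quality metrics.

ARI (chance-corrected pair agreement, used when ground truth exists) and the
internal Silhouette / Davies-Bouldin indices (used when it does not) are
delegated to scikit-learn; all distances are Euclidean and metrics are
computed in the same embedding space that is clustered.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from sklearn import metrics as skmetrics

logger = logging.getLogger(__name__)

from .pre_clustering import gmm_labels, louvain_labels, _relabel_by_size, _pca_reduce
from .types import ClusteringResult, LabelVector

# embeddings this small are clustered directly; wider ones are PCA-reduced
_PCA_THRESHOLD = 64


def cluster_embedding(embedding: np.ndarray, method: str, n_clusters: int,
                      seed: int) -> LabelVector:
    """Cluster the latent embedding into spatial domains."""
    emb = np.asarray(embedding, dtype=float)
    n, d = emb.shape
    if not np.all(np.isfinite(emb)):
        raise ValueError("embedding contains NaN or Inf")
    if n_clusters > n:
        raise ValueError("n_clusters exceeds number of spots")
    if n_clusters == 1:
        return LabelVector(np.zeros(n, dtype=int), source="final")
    points = emb if d <= _PCA_THRESHOLD else _pca_reduce(emb, 50, seed)
    if method == "gmm":
        raw = gmm_labels(points, n_clusters, seed)
    elif method == "louvain":
        raw = louvain_labels(points, n_clusters, seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    return LabelVector(_relabel_by_size(raw), source="final")


def adjusted_rand_index(a: LabelVector, b: LabelVector) -> float:
    """Pair-counting ARI between two labelings; symmetric, range [-1, 1]."""
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    if len(a) < 2:
        raise ValueError("ARI needs at least two spots")
    return float(skmetrics.adjusted_rand_score(a.labels, b.labels))


def silhouette_score(points: np.ndarray, labels: LabelVector) -> float:
    """Mean silhouette (b - a)/max(a, b); singleton clusters contribute 0."""
    lab = labels.labels
    if len(np.unique(lab)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(skmetrics.silhouette_score(points, lab, metric="euclidean"))


def davies_bouldin_index(points: np.ndarray, labels: LabelVector) -> float:
    """Mean over clusters of the worst (s_i + s_j) / d_ij similarity.

    s_i is the mean Euclidean distance of cluster i's members to its
    centroid, d_ij the distance between centroids.  Coincident centroids
    yield +inf, propagated with a warning.  (Computed here rather than via
    scikit-learn, whose version rejects the all-singleton boundary case and
    masks the coincident-centroid degeneracy.)
    """
    points = np.asarray(points, dtype=float)
    lab = labels.labels
    uniq = np.unique(lab)
    k = uniq.size
    if k < 2:
        raise ValueError("Davies-Bouldin undefined for a single cluster")
    centroids = np.stack([points[lab == u].mean(axis=0) for u in uniq])
    scatter = np.array([
        np.linalg.norm(points[lab == u] - centroids[i], axis=1).mean()
        for i, u in enumerate(uniq)])
    dist = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :],
                          axis=2)
    if np.any(dist[~np.eye(k, dtype=bool)] == 0):
        logger.warning("coincident cluster centroids; Davies-Bouldin is inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (scatter[:, None] + scatter[None, :]) / dist
    ratio[(dist == 0) & ~np.eye(k, dtype=bool)] = np.inf
    np.fill_diagonal(ratio, -np.inf)
    return float(np.mean(ratio.max(axis=1)))


def evaluate(embedding: np.ndarray, labels: LabelVector, method: str,
             truth: Optional[LabelVector] = None) -> ClusteringResult:
    """Bundle labels with SC/DB (and ARI when truth is available).

    Spots with a negative truth label (missing annotation) are excluded
    from ARI only.
    """
    k = len(np.unique(labels.labels))
    res = ClusteringResult(labels=labels, n_clusters=k, method=method)
    if k >= 2:
        res.silhouette = silhouette_score(embedding, labels)
        res.davies_bouldin = davies_bouldin_index(embedding, labels)
    if truth is not None:
        mask = truth.labels >= 0
        res.ari = float(skmetrics.adjusted_rand_score(
            truth.labels[mask], labels.labels[mask]))
    return res


def plot_domains(coords: np.ndarray, labels: LabelVector, path=None):
    """Scatter of spots colored by domain; saves to ``path`` if given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=labels.labels,
                    cmap="tab10", s=12)
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.colorbar(sc, ax=ax, label="domain")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
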