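"""End-to-end pipeline: preprocessing -> graph -> pre-clustering ->
adversarial training -> clustering -> metrics."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from . import io as sio
from .config import RunConfig
from .evaluation import cluster_embedding, evaluate
from .pre_clustering import _pca_reduce, initial_labels
from .preprocessing import normalize_counts, scale_features, select_hvg
from .spatial_graph import build_knn_graph
from .training import train
from .types import (ClusteringResult, ExpressionMatrix, LabelVector,
                    SpatialCoordinates)


def run_pipeline(config: RunConfig, expr: ExpressionMatrix,
                 coords: SpatialCoordinates,
                 truth: Optional[LabelVector] = None,
                 out_dir=None) -> ClusteringResult:
    """Run every stage on one tissue section; fully determined by the seed.

    When ``out_dir`` is given, writes labels.csv, embedding.csv,
    metrics.json and trace.csv there.
    """
    if expr.n_spots != coords.n_spots:
        raise ValueError("expression and coordinates disagree on spot count")
    if config.n_clusters > expr.n_spots:
        raise ValueError("n_clusters exceeds number of spots")

    normed = normalize_counts(expr) if not expr.is_normalized else expr
    hvg, report = select_hvg(normed, config.n_hvg)
    X = scale_features(hvg) if config.scale_features else hvg.dense()
    if config.encoder_input == "pca":
        # denoised encoder features: standardized principal components
        X = _pca_reduce(X, config.n_pca, config.seed)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - X.mean(axis=0)) / std

    graph = build_knn_graph(coords, config.k_neighbors)
    y = None
    if config.use_classifier:
        y = initial_labels(hvg, config.pre_cluster_method,
                           config.n_clusters, config.seed)

    model = train(X, graph, y, config)
    labels = cluster_embedding(model.embedding, config.final_cluster_method,
                               config.n_clusters, config.seed)
    result = evaluate(model.embedding, labels, config.final_cluster_method,
                      truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_labels(labels, expr.spot_ids, out / "labels.csv")
        sio.write_embedding(model.embedding, expr.spot_ids,
                            out / "embedding.csv")
        metrics = result.metrics_dict()
        metrics["seed"] = config.seed
        metrics["preprocessing"] = report.to_dict()
        sio.write_metrics(metrics, out / "metrics.json")
        model.trace.to_csv(out / "trace.csv")
    return result
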