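"""Count normalization and highly-variable-gene selection.

The feature matrix fed to the graph encoder is built in three steps:
library-size scaling of each spot to a common ``target_sum`` followed by
log1p, selection of the ``n_hvg`` genes with the highest dispersion
(variance/mean on the log-normalized values, ties broken by gene index),
and optional per-gene z-scaling clipped at +/-10 for conditioning.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import scipy.sparse as sp

from .types import ExpressionMatrix, PreprocessReport

logger = logging.getLogger(__name__)

DEFAULT_TARGET_SUM = 1e4
SCALE_CLIP = 10.0


def normalize_counts(expr: ExpressionMatrix,
                     target_sum: float = DEFAULT_TARGET_SUM) -> ExpressionMatrix:
    """Scale each spot's counts to ``target_sum`` and log1p-transform.

    All-zero spots are left as zero rows (with a warning) rather than
    producing NaNs.  Refuses to run twice on the same matrix.
    """
    if expr.is_normalized:
        raise ValueError("expression is already normalized")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")

    if sp.issparse(expr.values):
        mat = expr.values.tocsr().astype(float, copy=True)
        sums = np.asarray(mat.sum(axis=1)).ravel()
        empty = sums == 0
        scale = np.divide(target_sum, sums, out=np.zeros_like(sums),
                          where=~empty)
        mat = sp.diags(scale) @ mat
        mat.data = np.log1p(mat.data)
        values = mat.tocsr()
    else:
        mat = np.asarray(expr.values, dtype=float)
        sums = mat.sum(axis=1)
        empty = sums == 0
        scale = np.divide(target_sum, sums, out=np.zeros_like(sums),
                          where=~empty)
        values = np.log1p(mat * scale[:, None])

    if empty.any():
        logger.warning("%d all-zero spots left unnormalized", int(empty.sum()))

    return ExpressionMatrix(values=values, spot_ids=list(expr.spot_ids),
                            gene_ids=list(expr.gene_ids), is_normalized=True)


def gene_dispersion(expr: ExpressionMatrix) -> np.ndarray:
    """Per-gene dispersion statistic variance/mean; zero-mean genes get 0."""
    if sp.issparse(expr.values):
        x = expr.values.tocsc()
        mean = np.asarray(x.mean(axis=0)).ravel()
        sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
        var = sq - mean ** 2
    else:
        x = np.asarray(expr.values, dtype=float)
        mean = x.mean(axis=0)
        var = x.var(axis=0)
    disp = np.zeros_like(mean)
    nz = mean > 0
    disp[nz] = var[nz] / mean[nz]
    return disp


def select_hvg(expr: ExpressionMatrix,
               n_hvg: int) -> Tuple[ExpressionMatrix, PreprocessReport]:
    """Keep the ``n_hvg`` genes with the highest dispersion.

    Gene order of the input matrix is preserved among the kept genes; ties in
    the dispersion ranking are broken by lower gene index so the selection is
    deterministic.  ``n_hvg >= n_genes`` keeps every gene.
    """
    if n_hvg < 1:
        raise ValueError("n_hvg must be >= 1")
    if not expr.is_normalized:
        raise ValueError("select_hvg expects normalized expression")

    n_genes = expr.n_genes
    if n_hvg >= n_genes:
        report = PreprocessReport(n_genes_in=n_genes, n_genes_kept=n_genes,
                                  target_sum=DEFAULT_TARGET_SUM,
                                  hvg_gene_ids=list(expr.gene_ids))
        return expr, report

    disp = gene_dispersion(expr)
    # stable sort on -disp: equal dispersions keep ascending gene index
    order = np.argsort(-disp, kind="stable")[:n_hvg]
    keep = np.zeros(n_genes, dtype=bool)
    keep[order] = True
    idx = np.flatnonzero(keep)

    values = expr.values.tocsc()[:, idx].tocsr() if sp.issparse(expr.values) \
        else np.asarray(expr.values)[:, idx]
    gene_ids = [expr.gene_ids[i] for i in idx]
    out = ExpressionMatrix(values=values, spot_ids=list(expr.spot_ids),
                           gene_ids=gene_ids, is_normalized=True)
    report = PreprocessReport(n_genes_in=n_genes, n_genes_kept=len(gene_ids),
                              target_sum=DEFAULT_TARGET_SUM,
                              hvg_gene_ids=gene_ids)
    return out, report


def scale_features(expr: ExpressionMatrix, clip: float = SCALE_CLIP) -> np.ndarray:
    """Z-scale each gene across spots and clip at ``+/-clip``.

    Returns a dense float array ready for the encoder; constant genes map
    to zero.
    """
    x = expr.dense().astype(float)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    return np.clip((x - mean) / std, -clip, clip)
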