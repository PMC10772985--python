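"""Core in-memory containers shared across the pipeline.

Expression lives either densely (ndarray) or as a scipy CSR matrix; every
operation that touches values must go through :meth:`ExpressionMatrix.dense`
or keep the sparse path explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import numpy as np
import scipy.sparse as sp

Matrix = Union[np.ndarray, sp.spmatrix]


def _check_unique(ids: List[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} are not unique")


@dataclass
class ExpressionMatrix:
    """A spots x genes expression matrix with aligned identifiers.

    ``values`` holds raw counts (``is_normalized=False``) or library-size
    normalized, log1p-transformed expression (``is_normalized=True``).
    """

    values: Matrix
    spot_ids: List[str]
    gene_ids: List[str]
    is_normalized: bool = False

    def __post_init__(self) -> None:
        n, g = self.values.shape
        if len(self.spot_ids) != n:
            raise ValueError(
                f"spot_ids length {len(self.spot_ids)} != {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != {g} matrix columns"
            )
        _check_unique(self.spot_ids, "spot identifiers")
        _check_unique(self.gene_ids, "gene identifiers")
        dense_probe = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(dense_probe)):
            raise ValueError("expression contains NaN or Inf")
        if not self.is_normalized and dense_probe.size and dense_probe.min() < 0:
            raise ValueError("count matrix contains negative values")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)


@dataclass
class SpatialCoordinates:
    """Spot positions (platform units); row order matches the expression."""

    positions: np.ndarray
    spot_ids: List[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an n x 2 array")
        if len(self.spot_ids) != self.positions.shape[0]:
            raise ValueError("spot_ids length does not match positions")
        _check_unique(self.spot_ids, "spot identifiers")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("coordinates contain NaN or Inf")

    @property
    def n_spots(self) -> int:
        return self.positions.shape[0]


@dataclass
class LabelVector:
    """Integer cluster labels in [0, K) for every spot.

    Truth vectors may carry -1 for spots without annotation; such spots are
    excluded from ARI but still contribute to internal metrics.
    """

    labels: np.ndarray
    source: str = "pre_cluster"  # pre_cluster | final | truth

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        floor = -1 if self.source == "truth" else 0
        if self.labels.size and self.labels.min() < floor:
            raise ValueError("labels must be non-negative")
        if self.source not in ("pre_cluster", "final", "truth"):
            raise ValueError(f"unknown label source {self.source!r}")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class SpatialGraph:
    """Binary symmetric spatial adjacency A and its Kipf-normalized form.

    ``normalized_adjacency`` is D^{-1/2} (A + I) D^{-1/2} with D the degree
    matrix of A + I; it is what every encoder layer multiplies by.
    """

    adjacency: sp.csr_matrix
    k_neighbors: int
    normalized_adjacency: Optional[sp.csr_matrix] = None

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2


@dataclass
class PreprocessReport:
    n_genes_in: int
    n_genes_kept: int
    target_sum: float
    hvg_gene_ids: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {
            "n_genes_in": self.n_genes_in,
            "n_genes_kept": self.n_genes_kept,
            "target_sum": self.target_sum,
            "hvg_gene_ids": list(self.hvg_gene_ids),
        }


@dataclass
class ClusteringResult:
    labels: LabelVector
    n_clusters: int
    method: str
    silhouette: Optional[float] = None
    davies_bouldin: Optional[float] = None
    ari: Optional[float] = None

    def metrics_dict(self) -> Dict:
        out: Dict = {
            "n_clusters": self.n_clusters,
            "method": self.method,
            "silhouette": self.silhouette,
            "davies_bouldin": self.davies_bouldin,
        }
        if self.ari is not None:
            out["ari"] = self.ari
        return out
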