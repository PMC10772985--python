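"""Readers and writers for expression matrices, coordinates and labels.

Supported expression dialects: dense CSV/TSV (header row = gene names,
first column = spot identifiers), MatrixMarket MTX accompanied by
``genes.tsv``/``barcodes.tsv`` name files (spots x genes orientation), and
AnnData ``.h5ad`` (main matrix + obs/var names, coordinates from
``obsm['spatial']`` when present).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import ExpressionMatrix, LabelVector, SpatialCoordinates

logger = logging.getLogger(__name__)


def _read_names(path: Path) -> List[str]:
    # name files may carry extra columns (10X style: id, symbol); use first
    df = pd.read_csv(path, sep="\t", header=None)
    return [str(v) for v in df.iloc[:, 0]]


def load_expression(path, fmt: Optional[str] = None) -> ExpressionMatrix:
    """Read a spots x genes expression matrix.

    ``fmt`` is one of ``mtx``, ``csv``, ``h5ad``; inferred from the file
    suffix when omitted.  MTX expects ``genes.tsv`` and ``barcodes.tsv``
    next to the matrix file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "csv",
               ".h5ad": "h5ad"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")

    if fmt == "csv":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        return ExpressionMatrix(values=values,
                                spot_ids=[str(i) for i in df.index],
                                gene_ids=[str(c) for c in df.columns])
    if fmt == "mtx":
        mat = scipy.io.mmread(path).tocsr()
        genes = _read_names(path.parent / "genes.tsv")
        barcodes = _read_names(path.parent / "barcodes.tsv")
        if mat.shape != (len(barcodes), len(genes)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(barcodes)} barcodes x {len(genes)} genes")
        return ExpressionMatrix(values=mat, spot_ids=barcodes, gene_ids=genes)
    if fmt == "h5ad":
        import anndata
        adata = anndata.read_h5ad(path)
        values = adata.X
        if sp.issparse(values):
            values = values.tocsr()
        else:
            values = np.asarray(values)
        return ExpressionMatrix(values=values,
                                spot_ids=[str(i) for i in adata.obs_names],
                                gene_ids=[str(v) for v in adata.var_names])
    raise ValueError(f"unknown format {fmt!r}")


def load_coordinates(path, expr: Optional[ExpressionMatrix] = None
                     ) -> SpatialCoordinates:
    """Read spot coordinates from CSV/TSV (or the h5ad ``obsm['spatial']``).

    With an identifier column present on both sides, rows are reordered by
    join to the expression spot order; a headerless/identifier-free table is
    taken in row order with a warning.  More than two numeric columns: the
    first two are used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if path.suffix.lower() == ".h5ad":
        import anndata
        adata = anndata.read_h5ad(path)
        if "spatial" not in adata.obsm:
            raise ValueError("h5ad has no obsm['spatial'] entry")
        coords = SpatialCoordinates(
            positions=np.asarray(adata.obsm["spatial"])[:, :2],
            spot_ids=[str(i) for i in adata.obs_names])
        return _align(coords, expr)

    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, header=None)
    # a non-numeric first row is a header
    if not pd.api.types.is_numeric_dtype(df.iloc[:, -1]) or \
            df.iloc[0].apply(lambda v: isinstance(v, str)).all():
        try:
            float(df.iloc[0, df.shape[1] - 1])
        except (TypeError, ValueError):
            df = pd.read_csv(path, sep=sep, header=0)

    first_numeric = pd.api.types.is_numeric_dtype(df.iloc[:, 0])
    if first_numeric and df.shape[1] >= 2:
        ids = [f"row{i}" for i in range(len(df))]
        num = df
        has_ids = False
    else:
        ids = [str(v) for v in df.iloc[:, 0]]
        num = df.iloc[:, 1:]
        has_ids = True
    num = num.apply(pd.to_numeric, errors="coerce")
    if num.shape[1] < 2:
        raise ValueError("coordinate table needs at least two numeric columns")
    if num.shape[1] > 2:
        logger.warning("coordinate table has %d numeric columns; using the "
                       "first two", num.shape[1])
    pos = num.iloc[:, :2].to_numpy(dtype=float)
    if np.isnan(pos).any():
        raise ValueError("non-numeric coordinate values")
    coords = SpatialCoordinates(positions=pos, spot_ids=ids)
    return _align(coords, expr, has_ids=has_ids)


def _align(coords: SpatialCoordinates, expr: Optional[ExpressionMatrix],
           has_ids: bool = True) -> SpatialCoordinates:
    if expr is None:
        return coords
    if coords.n_spots != expr.n_spots and not has_ids:
        raise ValueError("coordinate row count does not match expression")
    if not has_ids:
        logger.warning("no spot identifiers in coordinate table; "
                       "aligning by row order")
        return SpatialCoordinates(positions=coords.positions,
                                  spot_ids=list(expr.spot_ids))
    index = {s: i for i, s in enumerate(coords.spot_ids)}
    missing = [s for s in expr.spot_ids if s not in index]
    if missing:
        raise ValueError(f"coordinates missing {len(missing)} spot(s), "
                         f"e.g. {missing[:3]}")
    order = [index[s] for s in expr.spot_ids]
    return SpatialCoordinates(positions=coords.positions[order],
                              spot_ids=list(expr.spot_ids))


# ---------------------------------------------------------------------------
# writers

def write_expression_mtx(expr: ExpressionMatrix, out_dir) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv, re-readable as ``mtx``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    values = expr.values if sp.issparse(expr.values) \
        else sp.csr_matrix(expr.values)
    scipy.io.mmwrite(out_dir / "matrix.mtx", values)
    (out_dir / "genes.tsv").write_text("\n".join(expr.gene_ids) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(expr.spot_ids) + "\n")


def write_coordinates(coords: SpatialCoordinates, path) -> None:
    pd.DataFrame({"spot_id": coords.spot_ids,
                  "x": coords.positions[:, 0],
                  "y": coords.positions[:, 1]}).to_csv(path, index=False)


def write_labels(labels: LabelVector, spot_ids: List[str], path) -> None:
    pd.DataFrame({"spot_id": spot_ids,
                  "label": labels.labels}).to_csv(path, index=False)


def read_labels(path, expr: Optional[ExpressionMatrix] = None) -> LabelVector:
    df = pd.read_csv(path)
    if expr is not None:
        df = df.set_index("spot_id").loc[expr.spot_ids].reset_index()
    return LabelVector(df["label"].to_numpy(dtype=int), source="truth")


def write_embedding(embedding: np.ndarray, spot_ids: List[str], path) -> None:
    cols = [f"z{j}" for j in range(embedding.shape[1])]
    pd.DataFrame(embedding, index=spot_ids, columns=cols).to_csv(
        path, index_label="spot_id")


def write_metrics(metrics: dict, path) -> None:
    Path(path).write_text(json.dumps(metrics, indent=2, sort_keys=True) + "\n")
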