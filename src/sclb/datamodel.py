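"""Annotated cell-by-gene container, serialization, and normalization transforms.

The :class:`CellByGeneDataset` is the object every benchmark component
consumes and produces: a UMI count matrix with per-cell and per-gene
metadata, named layers (same shape as the counts), named embeddings,
named cell-cell graphs, and a free-form ground-truth store that metrics
(and only metrics, plus positive controls) may read.

Two on-disk dialects are supported: the h5ad annotated-matrix layout
(via :mod:`anndata`) and a plain-text Matrix Market directory with CSV
metadata, genes-as-rows on disk following the 10x convention.
"""

from __future__ import annotations

import dataclasses
import json
import numbers
import pathlib
from typing import Any

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CellByGeneDataset",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "normalize_log10k",
    "cpm_normalize",
]


class ValidationError(ValueError):
    """An object violates a container invariant."""


def _is_integral(m) -> bool:
    data = m.data if sp.issparse(m) else np.asarray(m)
    if data.size == 0:
        return True
    if np.issubdtype(data.dtype, np.integer):
        return True
    return bool(np.all(np.equal(np.mod(data, 1), 0)))


def _min(m) -> float:
    if sp.issparse(m):
        return float(m.data.min()) if m.nnz else 0.0
    arr = np.asarray(m)
    return float(arr.min()) if arr.size else 0.0


@dataclasses.dataclass
class CellByGeneDataset:
    """Annotated count matrix with task ground truth.

    Parameters
    ----------
    counts
        ``n_cells x n_genes`` matrix of non-negative integer UMI counts
        (dense ndarray or scipy sparse).
    cell_meta, gene_meta
        Per-cell / per-gene tables; the index is the identifier.
    layers
        Named matrices with exactly the shape of ``counts``
        (e.g. ``"train"``, ``"test"``, ``"denoised"``, ``"log10k"``).
    embeddings
        Named ``n_cells x d`` matrices (e.g. ``"X_emb"``, ``"X_2d"``).
    pairgraphs
        Named sparse ``n_cells x n_cells`` matrices with non-negative
        entries (e.g. ``"connectivities"``).
    truth
        Free-form keyed store for task ground truth; values are arrays,
        DataFrames, scalars, strings or (nested) lists thereof.
    """

    counts: Any
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    layers: dict = dataclasses.field(default_factory=dict)
    embeddings: dict = dataclasses.field(default_factory=dict)
    pairgraphs: dict = dataclasses.field(default_factory=dict)
    truth: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------

    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if _min(self.counts) < 0 or not _is_integral(self.counts):
            raise ValidationError("counts must be non-negative integers")
        if len(self.cell_meta) != n_cells:
            raise ValidationError(
                f"cell_meta has {len(self.cell_meta)} rows for {n_cells} cells"
            )
        if len(self.gene_meta) != n_genes:
            raise ValidationError(
                f"gene_meta has {len(self.gene_meta)} rows for {n_genes} genes"
            )
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValidationError(
                    f"layer {name!r} shape {layer.shape} != counts shape"
                )
        for name, emb in self.embeddings.items():
            if emb.shape[0] != n_cells:
                raise ValidationError(f"embedding {name!r} has wrong row count")
        for name, g in self.pairgraphs.items():
            if g.shape != (n_cells, n_cells):
                raise ValidationError(f"pairgraph {name!r} is not n_cells x n_cells")
            if _min(g) < 0:
                raise ValidationError(f"pairgraph {name!r} has negative entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def copy(self) -> "CellByGeneDataset":
        return CellByGeneDataset(
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            layers={k: v.copy() for k, v in self.layers.items()},
            embeddings={k: v.copy() for k, v in self.embeddings.items()},
            pairgraphs={k: v.copy() for k, v in self.pairgraphs.items()},
            truth=_decode_truth(_encode_truth(self.truth)),
        )


# -- truth-store codec ---------------------------------------------
# One tagged-JSON codec shared by both serialization dialects so the
# truth store round-trips exactly (arrays keep dtype, frames keep
# column order, floats survive via repr round-tripping).


def _encode_value(v):
    if isinstance(v, np.ndarray):
        return {"__kind__": "ndarray", "dtype": str(v.dtype), "data": v.tolist()}
    if isinstance(v, pd.DataFrame):
        return {
            "__kind__": "frame",
            "columns": list(map(str, v.columns)),
            "data": {str(c): _encode_value(v[c].to_numpy()) for c in v.columns},
        }
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (list, tuple)):
        return {"__kind__": "list", "data": [_encode_value(x) for x in v]}
    if v is None or isinstance(v, (bool, str, numbers.Number)):
        return v
    raise ValidationError(f"unsupported truth value of type {type(v)!r}")


def _decode_value(v):
    if isinstance(v, dict) and "__kind__" in v:
        kind = v["__kind__"]
        if kind == "ndarray":
            return np.asarray(v["data"], dtype=v["dtype"])
        if kind == "frame":
            return pd.DataFrame(
                {c: _decode_value(v["data"][c]) for c in v["columns"]},
                columns=v["columns"],
            )
        if kind == "list":
            return [_decode_value(x) for x in v["data"]]
        raise ValidationError(f"unknown truth tag {kind!r}")
    return v


def _encode_truth(truth: dict) -> str:
    return json.dumps({k: _encode_value(v) for k, v in truth.items()})


def _decode_truth(payload: str) -> dict:
    return {k: _decode_value(v) for k, v in json.loads(payload).items()}


# -- serialization -------------------------------------------------

_TRUTH_KEY = "truth_json"


def _density(m) -> float:
    if sp.issparse(m):
        return m.nnz / max(1, m.shape[0] * m.shape[1])
    return float(np.count_nonzero(m)) / max(1, m.size)


def _storage_form(m):
    # storage contract: sparse below 50% density, dense otherwise
    if _density(m) < 0.5:
        return sp.csr_matrix(m)
    return np.asarray(m.todense()) if sp.issparse(m) else np.asarray(m)


def write_dataset(ds: CellByGeneDataset, path, format: str = "h5ad") -> None:
    """Write ``ds`` to ``path`` in h5ad or Matrix-Market-directory form."""
    ds.validate()
    path = pathlib.Path(path)
    if format == "h5ad":
        adata = ad.AnnData(
            X=_storage_form(ds.counts),
            obs=ds.cell_meta.copy(),
            var=ds.gene_meta.copy(),
            layers={k: _storage_form(v) for k, v in ds.layers.items()},
            obsm={k: np.asarray(v) for k, v in ds.embeddings.items()},
            obsp={k: sp.csr_matrix(v) for k, v in ds.pairgraphs.items()},
        )
        adata.uns[_TRUTH_KEY] = _encode_truth(ds.truth)
        adata.write_h5ad(path)
    elif format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        # genes-as-rows on disk (10x convention), transposed back on read
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(ds.counts).T)
        ds.cell_meta.to_csv(path / "cells.csv")
        ds.gene_meta.to_csv(path / "genes.csv")
        for name, layer in ds.layers.items():
            scipy.io.mmwrite(
                path / f"layer_{name}.mtx", sp.coo_matrix(layer).T, precision=17
            )
        for name, emb in ds.embeddings.items():
            pd.DataFrame(np.asarray(emb)).to_csv(
                path / f"emb_{name}.csv", index=False
            )
        for name, g in ds.pairgraphs.items():
            scipy.io.mmwrite(path / f"graph_{name}.mtx", sp.coo_matrix(g), precision=17)
        (path / "truth.json").write_text(_encode_truth(ds.truth))
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_meta_csv(path: pathlib.Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_dataset(path, format: str = "h5ad") -> CellByGeneDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset: {path}")
    if format == "h5ad":
        adata = ad.read_h5ad(path)
        counts = adata.X
        if sp.issparse(counts):
            counts = sp.csr_matrix(counts)
            counts.data = np.rint(counts.data).astype(np.int64).astype(counts.data.dtype)
        truth = _decode_truth(adata.uns.get(_TRUTH_KEY, "{}"))
        return CellByGeneDataset(
            counts=counts,
            cell_meta=adata.obs.copy(),
            gene_meta=adata.var.copy(),
            layers={k: v.copy() for k, v in adata.layers.items()},
            embeddings={k: np.asarray(v) for k, v in adata.obsm.items()},
            pairgraphs={k: sp.csr_matrix(v) for k, v in adata.obsp.items()},
            truth=truth,
        )
    if format == "mtx_dir":
        counts = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx").T)
        cell_meta = _read_meta_csv(path / "cells.csv")
        gene_meta = _read_meta_csv(path / "genes.csv")
        if counts.shape != (len(cell_meta), len(gene_meta)):
            raise ValidationError(
                f"matrix shape {counts.shape} does not match metadata "
                f"({len(cell_meta)} cells, {len(gene_meta)} genes)"
            )
        layers, embeddings, pairgraphs = {}, {}, {}
        for f in sorted(path.glob("layer_*.mtx")):
            layers[f.stem[len("layer_"):]] = sp.csr_matrix(scipy.io.mmread(f).T)
        for f in sorted(path.glob("emb_*.csv")):
            embeddings[f.stem[len("emb_"):]] = pd.read_csv(f).to_numpy()
        for f in sorted(path.glob("graph_*.mtx")):
            pairgraphs[f.stem[len("graph_"):]] = sp.csr_matrix(scipy.io.mmread(f))
        truth_file = path / "truth.json"
        truth = _decode_truth(truth_file.read_text()) if truth_file.exists() else {}
        return CellByGeneDataset(
            counts=counts,
            cell_meta=cell_meta,
            gene_meta=gene_meta,
            layers=layers,
            embeddings=embeddings,
            pairgraphs=pairgraphs,
            truth=truth,
        )
    raise ValueError(f"unknown format {format!r}")


# -- normalization transforms --------------------------------------


def cpm_normalize(counts, target: float = 1e4):
    """Scale each cell to ``target`` total counts.

    All-zero cells map to all-zero rows rather than raising, so
    degenerate inputs flow through pipelines. Negative entries raise.
    Returns the same container kind (sparse in, sparse out).
    """
    if _min(counts) < 0:
        raise ValidationError("counts must be non-negative")
    if sp.issparse(counts):
        m = sp.csr_matrix(counts, dtype=np.float64, copy=True)
        totals = np.asarray(m.sum(axis=1)).ravel()
        scale = np.divide(target, totals, out=np.zeros_like(totals), where=totals > 0)
        return sp.diags(scale) @ m
    m = np.asarray(counts, dtype=np.float64)
    totals = m.sum(axis=1)
    scale = np.divide(target, totals, out=np.zeros_like(totals), where=totals > 0)
    return m * scale[:, None]


def normalize_log10k(counts):
    """log-10k transform: scale each cell to 10,000 counts, then log1p.

    For a cell with total :math:`T > 0`, entry :math:`x` maps to
    :math:`\\ln(1 + 10^4 x / T)`; all-zero cells map to zero rows.
    Scaling a single cell's counts by a positive scalar leaves its
    normalized row unchanged.
    """
    scaled = cpm_normalize(counts, target=1e4)
    if sp.issparse(scaled):
        out = scaled.copy()
        out.data = np.log1p(out.data)
        return out
    return np.log1p(scaled)
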