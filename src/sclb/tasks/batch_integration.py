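"""Batch integration: remove batch effects, keep biological variation.

Integrators can emit three output formats — a corrected expression
matrix, an embedding, or a neighborhood graph — so the task converts
outputs down the chain (matrix -> embedding -> graph) and one metric
pair evaluates every subtask: batch-mixing entropy on the graph
(removal) and cell-type silhouette on the embedding (conservation).
The negative control is the unintegrated PCA embedding; the positive
control embeds each cell at its one-hot cell-type indicator (plus tiny
jitter) — batch-free and label-perfect by construction.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.metrics import silhouette_score

from ..core import DatasetDef, MethodDef, MetricDef, TaskSpec, register
from ..datamodel import CellByGeneDataset
from ..synthetic import SyntheticConfig, add_batch_effect, make_celltype_counts, test_scale
from ._shared import ensure_log10k, pca_embed, symmetric_knn_graph

TASK = "batch_integration"

K_DEFAULT = 15


def to_embedding(ds: CellByGeneDataset) -> CellByGeneDataset:
    """Derive X_emb (top-30 PCs of the corrected matrix) if absent."""
    if "X_emb" in ds.embeddings:
        return ds
    if "corrected" not in ds.layers:
        raise ValueError("nothing to convert: no corrected matrix or embedding")
    ds.embeddings["X_emb"] = pca_embed(np.asarray(ds.layers["corrected"]), 30)
    return ds


def to_graph(ds: CellByGeneDataset, k: int = K_DEFAULT) -> CellByGeneDataset:
    """Derive the symmetrized k-NN connectivity graph from X_emb if absent."""
    if "connectivities" in ds.pairgraphs:
        return ds
    to_embedding(ds)
    ds.pairgraphs["connectivities"] = symmetric_knn_graph(
        np.asarray(ds.embeddings["X_emb"]), k
    )
    return ds


def _batches_labels(ds):
    for col in ("batch", "label"):
        if col not in ds.cell_meta:
            raise ValueError(f"dataset lacks {col!r}")
    return (
        np.asarray(ds.cell_meta["batch"]).astype(str),
        np.asarray(ds.cell_meta["label"]).astype(str),
    )


def control_no_integration(ds: CellByGeneDataset) -> CellByGeneDataset:
    """Negative control: PCA embedding of the unintegrated log-10k matrix."""
    _batches_labels(ds)
    ds.embeddings["X_emb"] = pca_embed(ds.layers["log10k"], 30)
    return ds


def control_perfect_embedding(
    ds: CellByGeneDataset, jitter: float = 0.01, seed: int = 0
) -> CellByGeneDataset:
    """Positive control: one-hot cell-type indicators plus N(0, jitter^2)."""
    _, labels = _batches_labels(ds)
    rng = np.random.default_rng(seed)
    uniq = sorted(np.unique(labels).tolist())
    onehot = np.zeros((ds.n_cells, len(uniq)))
    onehot[np.arange(ds.n_cells), [uniq.index(l) for l in labels]] = 1.0
    ds.embeddings["X_emb"] = onehot + jitter * rng.standard_normal(onehot.shape)
    return ds


def method_batch_centering(ds: CellByGeneDataset) -> CellByGeneDataset:
    """Per-batch per-gene standardization, restored to global moments.

    Single-cell batches are centered only (scale restoration skipped,
    with a warning).
    """
    batches, _ = _batches_labels(ds)
    x = np.asarray(ds.layers["log10k"], dtype=np.float64).copy()
    g_mean, g_std = x.mean(axis=0), x.std(axis=0)
    for b in np.unique(batches):
        rows = batches == b
        xb = x[rows]
        centered = xb - xb.mean(axis=0)
        if rows.sum() < 2:
            warnings.warn(f"batch {b!r} has a single cell; centering only")
            x[rows] = centered + g_mean
            continue
        std = xb.std(axis=0)
        z = np.divide(centered, std, out=centered.copy(), where=std > 0)
        x[rows] = z * g_std + g_mean
    ds.layers["corrected"] = x
    return ds


def method_linear_regression_out(ds: CellByGeneDataset) -> CellByGeneDataset:
    """Residual of log-10k after a per-gene batch-indicator fit, plus gene mean.

    With a one-hot batch design the least-squares fit per gene is the
    per-batch mean, so the residual is computed by group-mean removal.
    """
    batches, _ = _batches_labels(ds)
    x = np.asarray(ds.layers["log10k"], dtype=np.float64).copy()
    g_mean = x.mean(axis=0)
    for b in np.unique(batches):
        rows = batches == b
        x[rows] -= x[rows].mean(axis=0)
    ds.layers["corrected"] = x + g_mean
    return ds


def metric_batch_mixing_entropy(ds: CellByGeneDataset, k: int = K_DEFAULT) -> float:
    """Mean per-cell entropy of batch composition among graph neighbors.

    Normalized by ln(n_batches) so perfect mixing scores 1 and fully
    separated batches score 0.
    """
    batches, _ = _batches_labels(ds)
    uniq = np.unique(batches)
    if len(uniq) < 2:
        raise ValueError("mixing entropy needs at least two batches")
    to_graph(ds, k)
    g = ds.pairgraphs["connectivities"].tocsr()
    codes = np.searchsorted(uniq, batches)
    ent = []
    for i in range(ds.n_cells):
        nbrs = g.indices[g.indptr[i]:g.indptr[i + 1]]
        if nbrs.size == 0:
            continue
        p = np.bincount(codes[nbrs], minlength=len(uniq)) / nbrs.size
        p = p[p > 0]
        ent.append(-(p * np.log(p)).sum())
    return float(np.mean(ent) / np.log(len(uniq)))


def metric_celltype_silhouette(ds: CellByGeneDataset) -> float:
    """Mean silhouette width by cell type on X_emb, rescaled to [0, 1]."""
    _, labels = _batches_labels(ds)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least two cell types")
    to_embedding(ds)
    s = silhouette_score(np.asarray(ds.embeddings["X_emb"]), labels)
    return float((s + 1) / 2)


def _api_check(ds, stage: str = "pre"):
    _batches_labels(ds)
    assert "log10k" in ds.layers
    if stage == "post":
        assert "corrected" in ds.layers or "X_emb" in ds.embeddings \
            or "connectivities" in ds.pairgraphs


def _dataset(config: dict):
    params = dict(config or {})

    def fn(test_mode: bool = True, seed: int = 0):
        cfg = SyntheticConfig(**{**params, "seed": seed})
        if test_mode:
            cfg = test_scale(cfg)
        ds = make_celltype_counts(cfg)
        ds = add_batch_effect(ds, cfg.n_batches, cfg.batch_strength, seed + 1)
        return ensure_log10k(ds)

    return fn


def build_task(config: dict | None = None) -> TaskSpec:
    task = TaskSpec(name=TASK, api_check=_api_check)
    register(task, DatasetDef("synthetic_batched", _dataset(config), TASK))
    register(task, MethodDef("perfect_embedding", control_perfect_embedding, TASK, "positive_control"))
    register(task, MethodDef("no_integration", control_no_integration, TASK, "negative_control"))
    register(task, MethodDef("batch_centering", method_batch_centering, TASK))
    register(task, MethodDef("linear_regression_out", method_linear_regression_out, TASK))
    register(task, MetricDef("batch_mixing_entropy", metric_batch_mixing_entropy, "maximize", TASK))
    register(task, MetricDef("celltype_silhouette", metric_celltype_silhouette, "maximize", TASK))
    return task
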