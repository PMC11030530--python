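"""Dimensionality reduction for 2D visualisation.

Methods must accept the log-10k matrix (computed once by the harness
and handed unchanged to both methods and metrics, so no method can gain
an edge by renormalizing) and emit a two-dimensional coordinate per
cell. The positive control passes the full log-10k matrix itself to the
metrics — an explicit exemption from the 2D contract that bounds the
achievable score; the negative control emits i.i.d. normal coordinates.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr
from sklearn.manifold import trustworthiness as _sk_trustworthiness

from ..core import DatasetDef, MethodDef, MetricDef, TaskSpec, register
from ..datamodel import CellByGeneDataset
from ..synthetic import SyntheticConfig, make_celltype_counts, test_scale
from ._shared import ensure_log10k, pca_embed, symmetric_knn_graph

TASK = "dimred"

EMB = "X_2d"


def method_pca2(ds: CellByGeneDataset) -> CellByGeneDataset:
    """First two principal components (centered, unscaled) of log-10k."""
    if ds.n_cells < 3:
        raise ValueError("need at least 3 cells")
    ds.embeddings[EMB] = pca_embed(ds.layers["log10k"], 2)
    return ds


def method_spectral2(ds: CellByGeneDataset, k: int = 15) -> CellByGeneDataset:
    """Laplacian eigenmaps on a symmetrized k-NN graph of log-10k.

    The two nontrivial eigenvectors of the normalized graph Laplacian
    give the coordinates; a disconnected graph triggers an internal
    k increase (with a warning) until connected.
    """
    if ds.n_cells < 3:
        raise ValueError("need at least 3 cells")
    g = symmetric_knn_graph(ds.layers["log10k"], k)
    deg = np.asarray(g.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(np.maximum(deg, 1e-12)))
    lap = sp.identity(g.shape[0]) - d_inv_sqrt @ g @ d_inv_sqrt
    vals, vecs = scipy.sparse.linalg.eigsh(lap.tocsc(), k=3, sigma=-1e-9, which="LM")
    order = np.argsort(vals)
    coords = d_inv_sqrt @ vecs[:, order[1:3]]
    ds.embeddings[EMB] = np.asarray(coords)
    return ds


def control_random_coords(ds: CellByGeneDataset, seed: int = 0) -> CellByGeneDataset:
    """Negative control: i.i.d. standard-normal 2D coordinates."""
    rng = np.random.default_rng(seed)
    ds.embeddings[EMB] = rng.standard_normal((ds.n_cells, 2))
    return ds


def control_full_features(ds: CellByGeneDataset) -> CellByGeneDataset:
    """Positive control: the full log-10k matrix in place of 2D coordinates."""
    ds.embeddings[EMB] = np.asarray(ds.layers["log10k"])
    return ds


def _emb_ref(ds):
    if EMB not in ds.embeddings:
        raise ValueError("no embedding present")
    return np.asarray(ds.embeddings[EMB]), np.asarray(ds.layers["log10k"])


def metric_trustworthiness(ds: CellByGeneDataset, k: int = 15) -> float:
    """Rank-penalty trustworthiness of the embedding at ``k`` neighbors.

    Penalizes embedded neighbors that are not neighbors in the high-
    dimensional log-10k space; 1 means every embedded neighborhood is
    trustworthy.
    """
    emb, ref = _emb_ref(ds)
    n = emb.shape[0]
    if k >= n / 2:
        raise ValueError("k must be below n/2")
    return float(_sk_trustworthiness(ref, emb, n_neighbors=k))


def metric_distance_correlation(ds: CellByGeneDataset, max_cells: int = 1000) -> float:
    """Spearman correlation of pairwise distances, high- vs low-dimensional.

    Subsampled (with a fixed internal seed, so the metric stays pure)
    to at most ``max_cells`` cells; average ranks break distance ties.
    """
    emb, ref = _emb_ref(ds)
    n = emb.shape[0]
    if n > max_cells:
        idx = np.random.default_rng(0).choice(n, size=max_cells, replace=False)
        emb, ref = emb[idx], ref[idx]
    rho = spearmanr(pdist(ref), pdist(emb)).statistic
    return float(rho)


def _api_check(ds, stage: str = "pre"):
    assert "log10k" in ds.layers
    if stage == "post":
        emb = np.asarray(ds.embeddings[EMB])
        assert emb.shape[0] == ds.n_cells and emb.shape[1] >= 2
        assert np.all(np.isfinite(emb))


def _dataset(config: dict):
    params = dict(config or {})

    def fn(test_mode: bool = True, seed: int = 0):
        cfg = SyntheticConfig(**{**params, "seed": seed})
        if test_mode:
            cfg = test_scale(cfg)
        ds = make_celltype_counts(cfg)
        return ensure_log10k(ds)

    return fn


def build_task(config: dict | None = None) -> TaskSpec:
    task = TaskSpec(name=TASK, api_check=_api_check)
    register(task, DatasetDef("synthetic_celltypes", _dataset(config), TASK))
    register(task, MethodDef("full_features", control_full_features, TASK, "positive_control"))
    register(task, MethodDef("random_coords", control_random_coords, TASK, "negative_control"))
    register(task, MethodDef("pca2", method_pca2, TASK))
    register(task, MethodDef("spectral2", method_spectral2, TASK))
    register(task, MetricDef("trustworthiness", metric_trustworthiness, "maximize", TASK))
    register(task, MetricDef("distance_correlation", metric_distance_correlation, "maximize", TASK))
    return task
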