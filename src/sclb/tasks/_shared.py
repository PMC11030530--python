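"""Helpers shared by the task harnesses."""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from ..datamodel import CellByGeneDataset, normalize_log10k


def dense(m) -> np.ndarray:
    return np.asarray(m.todense()) if sp.issparse(m) else np.asarray(m)


def ensure_log10k(ds: CellByGeneDataset) -> CellByGeneDataset:
    """Compute the log-10k layer once; methods and metrics share it."""
    if "log10k" not in ds.layers:
        ds.layers["log10k"] = dense(normalize_log10k(ds.counts))
    return ds


def pca_embed(x: np.ndarray, n_components: int, seed: int = 0) -> np.ndarray:
    n_components = min(n_components, x.shape[0], x.shape[1])
    return PCA(n_components=n_components, random_state=seed).fit_transform(x)


def symmetric_knn_graph(x: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetrized k-NN connectivity graph; k grows until connected."""
    n = x.shape[0]
    k = min(k, n - 1)
    while True:
        g = kneighbors_graph(x, n_neighbors=k, mode="connectivity")
        g = g.maximum(g.T).tocsr()
        n_comp, _ = connected_components(g, directed=False)
        if n_comp == 1 or k >= n - 1:
            if n_comp > 1:
                warnings.warn("k-NN graph disconnected even at k = n - 1")
            return g
        k = min(2 * k, n - 1)
        warnings.warn(f"k-NN graph disconnected; increasing k to {k}")
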