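"""Matching modalities: align two views of the same cells in one latent space.

Jointly profiled cells are the ground truth: a perfect alignment places
each cell's two modality profiles at the same coordinates. Methods see
only the data (the pairing lives in the truth store and is stripped
from the working copy before any non-control method runs); the metric
is FOSCTTM — the fraction of samples closer than the true match,
averaged over both directions. 0 is perfect; a random pairing tends to
0.5; the fully adversarial arrangement reaches 1 (the true match is
excluded from the n-1 candidates, and ties count in the method's
favor).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from ..core import DatasetDef, MethodDef, MetricDef, TaskSpec, register
from ..datamodel import CellByGeneDataset
from ..synthetic import make_paired_modalities

TASK = "matching_modalities"


def method_shared_feature_svd(
    mod1: CellByGeneDataset, mod2: CellByGeneDataset, d: int = 10
):
    """Project both modalities' shared feature blocks into one SVD basis.

    Each modality's shared block is standardized per feature, the two
    standardized blocks are row-concatenated, and a rank-``d`` SVD
    basis fit on the concatenation projects each block. Component signs
    are fixed by making each basis vector's largest-magnitude loading
    positive, so the embedding is deterministic.
    """
    n_shared = int(mod1.truth["n_shared_features"])
    if d > n_shared:
        raise ValueError("d exceeds the shared feature block width")
    blocks = []
    for ds in (mod1, mod2):
        b = np.asarray(ds.layers["data"])[:, :n_shared]
        mu, sd = b.mean(axis=0), b.std(axis=0)
        blocks.append((b - mu) / np.where(sd > 0, sd, 1.0))
    stacked = np.vstack(blocks)
    _, _, vt = np.linalg.svd(stacked, full_matrices=False)
    basis = vt[:d].T
    flip = np.sign(basis[np.abs(basis).argmax(axis=0), np.arange(d)])
    basis = basis * flip
    return blocks[0] @ basis, blocks[1] @ basis


def control_true_coords(mod1: CellByGeneDataset, mod2: CellByGeneDataset, d: int = 10):
    """Positive control: paired cells share modality-1's coordinates exactly."""
    emb1, _ = method_shared_feature_svd(mod1, mod2, d)
    pairing = np.asarray(mod1.truth["pairing"], dtype=np.int64)
    emb2 = np.empty_like(emb1)
    emb2[pairing] = emb1
    return emb1, emb2


def control_shuffled(
    mod1: CellByGeneDataset, mod2: CellByGeneDataset, seed: int = 0, d: int = 10
):
    """Negative control: embed both, then permute modality-2 rows at random."""
    emb1, emb2 = method_shared_feature_svd(mod1, mod2, d)
    rng = np.random.default_rng(seed)
    return emb1, emb2[rng.permutation(emb2.shape[0])]


def metric_foscttm(emb1: np.ndarray, emb2: np.ndarray, pairing: np.ndarray) -> float:
    """Fraction of samples closer than the true match, symmetrized.

    For cell ``i`` in modality 1 with true match ``pairing[i]`` in
    modality 2: the fraction of the other ``n-1`` modality-2 cells
    strictly closer to ``emb1[i]`` than the match; averaged with the
    reverse direction and over cells.
    """
    emb1, emb2 = np.asarray(emb1), np.asarray(emb2)
    pairing = np.asarray(pairing, dtype=np.int64)
    n = emb1.shape[0]
    if emb2.shape[0] != n or sorted(pairing.tolist()) != list(range(n)):
        raise ValueError("pairing must be a permutation matching the row counts")
    d = cdist(emb1, emb2)
    rows = np.arange(n)
    d_true = d[rows, pairing]
    closer_12 = (d < d_true[:, None]).sum(axis=1)  # true match never < itself
    inv = np.empty(n, dtype=np.int64)
    inv[pairing] = rows
    d_true_2 = d[inv, rows]
    closer_21 = (d < d_true_2[None, :]).sum(axis=0)
    return float((closer_12.mean() + closer_21.mean()) / (2 * (n - 1)))


# -- harness plumbing ----------------------------------------------
# The runner passes one dataset, so the generator packs modality 2's
# view into the truth store; method wrappers strip the pairing from
# their working copy (non-control methods must never see it).

EMB1, EMB2 = "X_joint", "X_joint2"


def _unpack(ds):
    import pandas as pd

    x2 = np.asarray(ds.truth["mod2_data"])
    mod2 = CellByGeneDataset(
        counts=np.zeros(x2.shape, dtype=np.int64),
        cell_meta=pd.DataFrame(index=[f"c{i}" for i in range(x2.shape[0])]),
        gene_meta=pd.DataFrame(index=[f"f{j}" for j in range(x2.shape[1])]),
        layers={"data": x2},
        truth={"n_shared_features": ds.truth["n_shared_features"]},
    )
    return mod2


def _wrap_method(fn, blind: bool, seeded: bool = False):
    def wrapped(ds, seed: int = 0):
        mod2 = _unpack(ds)
        mod1 = ds
        if blind:
            mod1 = ds.copy()
            mod1.truth.pop("pairing")
        kwargs = {"seed": seed} if seeded else {}
        emb1, emb2 = fn(mod1, mod2, **kwargs)
        ds.embeddings[EMB1] = emb1
        ds.truth[EMB2] = emb2
        return ds

    return wrapped


def _metric(ds) -> float:
    return metric_foscttm(
        ds.embeddings[EMB1], np.asarray(ds.truth[EMB2]), ds.truth["pairing"]
    )


def _api_check(ds, stage: str = "pre"):
    assert "pairing" in ds.truth and "mod2_data" in ds.truth
    pairing = np.asarray(ds.truth["pairing"])
    assert sorted(pairing.tolist()) == list(range(ds.n_cells))
    if stage == "post":
        assert np.asarray(ds.embeddings[EMB1]).shape[0] == ds.n_cells
        assert np.asarray(ds.truth[EMB2]).shape[0] == ds.n_cells


def _dataset(config: dict):
    params = {
        "n_cells": 500,
        "d_latent": 10,
        "d1": 100,
        "d2": 80,
        "n_shared_features": 40,
        "noise_sd": 0.1,
    }
    params.update(config or {})

    def fn(test_mode: bool = True, seed: int = 0):
        p = dict(params)
        if test_mode:
            p["n_cells"] = min(p["n_cells"], 300)
        mod1, mod2 = make_paired_modalities(seed=seed, **p)
        mod1.truth["mod2_data"] = np.asarray(mod2.layers["data"])
        return mod1

    return fn


def build_task(config: dict | None = None) -> TaskSpec:
    task = TaskSpec(name=TASK, api_check=_api_check)
    register(task, DatasetDef("synthetic_paired", _dataset(config), TASK))
    register(task, MethodDef(
        "true_coords", _wrap_method(control_true_coords, blind=False),
        TASK, "positive_control",
    ))
    register(task, MethodDef(
        "shuffled", _wrap_method(control_shuffled, blind=False, seeded=True),
        TASK, "negative_control",
    ))
    register(task, MethodDef(
        "shared_feature_svd", _wrap_method(method_shared_feature_svd, blind=True), TASK
    ))
    register(task, MetricDef("foscttm", _metric, "minimize", TASK))
    return task
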