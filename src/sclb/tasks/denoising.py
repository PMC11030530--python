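"""Denoising with molecular cross-validation (MCV) evaluation.

Observed UMI counts are split binomially per entry into "train" and
"test" pseudo-replicates; denoisers see only the train layer and are
scored on how well their output (rescaled by ``(1-p)/p`` to match the
test layer's expected depth) predicts the held-out test counts. The
negative control returns the train layer unchanged; the positive
control returns the rescaled test layer itself — the best attainable
predictor of test given the split.
"""

from __future__ import annotations

import numpy as np

from ..core import DatasetDef, MethodDef, MetricDef, TaskSpec, register
from ..datamodel import CellByGeneDataset, normalize_log10k
from ..synthetic import SyntheticConfig, make_celltype_counts, test_scale
from ._shared import dense, pca_embed

TASK = "denoising"

P_TRAIN_DEFAULT = 0.9
EPS = 1e-6


def mcv_split(ds: CellByGeneDataset, p_train: float = P_TRAIN_DEFAULT, seed: int = 0):
    """Binomially thin each count into train/test layers (train + test == counts)."""
    if not 0 < p_train < 1:
        raise ValueError("p_train must be in (0, 1)")
    rng = np.random.default_rng(seed)
    counts = dense(ds.counts).astype(np.int64)
    train = rng.binomial(counts, p_train)
    ds.layers["train"] = train
    ds.layers["test"] = counts - train
    ds.truth["p_train"] = float(p_train)
    return ds


def _split(ds):
    if "train" not in ds.layers or "test" not in ds.layers:
        raise ValueError("dataset has no MCV split")
    return ds.layers["train"], ds.layers["test"], float(ds.truth["p_train"])


def control_identity(ds: CellByGeneDataset) -> CellByGeneDataset:
    """Negative control: the train layer, undenoised."""
    train, _, _ = _split(ds)
    ds.layers["denoised"] = train.astype(np.float64)
    return ds


def control_test_oracle(ds: CellByGeneDataset) -> CellByGeneDataset:
    """Positive control: the test layer rescaled by p/(1-p)."""
    _, test, p = _split(ds)
    ds.layers["denoised"] = test * (p / (1 - p))
    return ds


def method_knn_smoothing(ds: CellByGeneDataset, k: int = 10) -> CellByGeneDataset:
    """Average each cell's raw train counts over its k nearest neighbors.

    Neighbors (the cell itself included, so k=1 is the identity) are
    found in the top-30 PC space of log-10k-transformed train counts.
    """
    train, _, _ = _split(ds)
    if k >= ds.n_cells:
        raise ValueError("k must be below the number of cells")
    pcs = pca_embed(dense(normalize_log10k(train)), 30)
    from sklearn.neighbors import NearestNeighbors

    _, idx = NearestNeighbors(n_neighbors=k).fit(pcs).kneighbors(pcs)
    ds.layers["denoised"] = train[idx].mean(axis=1)
    return ds


def method_lowrank(ds: CellByGeneDataset, rank: int = 10) -> CellByGeneDataset:
    """Truncated-SVD reconstruction of log-10k train counts.

    The rank-``rank`` reconstruction is mapped back through expm1,
    negatives clamped to zero, and each row rescaled to the cell's
    train library size.
    """
    train, _, _ = _split(ds)
    x = dense(normalize_log10k(train))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    r = min(rank, s.size)
    recon = (u[:, :r] * s[:r]) @ vt[:r]
    expr = np.clip(np.expm1(recon), 0, None)
    row_tot = expr.sum(axis=1)
    lib = train.sum(axis=1)
    scale = np.divide(lib, row_tot, out=np.zeros_like(row_tot), where=row_tot > 0)
    ds.layers["denoised"] = expr * scale[:, None]
    return ds


def _lam_y(ds):
    if "denoised" not in ds.layers:
        raise ValueError("no denoised layer present")
    _, test, p = _split(ds)
    denoised = dense(ds.layers["denoised"])
    if denoised.min() < 0:
        raise ValueError("denoised layer has negative values; methods must clamp")
    # cross-split expectation matching: train-depth output scaled to test depth
    return denoised * ((1 - p) / p), dense(test)


def metric_mse_log10k(ds: CellByGeneDataset) -> float:
    """Mean squared error between log-10k of the rescaled denoised and test layers."""
    lam, y = _lam_y(ds)
    a = dense(normalize_log10k(lam))
    b = dense(normalize_log10k(y))
    return float(np.mean((a - b) ** 2))


def metric_poisson_loss(ds: CellByGeneDataset) -> float:
    """Mean Poisson deviance term ``lam - y*ln(lam)`` against test counts."""
    lam, y = _lam_y(ds)
    lam = lam + EPS
    return float(np.mean(lam - y * np.log(lam)))


def _api_check(ds, stage: str = "pre"):
    train, test, p = _split(ds)
    assert np.array_equal(dense(train) + dense(test), dense(ds.counts))
    if stage == "post":
        assert "denoised" in ds.layers


def _dataset(config: dict):
    params = dict(config or {})
    p_train = params.pop("p_train", P_TRAIN_DEFAULT)

    def fn(test_mode: bool = True, seed: int = 0):
        cfg = SyntheticConfig(**{**params, "seed": seed})
        if test_mode:
            cfg = test_scale(cfg)
        ds = make_celltype_counts(cfg)
        return mcv_split(ds, p_train=p_train, seed=seed + 1)

    return fn


def build_task(config: dict | None = None) -> TaskSpec:
    task = TaskSpec(name=TASK, api_check=_api_check)
    register(task, DatasetDef("synthetic_celltypes", _dataset(config), TASK))
    register(task, MethodDef("test_oracle", control_test_oracle, TASK, "positive_control"))
    register(task, MethodDef("identity", control_identity, TASK, "negative_control"))
    register(task, MethodDef("knn_smoothing", method_knn_smoothing, TASK))
    register(task, MethodDef("lowrank", method_lowrank, TASK))
    register(task, MetricDef("mse_log10k", metric_mse_log10k, "minimize", TASK))
    register(task, MetricDef("poisson_loss", metric_poisson_loss, "minimize", TASK))
    return task
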