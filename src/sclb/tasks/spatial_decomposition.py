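"""Spatial decomposition: recover cell-type proportions at capture spots.

Synthetic spots are Dirichlet mixtures of reference cells; methods see
the spot counts plus a labelled single-cell reference (packed into the
truth store by the dataset generator) and must produce a row-stochastic
spot-by-type proportion matrix. Recovery is scored by joint-entry R^2
and mean absolute error against the planted proportions.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.optimize

from ..core import DatasetDef, MethodDef, MetricDef, TaskSpec, register
from ..datamodel import CellByGeneDataset, cpm_normalize
from ..synthetic import SyntheticConfig, make_celltype_counts, make_spatial_mixture, test_scale
from ._shared import dense

TASK = "spatial_decomposition"

PRED_KEY = "proportions_pred"


def method_nnls(
    spots: CellByGeneDataset, reference: CellByGeneDataset
) -> np.ndarray:
    """Non-negative least squares against per-type reference signatures.

    Signatures are per-type means of CPM-normalized reference counts;
    each CPM spot profile is decomposed by NNLS and the solution
    renormalized to sum one (an all-zero solution falls back to a
    uniform row, with a warning).
    """
    if "label" not in reference.cell_meta:
        raise ValueError("reference lacks labels")
    if list(spots.gene_meta.index) != list(reference.gene_meta.index):
        raise ValueError("gene panels differ between spots and reference")
    type_order = spots.truth["type_order"]
    labels = np.asarray(reference.cell_meta["label"]).astype(str)
    missing = [t for t in type_order if t not in set(labels)]
    if missing:
        raise ValueError(f"reference lacks truth types: {missing}")
    ref_cpm = dense(cpm_normalize(reference.counts))
    signatures = np.stack(
        [ref_cpm[labels == t].mean(axis=0) for t in type_order]
    )  # n_types x n_genes
    spot_cpm = dense(cpm_normalize(spots.counts))
    out = np.zeros((spots.n_cells, len(type_order)))
    for s in range(spots.n_cells):
        x, _ = scipy.optimize.nnls(signatures.T, spot_cpm[s])
        tot = x.sum()
        if tot == 0:
            warnings.warn(f"all-zero NNLS solution for spot {s}; uniform fallback")
            out[s] = 1.0 / len(type_order)
        else:
            out[s] = x / tot
    return out


def method_de_novo(spots: CellByGeneDataset) -> np.ndarray:
    """Reference-free decomposition: a declared but unimplemented slot.

    De novo factorization leaves the inferred-factor-to-type matching
    ambiguous; until a matching rule is chosen this method reports
    failure, which the runner records as missing scores.
    """
    raise NotImplementedError(
        "de novo decomposition requires a factor-to-type matching rule"
    )


def control_random_proportions(spots: CellByGeneDataset, seed: int = 0) -> np.ndarray:
    """Negative control: flat-Dirichlet random proportion rows."""
    n_types = len(spots.truth["type_order"])
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(n_types), spots.n_cells)


def control_true_proportions(spots: CellByGeneDataset) -> np.ndarray:
    """Positive control: the planted proportions themselves."""
    if "proportions" not in spots.truth:
        raise ValueError("no ground-truth proportions present")
    return np.asarray(spots.truth["proportions"])


def metric_r2_proportions(pred: np.ndarray, truth: np.ndarray) -> float:
    """Joint-entry R^2 of predicted vs true proportions (about the global mean)."""
    pred, truth = _check_shapes(pred, truth)
    ss_res = float(((pred - truth) ** 2).sum())
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def metric_mae_proportions(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error over all proportion entries."""
    pred, truth = _check_shapes(pred, truth)
    return float(np.abs(pred - truth).mean())


def _check_shapes(pred, truth):
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def _api_check(ds, stage: str = "pre"):
    assert "proportions" in ds.truth and "type_order" in ds.truth
    props = np.asarray(ds.truth["proportions"])
    assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)
    if stage == "post":
        pred = np.asarray(ds.truth[PRED_KEY])
        assert pred.shape == props.shape
        assert pred.min() >= 0 and np.allclose(pred.sum(axis=1), 1.0, atol=1e-6)


def _unpack_reference(ds) -> CellByGeneDataset:
    import pandas as pd

    ref_counts = np.asarray(ds.truth["ref_counts"], dtype=np.int64)
    return CellByGeneDataset(
        counts=ref_counts,
        cell_meta=pd.DataFrame(
            {"label": np.asarray(ds.truth["ref_labels"]).astype(str)},
            index=[f"ref_{i:05d}" for i in range(ref_counts.shape[0])],
        ),
        gene_meta=ds.gene_meta.copy(),
    )


def _wrap(fn_needs_ref=False, fn=None, seeded=False):
    if fn_needs_ref:
        def wrapped(ds):
            ds.truth[PRED_KEY] = fn(ds, _unpack_reference(ds))
            return ds
    elif seeded:
        def wrapped(ds, seed=0):
            ds.truth[PRED_KEY] = fn(ds, seed=seed)
            return ds
    else:
        def wrapped(ds):
            ds.truth[PRED_KEY] = fn(ds)
            return ds
    return wrapped


def _metric_adapter(metric):
    def wrapped(ds):
        return metric(
            np.asarray(ds.truth[PRED_KEY]), np.asarray(ds.truth["proportions"])
        )
    return wrapped


def _dataset(config: dict):
    params = dict(config or {})
    n_spots = params.pop("n_spots", 100)
    cells_per_spot = params.pop("cells_per_spot_mean", 20)
    alpha = params.pop("dirichlet_alpha", 1.0)

    def fn(test_mode: bool = True, seed: int = 0):
        cfg = SyntheticConfig(**{**params, "seed": seed})
        if test_mode:
            cfg = test_scale(cfg)
        reference = make_celltype_counts(cfg)
        spots = make_spatial_mixture(
            reference,
            n_spots=min(n_spots, 50) if test_mode else n_spots,
            cells_per_spot_mean=cells_per_spot,
            dirichlet_alpha=alpha,
            seed=seed + 1,
        )
        spots.truth["ref_counts"] = np.asarray(reference.counts)
        spots.truth["ref_labels"] = np.asarray(
            reference.cell_meta["label"]
        ).astype(str)
        return spots

    return fn


def build_task(config: dict | None = None) -> TaskSpec:
    task = TaskSpec(name=TASK, api_check=_api_check)
    register(task, DatasetDef("synthetic_spots", _dataset(config), TASK))
    register(task, MethodDef(
        "true_proportions", _wrap(fn=control_true_proportions), TASK, "positive_control"
    ))
    register(task, MethodDef(
        "random_proportions", _wrap(fn=control_random_proportions, seeded=True),
        TASK, "negative_control",
    ))
    register(task, MethodDef("nnls", _wrap(fn_needs_ref=True, fn=method_nnls), TASK))
    register(task, MethodDef("de_novo", _wrap(fn=method_de_novo), TASK))
    register(task, MetricDef(
        "r2_proportions", _metric_adapter(metric_r2_proportions), "maximize", TASK
    ))
    register(task, MetricDef(
        "mae_proportions", _metric_adapter(metric_mae_proportions), "minimize", TASK
    ))
    return task
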