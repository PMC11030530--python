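"""Label projection: transfer cell-type labels from a reference to a query.

Datasets are divided into reference and query subsets; methods train on
the reference and predict cell-type labels for the query, which are
scored against the held-out truth. Two split modes ship as distinct
dataset variants: a per-label stratified random split and a
hold-one-batch-out split. The positive control copies the true labels;
the negative control samples predictions from the reference's empirical
label distribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.neighbors import NearestNeighbors

from ..core import DatasetDef, MethodDef, MetricDef, TaskSpec, register
from ..datamodel import CellByGeneDataset
from ..synthetic import SyntheticConfig, add_batch_effect, make_celltype_counts, test_scale
from ._shared import ensure_log10k, pca_embed

TASK = "label_projection"

PRED_COL = "label_pred"


def split_reference_query(
    ds: CellByGeneDataset,
    query_fraction: float = 0.25,
    by_batch: bool = False,
    seed: int = 0,
) -> CellByGeneDataset:
    """Partition cells into reference and query; mask query labels.

    Stratified mode draws ``query_fraction`` of each label's cells into
    the query; batch mode holds out one whole (seed-chosen) batch. True
    query labels move to ``truth["labels_query"]`` and the query entries
    of ``cell_meta["label"]`` are blanked.
    """
    if "label" not in ds.cell_meta:
        raise ValueError("dataset lacks labels")
    rng = np.random.default_rng(seed)
    labels = np.asarray(ds.cell_meta["label"]).astype(str)
    n = ds.n_cells
    mask = np.zeros(n, dtype=bool)
    if by_batch:
        if "batch" not in ds.cell_meta:
            raise ValueError("by_batch split requires batches")
        batches = np.asarray(ds.cell_meta["batch"]).astype(str)
        uniq = np.unique(batches)
        if len(uniq) < 2:
            raise ValueError("by_batch split requires at least two batches")
        held = uniq[rng.integers(len(uniq))]
        mask = batches == held
    else:
        if not 0 < query_fraction < 1:
            raise ValueError("query_fraction must be in (0, 1)")
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            k = int(round(query_fraction * idx.size))
            mask[rng.choice(idx, size=k, replace=False)] = True
    out = ds.copy()
    out.truth["labels_query"] = labels[mask]
    out.truth["query_mask"] = mask
    shown = pd.Series(labels, index=out.cell_meta.index, dtype=object)
    shown[mask] = "unknown"  # masked marker; synthetic labels never collide
    out.cell_meta["label"] = shown
    out.cell_meta["is_query"] = mask
    return out


def _query_mask(ds) -> np.ndarray:
    if "query_mask" not in ds.truth:
        raise ValueError("dataset has no reference/query split")
    return np.asarray(ds.truth["query_mask"], dtype=bool)


def control_true_labels(ds: CellByGeneDataset) -> CellByGeneDataset:
    """Positive control: copy the ground-truth labels into predictions."""
    mask = _query_mask(ds)
    pred = pd.Series(index=ds.cell_meta.index, dtype=object)
    pred[mask] = np.asarray(ds.truth["labels_query"])
    ds.cell_meta[PRED_COL] = pred
    return ds


def control_random_labels(ds: CellByGeneDataset, seed: int = 0) -> CellByGeneDataset:
    """Negative control: sample from the reference's label distribution."""
    mask = _query_mask(ds)
    rng = np.random.default_rng(seed)
    ref_labels = np.asarray(ds.cell_meta["label"])[~mask].astype(str)
    labs, counts = np.unique(ref_labels, return_counts=True)
    pred = pd.Series(index=ds.cell_meta.index, dtype=object)
    pred[mask] = rng.choice(labs, size=int(mask.sum()), p=counts / counts.sum())
    ds.cell_meta[PRED_COL] = pred
    return ds


def _features(ds) -> np.ndarray:
    ensure_log10k(ds)
    return ds.layers["log10k"]


def method_logistic_regression(ds: CellByGeneDataset) -> CellByGeneDataset:
    """L2-regularized multinomial logistic regression on log-10k features."""
    mask = _query_mask(ds)
    if (~mask).sum() == 0:
        raise ValueError("empty reference")
    x = _features(ds)
    y = np.asarray(ds.cell_meta["label"])[~mask].astype(str)
    clf = LogisticRegression(C=1.0, max_iter=2000)
    clf.fit(x[~mask], y)
    pred = pd.Series(index=ds.cell_meta.index, dtype=object)
    pred[mask] = clf.predict(x[mask])
    ds.cell_meta[PRED_COL] = pred
    return ds


def method_knn_classifier(ds: CellByGeneDataset, k: int = 15) -> CellByGeneDataset:
    """Majority vote among k reference neighbors on top-50 PCs of log-10k.

    Ties are broken toward the lexicographically smallest label.
    """
    mask = _query_mask(ds)
    if (~mask).sum() == 0:
        raise ValueError("empty reference")
    x = _features(ds)
    pcs = pca_embed(x, 50)
    ref, query = pcs[~mask], pcs[mask]
    y = np.asarray(ds.cell_meta["label"])[~mask].astype(str)
    k = min(k, ref.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    _, idx = nn.kneighbors(query)
    labs = np.unique(y)
    lab_codes = {l: i for i, l in enumerate(labs)}
    votes = np.zeros((query.shape[0], labs.size), dtype=np.int64)
    for col in range(k):
        np.add.at(votes, (np.arange(query.shape[0]),
                          [lab_codes[l] for l in y[idx[:, col]]]), 1)
    # argmax picks the first (smallest) label on ties
    winners = labs[votes.argmax(axis=1)]
    pred = pd.Series(index=ds.cell_meta.index, dtype=object)
    pred[mask] = winners
    ds.cell_meta[PRED_COL] = pred
    return ds


def _pred_truth(ds):
    mask = _query_mask(ds)
    if PRED_COL not in ds.cell_meta:
        raise ValueError("no predictions present")
    pred = np.asarray(ds.cell_meta[PRED_COL])[mask].astype(str)
    truth = np.asarray(ds.truth["labels_query"]).astype(str)
    return pred, truth


def metric_accuracy(ds: CellByGeneDataset) -> float:
    """Fraction of query cells whose predicted label matches the truth."""
    pred, truth = _pred_truth(ds)
    return float(np.mean(pred == truth))


def metric_macro_f1(ds: CellByGeneDataset) -> float:
    """Unweighted mean of per-label F1 over the truth's label set."""
    pred, truth = _pred_truth(ds)
    labels = np.unique(truth)
    return float(
        f1_score(truth, pred, labels=labels, average="macro", zero_division=0)
    )


def _api_check(ds, stage: str = "pre"):
    assert "query_mask" in ds.truth and "labels_query" in ds.truth
    mask = _query_mask(ds)
    assert mask.sum() == len(np.asarray(ds.truth["labels_query"]))
    if stage == "post":
        pred = np.asarray(ds.cell_meta[PRED_COL])[mask]
        assert not pd.isna(pred).any(), "missing query predictions"


def _dataset(by_batch: bool, config: dict):
    params = dict(config or {})
    q_frac = params.pop("query_fraction", 0.25)

    def fn(test_mode: bool = True, seed: int = 0):
        cfg = SyntheticConfig(**{**params, "seed": seed})
        if test_mode:
            cfg = test_scale(cfg)
        ds = make_celltype_counts(cfg)
        if by_batch:
            ds = add_batch_effect(ds, max(3, cfg.n_batches), cfg.batch_strength, seed + 1)
        return split_reference_query(
            ds, query_fraction=q_frac, by_batch=by_batch, seed=seed + 2
        )

    return fn


def build_task(config: dict | None = None) -> TaskSpec:
    task = TaskSpec(name=TASK, api_check=_api_check)
    register(task, DatasetDef("synthetic_random_split", _dataset(False, config), TASK))
    register(task, DatasetDef("synthetic_batch_split", _dataset(True, config), TASK))
    register(task, MethodDef("true_labels", control_true_labels, TASK, "positive_control"))
    register(task, MethodDef("random_labels", control_random_labels, TASK, "negative_control"))
    register(task, MethodDef("logistic_regression", method_logistic_regression, TASK))
    register(task, MethodDef("knn_classifier", method_knn_classifier, TASK))
    register(task, MetricDef("accuracy", metric_accuracy, "maximize", TASK))
    register(task, MetricDef("macro_f1", metric_macro_f1, "maximize", TASK))
    return task
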