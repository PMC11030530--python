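"""Cell-cell communication: ligand-receptor scoring and ranking evaluation.

Methods score every (source type, target type, ligand-receptor pair)
triple either by expression magnitude (mean of the ligand's log-10k
mean in the source type and the receptor's in the target type, gated
on 10% detection) or by cell-type specificity (label-permutation test
on the ungated magnitude score). Scores are aggregated to one of two
levels — source-target or ligand-target, each its own subtask — by
mean or max, and the resulting ranking is evaluated against planted
positives with stepwise AUPRC and the odds ratio of true pairs in the
top 5%.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from ..core import DatasetDef, MethodDef, MetricDef, TaskSpec, register
from ..datamodel import CellByGeneDataset
from ..synthetic import (
    LRDatabase,
    SyntheticConfig,
    build_lr_database,
    make_ccc_truth,
    make_celltype_counts,
    test_scale,
)
from ._shared import ensure_log10k

DETECTION_GATE = 0.1
TOP_FRACTION = 0.05


# -- scoring -------------------------------------------------------


def _type_stats(ds):
    ensure_log10k(ds)
    labels = np.asarray(ds.cell_meta["label"]).astype(str)
    types = sorted(np.unique(labels).tolist())
    x = np.asarray(ds.layers["log10k"])
    counts = np.asarray(ds.counts)
    means = np.stack([x[labels == t].mean(axis=0) for t in types])
    detect = np.stack([(counts[labels == t] > 0).mean(axis=0) for t in types])
    return types, means, detect


def _resolve_pairs(ds, lr_db: LRDatabase):
    gene_index = {g: j for j, g in enumerate(ds.gene_meta.index)}
    resolved = []
    for lig, rec in lr_db.pairs:
        if lig in gene_index and rec in gene_index:
            resolved.append((lig, rec, gene_index[lig], gene_index[rec]))
        else:
            warnings.warn(f"ligand-receptor pair ({lig}, {rec}) not in panel; skipped")
    return resolved


def _magnitude_matrix(means, detect, li, ri, gated: bool):
    """Scores for every (source, target) given ligand/receptor gene columns."""
    lig_m, rec_m = means[:, li], means[:, ri]  # per-type
    score = 0.5 * (lig_m[:, None] + rec_m[None, :])
    if gated:
        ok = (detect[:, li][:, None] >= DETECTION_GATE) & (
            detect[:, ri][None, :] >= DETECTION_GATE
        )
        score = np.where(ok, score, 0.0)
    return score


def score_magnitude(ds: CellByGeneDataset, lr_db: LRDatabase) -> pd.DataFrame:
    """Expression-magnitude scores for every (source, target, LR) triple.

    Score = mean of ligand's source-type mean and receptor's
    target-type mean log-10k expression, set to 0 unless both genes are
    detected in at least 10% of their respective type's cells.
    """
    types, means, detect = _type_stats(ds)
    rows = []
    for lig, rec, li, ri in _resolve_pairs(ds, lr_db):
        score = _magnitude_matrix(means, detect, li, ri, gated=True)
        for i, s in enumerate(types):
            for j, t in enumerate(types):
                rows.append((s, t, lig, rec, float(score[i, j])))
    return pd.DataFrame(
        rows, columns=["source", "target", "ligand", "receptor", "score"]
    )


def score_specificity(
    ds: CellByGeneDataset, lr_db: LRDatabase, n_perm: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Cell-type-specificity scores via label permutation.

    The ungated magnitude score is recomputed under ``n_perm`` label
    permutations; the score is the fraction of permutations with null
    strictly below the observed value, i.e. ``1 - (r + 1)/(n_perm + 1)``
    with ``r`` the count of null values at or above the observed (the
    add-one correction keeps scores off the boundaries).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    types, means, detect = _type_stats(ds)
    labels = np.asarray(ds.cell_meta["label"]).astype(str)
    x = np.asarray(ds.layers["log10k"])
    pairs = _resolve_pairs(ds, lr_db)
    observed = {
        p[:2]: _magnitude_matrix(means, detect, p[2], p[3], gated=False)
        for p in pairs
    }
    exceed = {p[:2]: np.zeros_like(observed[p[:2]], dtype=np.int64) for p in pairs}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = labels[rng.permutation(labels.size)]
        p_means = np.stack([x[perm == t].mean(axis=0) for t in types])
        for lig, rec, li, ri in pairs:
            null = _magnitude_matrix(p_means, detect, li, ri, gated=False)
            exceed[(lig, rec)] += null >= observed[(lig, rec)]
    rows = []
    for lig, rec, li, ri in pairs:
        spec = 1.0 - (exceed[(lig, rec)] + 1) / (n_perm + 1)
        for i, s in enumerate(types):
            for j, t in enumerate(types):
                rows.append((s, t, lig, rec, float(spec[i, j])))
    return pd.DataFrame(
        rows, columns=["source", "target", "ligand", "receptor", "score"]
    )


# -- aggregation and metrics ---------------------------------------

LEVEL_KEYS = {"source_target": ["source", "target"], "ligand_target": ["ligand", "target"]}


def aggregate(pred: pd.DataFrame, how: str, level: str) -> list:
    """Group triple scores to a level and rank keys by aggregated score.

    Returns ``[(key, score), ...]`` sorted descending, ties broken
    lexicographically by key so the ranking is deterministic.
    """
    if level not in LEVEL_KEYS:
        raise ValueError(f"unknown level {level!r}")
    if how not in ("mean", "max"):
        raise ValueError(f"unknown aggregation {how!r}")
    if pred.empty:
        raise ValueError("empty prediction table")
    cols = LEVEL_KEYS[level]
    agg = pred.groupby(cols, sort=False)["score"].agg(how)
    items = [((str(k[0]), str(k[1])), float(v)) for k, v in agg.items()]
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return items


def metric_auprc(ranked: list, truth_set) -> float:
    """Stepwise area under the precision-recall curve of a ranking.

    Positives absent from the ranking count as never retrieved (the
    recall denominator is the full truth-set size); no interpolation.
    """
    truth_set = set(truth_set)
    if not truth_set:
        raise ValueError("empty truth set")
    n_pos = len(truth_set)
    hits = 0
    area = 0.0
    for rank, (key, _) in enumerate(ranked, start=1):
        if key in truth_set:
            hits += 1
            area += (hits / rank) * (1.0 / n_pos)
    return area


def top_bin_size(n: int, top_fraction: float = TOP_FRACTION) -> int:
    """Number of ranked predictions in the top bin: ceil(fraction * n)."""
    return math.ceil(top_fraction * n)


def metric_odds_ratio_top(
    ranked: list, truth_set, top_fraction: float = TOP_FRACTION
) -> float:
    """Odds ratio of true pairs inside vs outside the top ``top_fraction``.

    The 2x2 contingency table counts positives/negatives in and below
    the top bin; the Haldane-Anscombe +0.5 correction is applied to all
    four cells whenever any is zero, keeping the ratio finite.
    """
    truth_set = set(truth_set)
    n = len(ranked)
    if n < 20:
        raise ValueError("need at least 20 ranked predictions")
    m = top_bin_size(n, top_fraction)
    top = {k for k, _ in ranked[:m]}
    rest = {k for k, _ in ranked[m:]}
    a = len(top & truth_set)
    b = len(top) - a
    c = len(rest & truth_set)
    d = len(rest) - c
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return float((a * d) / (b * c))


# -- harness plumbing ----------------------------------------------


def _truth_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(sorted(pairs), columns=["first", "second"])


def _truth_set(ds, level: str):
    key = "positive_st" if level == "source_target" else "positive_lt"
    df = ds.truth[key]
    return {(str(a), str(b)) for a, b in zip(df["first"], df["second"])}


def _lr_db_from_truth(ds) -> LRDatabase:
    df = ds.truth["lr_pairs"]
    return LRDatabase(pairs=tuple(zip(map(str, df["ligand"]), map(str, df["receptor"]))))


def _ranking_frame(ranked) -> pd.DataFrame:
    return pd.DataFrame(
        [(k[0], k[1], v) for k, v in ranked], columns=["first", "second", "score"]
    )


def _ranked_from_frame(df) -> list:
    return [((str(r["first"]), str(r["second"])), float(r["score"])) for _, r in df.iterrows()]


def _make_scoring_method(scorer: str, how: str, level: str):
    def fn(ds, seed: int = 0):
        lr_db = _lr_db_from_truth(ds)
        if scorer == "magnitude":
            pred = score_magnitude(ds, lr_db)
        else:
            pred = score_specificity(ds, lr_db, seed=seed)
        ds.truth["ranking"] = _ranking_frame(aggregate(pred, how, level))
        return ds

    return fn


def _all_keys(ds, level: str):
    types = sorted(np.unique(np.asarray(ds.cell_meta["label"]).astype(str)).tolist())
    if level == "source_target":
        return [(s, t) for s in types for t in types]
    ligands = sorted({str(l) for l in ds.truth["lr_pairs"]["ligand"]})
    return [(l, t) for l in ligands for t in types]


def _make_control(level: str, positive: bool):
    def fn(ds, seed: int = 0):
        rng = np.random.default_rng(seed)
        keys = _all_keys(ds, level)
        order = [keys[i] for i in rng.permutation(len(keys))]
        if positive:
            truth = _truth_set(ds, level)
            order = [k for k in order if k in truth] + [
                k for k in order if k not in truth
            ]
        ranked = [(k, float(len(order) - i)) for i, k in enumerate(order)]
        ds.truth["ranking"] = _ranking_frame(ranked)
        return ds

    return fn


def _make_metric(level: str, which: str):
    def fn(ds) -> float:
        ranked = _ranked_from_frame(ds.truth["ranking"])
        truth = _truth_set(ds, level)
        if which == "auprc":
            return metric_auprc(ranked, truth)
        return metric_odds_ratio_top(ranked, truth)

    return fn


def _make_api_check(level: str):
    def check(ds, stage: str = "pre"):
        assert "lr_pairs" in ds.truth
        assert _truth_set(ds, level)
        if stage == "post":
            assert "ranking" in ds.truth and len(ds.truth["ranking"]) > 0

    return check


def _dataset(config: dict):
    params = dict(config or {})
    n_true = params.pop("n_true_pairs", 8)
    effect_fold = params.pop("effect_fold", 20.0)
    n_lr = params.pop("n_lr_pairs", 50)
    params.setdefault("n_types", 5)  # >= 20 source-target keys for the odds ratio

    def fn(test_mode: bool = True, seed: int = 0):
        cfg = SyntheticConfig(**{**params, "seed": seed})
        if test_mode:
            cfg = test_scale(cfg)
        base = make_celltype_counts(cfg)
        lr_db = build_lr_database(base.gene_meta.index, n_pairs=n_lr, seed=seed + 1)
        ds, truth = make_ccc_truth(
            base, lr_db, n_true_pairs=n_true, effect_fold=effect_fold, seed=seed + 2
        )
        ds.truth["lr_pairs"] = pd.DataFrame(
            list(lr_db.pairs), columns=["ligand", "receptor"]
        )
        ds.truth["positive_st"] = _truth_frame(truth.positive_st)
        ds.truth["positive_lt"] = _truth_frame(truth.positive_lt)
        return ensure_log10k(ds)

    return fn


def build_task(level: str = "source_target", config: dict | None = None) -> TaskSpec:
    """Build one CCC subtask (``source_target`` or ``ligand_target``)."""
    if level not in LEVEL_KEYS:
        raise ValueError(f"unknown level {level!r}")
    name = f"ccc_{level}"
    task = TaskSpec(name=name, api_check=_make_api_check(level))
    register(task, DatasetDef("synthetic_planted", _dataset(config), name))
    register(task, MethodDef(
        "oracle_ranking", _make_control(level, positive=True), name, "positive_control"
    ))
    register(task, MethodDef(
        "random_ranking", _make_control(level, positive=False), name, "negative_control"
    ))
    for scorer in ("magnitude", "specificity"):
        for how in ("mean", "max"):
            register(task, MethodDef(
                f"{scorer}_{how}", _make_scoring_method(scorer, how, level), name
            ))
    register(task, MetricDef("auprc", _make_metric(level, "auprc"), "maximize", name))
    register(task, MetricDef(
        "odds_ratio_top5", _make_metric(level, "or"), "maximize", name
    ))
    return task
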