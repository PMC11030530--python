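"""Baseline-anchored score normalization, overall scores, and ranking.

Raw metric values live on arbitrary scales, so before averaging across
metrics each value is linearly rescaled per (dataset, metric) against
the task's control methods: the best control's oriented score maps to 1
and the worst control's to 0. Scores are not clipped — a method can be
arbitrarily worse than random and land well below 0. Each method's
overall score on a dataset is the mean of its non-missing normalized
scores, and methods are ranked per dataset in descending overall score
with competition ranking (ties share the smaller rank).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Optional, Tuple

import pandas as pd

from .registry import TaskSpec

__all__ = [
    "ScoreTable",
    "normalize_scores",
    "overall_score",
    "collate_subtasks",
    "CollatedScore",
]

Key3 = Tuple[str, str, str]  # (dataset, method, metric)
Key2 = Tuple[str, str]  # (dataset, method)


@dataclasses.dataclass
class ScoreTable:
    """Raw and normalized metric values indexed by (dataset, method, metric)."""

    raw: Dict[Key3, Optional[float]] = dataclasses.field(default_factory=dict)
    normalized: Dict[Key3, Optional[float]] = dataclasses.field(default_factory=dict)
    overall: Dict[Key2, Optional[float]] = dataclasses.field(default_factory=dict)
    rank: Dict[Key2, int] = dataclasses.field(default_factory=dict)
    resources: Dict[Key2, dict] = dataclasses.field(default_factory=dict)

    def datasets(self):
        return sorted({k[0] for k in self.raw})

    def methods(self):
        return sorted({k[1] for k in self.raw})

    def metrics(self):
        return sorted({k[2] for k in self.raw})

    def raw_frame(self) -> pd.DataFrame:
        return self._frame(self.raw)

    def normalized_frame(self) -> pd.DataFrame:
        return self._frame(self.normalized)

    @staticmethod
    def _frame(d: Dict[Key3, Optional[float]]) -> pd.DataFrame:
        rows = [
            {"dataset": k[0], "method": k[1], "metric": k[2], "value": v}
            for k, v in d.items()
        ]
        return pd.DataFrame(rows, columns=["dataset", "method", "metric", "value"])

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset": d,
                "method": m,
                "overall": self.overall.get((d, m)),
                "rank": self.rank.get((d, m)),
            }
            for (d, m) in sorted(self.overall)
        ]
        return pd.DataFrame(rows, columns=["dataset", "method", "overall", "rank"])


def _oriented(value: float, orientation: str) -> float:
    return value if orientation == "maximize" else -value


def normalize_scores(table: ScoreTable, task: TaskSpec) -> ScoreTable:
    """Anchor each (dataset, metric) column to the control methods.

    The optimum is the maximum oriented raw score over control-role
    methods and random performance the minimum; every method's score is
    mapped through ``(x - worst) / (best - worst)``. Degenerate anchors
    (best == worst, or a missing control score) leave the whole column
    missing, with a warning.
    """
    controls = [m.name for m in task.control_methods()]
    orient = {mx.name: mx.orientation for mx in task.metrics}
    for ds in table.datasets():
        for metric in table.metrics():
            o = orient[metric]
            anchor_vals = [
                _oriented(table.raw[(ds, c, metric)], o)
                for c in controls
                if table.raw.get((ds, c, metric)) is not None
            ]
            ok = len(anchor_vals) == len(controls) and len(anchor_vals) >= 2
            best = max(anchor_vals) if anchor_vals else None
            worst = min(anchor_vals) if anchor_vals else None
            if not ok or best == worst:
                warnings.warn(
                    f"degenerate baseline anchors for ({ds!r}, {metric!r}); "
                    "normalized scores left missing"
                )
                for meth in table.methods():
                    if (ds, meth, metric) in table.raw:
                        table.normalized[(ds, meth, metric)] = None
                continue
            for meth in table.methods():
                if (ds, meth, metric) not in table.raw:
                    continue
                raw = table.raw[(ds, meth, metric)]
                if raw is None:
                    table.normalized[(ds, meth, metric)] = None
                else:
                    table.normalized[(ds, meth, metric)] = (
                        _oriented(raw, o) - worst
                    ) / (best - worst)
    return table


def overall_score(table: ScoreTable) -> ScoreTable:
    """Average normalized scores per (dataset, method) and rank per dataset."""
    for ds in table.datasets():
        for meth in table.methods():
            vals = [
                v
                for (d, m, _), v in table.normalized.items()
                if d == ds and m == meth and v is not None
            ]
            table.overall[(ds, meth)] = sum(vals) / len(vals) if vals else None
        # descending overall; all-missing methods rank last; competition ranking
        scored = [(m, table.overall[(ds, m)]) for m in table.methods()]
        scored.sort(key=lambda t: (t[1] is None, -(t[1] if t[1] is not None else 0.0)))
        prev_val, prev_rank = object(), 0
        for i, (m, v) in enumerate(scored, start=1):
            if v is not None and v == prev_val:
                table.rank[(ds, m)] = prev_rank
            else:
                table.rank[(ds, m)] = i
                prev_rank, prev_val = i, v
    return table


@dataclasses.dataclass(frozen=True)
class CollatedScore:
    score: float
    n_subtasks: int
    partial: bool  # method was absent from at least one subtask


def collate_subtasks(tables, method_names=None) -> Dict[str, CollatedScore]:
    """Cross-subtask score: unweighted mean of per-subtask overall scores.

    Each table's per-method score is first averaged over its datasets;
    methods absent from some subtasks are averaged over the subtasks
    where they ran and flagged ``partial``. Methods absent everywhere
    are omitted.
    """
    per_table: list[Dict[str, float]] = []
    for t in tables:
        scores: Dict[str, list] = {}
        for (ds, m), v in t.overall.items():
            if v is not None:
                scores.setdefault(m, []).append(v)
        per_table.append({m: sum(v) / len(v) for m, v in scores.items()})
    if method_names is None:
        method_names = sorted({m for d in per_table for m in d})
    out: Dict[str, CollatedScore] = {}
    for m in method_names:
        vals = [d[m] for d in per_table if m in d]
        if not vals:
            continue
        out[m] = CollatedScore(
            score=sum(vals) / len(vals),
            n_subtasks=len(vals),
            partial=len(vals) < len(tables),
        )
    return out
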