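"""Component registry: tasks declared as datasets + methods + metrics.

A task bundles dataset generators (with a test-mode contract), methods
(including the positive/negative control roles that anchor score
normalization), and metrics (single-real-valued, with an orientation).
Maturity levels communicate whether a benchmark's guidance is
meaningful: a *stub* has at least one dataset, three methods, and one
metric; a *full* task at least two datasets, six methods, and a metric;
anything less is *under discussion*. Control methods count toward the
method tallies.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

__all__ = [
    "MetricDef",
    "MethodDef",
    "DatasetDef",
    "TaskSpec",
    "RegistrationError",
    "register",
    "classify_maturity",
    "CONTROL_ROLES",
]

CONTROL_ROLES = ("positive_control", "negative_control")


class RegistrationError(ValueError):
    """Invalid component registration (duplicate name or wrong task tag)."""


@dataclasses.dataclass(frozen=True)
class MetricDef:
    """A metric: dataset-with-method-output -> single float."""

    name: str
    fn: Callable
    orientation: str  # "maximize" | "minimize"
    task: str

    def __post_init__(self):
        if self.orientation not in ("maximize", "minimize"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclasses.dataclass(frozen=True)
class MethodDef:
    """A method: dataset -> dataset with output slots filled.

    ``role`` is ``"method"`` for candidate methods, or a control role
    (``"positive_control"`` / ``"negative_control"``) for the baselines
    that bound performance.
    """

    name: str
    fn: Callable
    task: str
    role: str = "method"

    def __post_init__(self):
        if self.role not in ("method",) + CONTROL_ROLES:
            raise ValueError(f"bad role {self.role!r}")


@dataclasses.dataclass(frozen=True)
class DatasetDef:
    """A dataset generator: ``fn(test_mode, seed) -> CellByGeneDataset``.

    ``fn(test_mode=True, ...)`` must return a dataset with at most 500
    cells; the same seed must reproduce the identical dataset.
    """

    name: str
    fn: Callable
    task: str


@dataclasses.dataclass
class TaskSpec:
    """A task's declared API plus its registered components."""

    name: str
    datasets: list = dataclasses.field(default_factory=list)
    methods: list = dataclasses.field(default_factory=list)
    metrics: list = dataclasses.field(default_factory=list)
    api_check: Optional[Callable] = None  # api_check(ds, stage="pre"|"post")

    def control_methods(self) -> list:
        return [m for m in self.methods if m.role in CONTROL_ROLES]


_KIND_TO_LIST = {MetricDef: "metrics", MethodDef: "methods", DatasetDef: "datasets"}


def register(task: TaskSpec, component) -> TaskSpec:
    """Add a component to a task, preserving registration order."""
    attr = _KIND_TO_LIST.get(type(component))
    if attr is None:
        raise RegistrationError(f"not a registrable component: {component!r}")
    if component.task != task.name:
        raise RegistrationError(
            f"component {component.name!r} is tagged for task "
            f"{component.task!r}, not {task.name!r}"
        )
    existing = getattr(task, attr)
    if any(c.name == component.name for c in existing):
        raise RegistrationError(
            f"duplicate {attr[:-1]} name {component.name!r} in task {task.name!r}"
        )
    existing.append(component)
    return task


def classify_maturity(task: TaskSpec) -> str:
    """Classify a task as ``full``, ``stub`` or ``under_discussion``."""
    nd, nm, nx = len(task.datasets), len(task.methods), len(task.metrics)
    if nd >= 2 and nm >= 6 and nx >= 1:
        return "full"
    if nd >= 1 and nm >= 3 and nx >= 1:
        return "stub"
    return "under_discussion"
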