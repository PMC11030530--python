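"""Benchmark runner: every method on every dataset with every metric.

A failing method records missing values for all its metrics on that
dataset (with a logged diagnostic) instead of aborting the run, so one
bad contribution never takes down a living benchmark. Wall-clock time
and peak RSS are recorded per (dataset, method) but never enter scores.
"""

from __future__ import annotations

import inspect
import logging
import resource
import sys
import time

from .registry import CONTROL_ROLES, TaskSpec
from .scoring import ScoreTable

__all__ = ["run_benchmark", "ConfigurationError"]

logger = logging.getLogger("sclb")


class ConfigurationError(ValueError):
    """The task is not runnable as configured."""


def _check_complete(task: TaskSpec) -> None:
    problems = []
    if not task.datasets:
        problems.append("no datasets")
    if not task.metrics:
        problems.append("no metrics")
    roles = {m.role for m in task.methods}
    for role in CONTROL_ROLES:
        if role not in roles:
            problems.append(f"missing {role}")
    if problems:
        raise ConfigurationError(
            f"task {task.name!r} is incomplete: {', '.join(problems)}"
        )


def _peak_rss_bytes() -> int:
    rss = resource.getrusage(resource.RUSAGE_SELF).ru_maxrss
    # ru_maxrss is KiB on Linux, bytes on macOS
    return rss * 1024 if sys.platform.startswith("linux") else rss


def _call_with_optional_seed(fn, ds, seed: int):
    params = inspect.signature(fn).parameters
    if "seed" in params:
        return fn(ds, seed=seed)
    return fn(ds)


def run_benchmark(task: TaskSpec, test_mode: bool = True, seed: int = 0) -> ScoreTable:
    """Run all of a task's methods on all its datasets with all metrics.

    ``test_mode`` is forwarded to dataset generators, which must then
    return down-scaled datasets (at most 500 cells). ``seed`` drives
    dataset generation and any seeded method; a per-(dataset, method)
    sub-seed below 2**31 is derived so runs are reproducible end to end.
    """
    _check_complete(task)
    table = ScoreTable()
    for ds_idx, dsdef in enumerate(task.datasets):
        t0 = time.perf_counter()
        ds = dsdef.fn(test_mode=test_mode, seed=seed)
        logger.info(
            "dataset %s generated in %.2fs (%d cells x %d genes)",
            dsdef.name, time.perf_counter() - t0, ds.n_cells, ds.n_genes,
        )
        if task.api_check is not None:
            task.api_check(ds, stage="pre")
        for m_idx, method in enumerate(task.methods):
            sub_seed = (seed * 1000003 + ds_idx * 1009 + m_idx * 7 + 1) % (2**31)
            work = ds.copy()
            t0 = time.perf_counter()
            try:
                out = _call_with_optional_seed(method.fn, work, sub_seed)
                if out is None:
                    out = work
                if task.api_check is not None:
                    task.api_check(out, stage="post")
            except Exception:
                logger.warning(
                    "method %s failed on dataset %s", method.name, dsdef.name,
                    exc_info=True,
                )
                out = None
            elapsed = time.perf_counter() - t0
            table.resources[(dsdef.name, method.name)] = {
                "runtime_s": elapsed,
                "peak_mem_bytes": _peak_rss_bytes(),
            }
            logger.info("method %s on %s: %.2fs", method.name, dsdef.name, elapsed)
            for metric in task.metrics:
                key = (dsdef.name, method.name, metric.name)
                if out is None:
                    table.raw[key] = None
                    continue
                try:
                    table.raw[key] = float(metric.fn(out))
                except Exception:
                    logger.warning(
                        "metric %s failed for method %s on dataset %s",
                        metric.name, method.name, dsdef.name, exc_info=True,
                    )
                    table.raw[key] = None
    return table
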