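import json
import pathlib

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_dataset
from sclb.core import (
    ConfigurationError,
    DatasetDef,
    MethodDef,
    MetricDef,
    RegistrationError,
    ScoreTable,
    TaskSpec,
    classify_maturity,
    collate_subtasks,
    export_results,
    json_schema,
    load_results,
    normalize_scores,
    overall_score,
    register,
    run_benchmark,
)
from sclb.core.results import ResultsDocument


def _noop_method(ds):
    return ds


def _dummy_task(n_datasets=0, n_methods=0, n_metrics=0):
    task = TaskSpec(name="toy")
    for i in range(n_datasets):
        register(task, DatasetDef(f"d{i}", lambda **k: None, "toy"))
    for i in range(n_methods):
        role = ("positive_control", "negative_control")[i] if i < 2 else "method"
        register(task, MethodDef(f"m{i}", _noop_method, "toy", role))
    for i in range(n_metrics):
        register(task, MetricDef(f"x{i}", lambda ds: 0.0, "maximize", "toy"))
    return task


class TestRegistry:
    def test_duplicate_name_rejected(self):
        task = _dummy_task(n_metrics=1)
        with pytest.raises(RegistrationError, match="duplicate"):
            register(task, MetricDef("x0", lambda ds: 0.0, "maximize", "toy"))

    def test_order_preserved(self):
        task = _dummy_task(n_methods=3)
        assert [m.name for m in task.methods] == ["m0", "m1", "m2"]

    def test_wrong_task_tag_rejected(self):
        task = _dummy_task()
        with pytest.raises(RegistrationError, match="tagged"):
            register(task, MethodDef("m", _noop_method, "denoising"))


@pytest.mark.parametrize(
    "shape,expected",
    [
        ((1, 3, 1), "stub"),
        ((2, 6, 1), "full"),
        ((1, 2, 1), "under_discussion"),
        ((2, 6, 0), "under_discussion"),
        ((1, 6, 1), "stub"),
        ((2, 5, 1), "stub"),
        ((0, 3, 1), "under_discussion"),
    ],
)
def test_maturity_thresholds(shape, expected):
    assert classify_maturity(_dummy_task(*shape)) == expected


def _toy_runnable_task(method_fns=None, metric_fns=None):
    """A tiny runnable task on a 6-cell synthetic dataset."""

    def dataset(test_mode=True, seed=0):
        rng = np.random.default_rng(seed)
        return make_dataset(rng.poisson(4.0, (6, 3)))

    task = TaskSpec(name="toy")
    register(task, DatasetDef("tiny", dataset, "toy"))
    method_fns = method_fns or {}
    register(task, MethodDef("pos", method_fns.get("pos", _noop_method), "toy", "positive_control"))
    register(task, MethodDef("neg", method_fns.get("neg", _noop_method), "toy", "negative_control"))
    metric_fns = metric_fns or {
        "total": lambda ds: float(np.asarray(ds.counts).sum()),
        "mean": lambda ds: float(np.asarray(ds.counts).mean()),
    }
    for name, fn in metric_fns.items():
        register(task, MetricDef(name, fn, "maximize", "toy"))
    return task


class TestRunner:
    def test_raw_has_every_triple(self):
        table = run_benchmark(_toy_runnable_task(), seed=0)
        assert len(table.raw) == 1 * 2 * 2
        assert all(v is not None for v in table.raw.values())
        assert ("tiny", "pos") in table.resources

    def test_failing_method_isolated(self):
        def boom(ds):
            raise RuntimeError("bad contribution")

        table = run_benchmark(_toy_runnable_task(method_fns={"neg": boom}), seed=0)
        assert table.raw[("tiny", "neg", "total")] is None
        assert table.raw[("tiny", "neg", "mean")] is None
        assert table.raw[("tiny", "pos", "total")] is not None

    def test_incomplete_task_rejected_before_execution(self):
        task = TaskSpec(name="toy")
        register(task, DatasetDef("d", lambda **k: None, "toy"))
        with pytest.raises(ConfigurationError, match="incomplete"):
            run_benchmark(task)

    def test_same_seed_reproducible(self):
        t1 = run_benchmark(_toy_runnable_task(), seed=7)
        t2 = run_benchmark(_toy_runnable_task(), seed=7)
        assert t1.raw == t2.raw


def _table_from_raw(raw):
    t = ScoreTable()
    t.raw = dict(raw)
    return t


def _anchor_task(orientation="maximize", n_extra_methods=2):
    task = TaskSpec(name="toy")
    register(task, MethodDef("pos", _noop_method, "toy", "positive_control"))
    register(task, MethodDef("neg", _noop_method, "toy", "negative_control"))
    for i in range(n_extra_methods):
        register(task, MethodDef(f"m{i}", _noop_method, "toy"))
    register(task, MetricDef("x", lambda ds: 0.0, orientation, "toy"))
    return task


class TestNormalization:
    def test_best_control_maps_to_one_and_worst_to_zero(self):
        raw = {
            ("d", "pos", "x"): 0.9,
            ("d", "neg", "x"): 0.2,
            ("d", "m0", "x"): 0.55,
            ("d", "m1", "x"): 0.0,
        }
        table = normalize_scores(_table_from_raw(raw), _anchor_task())
        assert table.normalized[("d", "pos", "x")] == 1.0
        assert table.normalized[("d", "neg", "x")] == 0.0
        assert table.normalized[("d", "m0", "x")] == pytest.approx(0.5)
        # sub-zero scores permitted: arbitrarily worse than random
        assert table.normalized[("d", "m1", "x")] == pytest.approx(-0.2857, abs=1e-4)

    def test_degenerate_anchors_warn_and_leave_missing(self):
        raw = {("d", "pos", "x"): 0.5, ("d", "neg", "x"): 0.5, ("d", "m0", "x"): 0.7}
        with pytest.warns(UserWarning, match="degenerate"):
            table = normalize_scores(_table_from_raw(raw), _anchor_task(n_extra_methods=1))
        assert table.normalized[("d", "m0", "x")] is None

    def test_missing_raw_stays_missing(self):
        raw = {("d", "pos", "x"): 1.0, ("d", "neg", "x"): 0.0, ("d", "m0", "x"): None}
        table = normalize_scores(_table_from_raw(raw), _anchor_task(n_extra_methods=1))
        assert table.normalized[("d", "m0", "x")] is None

    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
    )
    def test_affine_equivariance(self, a, b):
        raw = {("d", "pos", "x"): 0.9, ("d", "neg", "x"): 0.2, ("d", "m0", "x"): 0.4}
        base = normalize_scores(_table_from_raw(raw), _anchor_task(n_extra_methods=1))
        scaled = normalize_scores(
            _table_from_raw({k: a * v + b for k, v in raw.items()}),
            _anchor_task(n_extra_methods=1),
        )
        for k in raw:
            assert scaled.normalized[k] == pytest.approx(base.normalized[k], abs=1e-9)

    def test_orientation_flip_equivalence(self):
        raw = {("d", "pos", "x"): 0.1, ("d", "neg", "x"): 0.8, ("d", "m0", "x"): 0.3}
        as_min = normalize_scores(
            _table_from_raw(raw), _anchor_task("minimize", n_extra_methods=1)
        )
        as_max = normalize_scores(
            _table_from_raw({k: -v for k, v in raw.items()}),
            _anchor_task("maximize", n_extra_methods=1),
        )
        for k in raw:
            assert as_min.normalized[k] == pytest.approx(as_max.normalized[k])


class TestOverallAndRank:
    def test_overall_is_mean_and_ties_share_smaller_rank(self):
        t = ScoreTable()
        t.raw = {("d", m, x): 0.0 for m in ("a", "b", "c") for x in ("x", "y")}
        t.normalized = {
            ("d", "a", "x"): 1.0, ("d", "a", "y"): 0.5,
            ("d", "b", "x"): 0.5, ("d", "b", "y"): 1.0,
            ("d", "c", "x"): 0.1, ("d", "c", "y"): None,
        }
        overall_score(t)
        assert t.overall[("d", "a")] == pytest.approx(0.75)
        assert t.overall[("d", "b")] == pytest.approx(0.75)
        assert t.overall[("d", "c")] == pytest.approx(0.1)  # missing excluded
        assert t.rank[("d", "a")] == 1 and t.rank[("d", "b")] == 1
        assert t.rank[("d", "c")] == 3

    def test_all_missing_method_ranks_last(self):
        t = ScoreTable()
        t.raw = {("d", m, "x"): 0.0 for m in ("a", "b")}
        t.normalized = {("d", "a", "x"): 0.2, ("d", "b", "x"): None}
        overall_score(t)
        assert t.overall[("d", "b")] is None
        assert t.rank[("d", "b")] == 2


class TestCollate:
    def _table(self, overalls):
        t = ScoreTable()
        t.overall = overalls
        return t

    def test_mean_of_subtask_overalls(self):
        tables = [
            self._table({("d", "m"): 0.8}),
            self._table({("d", "m"): 0.6}),
        ]
        out = collate_subtasks(tables)
        assert out["m"].score == pytest.approx(0.7)
        assert not out["m"].partial

    def test_partial_coverage_flagged(self):
        tables = [self._table({("d", "m"): 0.9}), self._table({("d", "other"): 0.1})]
        out = collate_subtasks(tables)
        assert out["m"].score == pytest.approx(0.9)
        assert out["m"].partial and out["m"].n_subtasks == 1

    def test_identical_tables_idempotent(self):
        t = self._table({("d", "m"): 0.42})
        out = collate_subtasks([t, t, t])
        assert out["m"].score == pytest.approx(0.42)


class TestExport:
    def _run(self):
        task = _toy_runnable_task()
        table = run_benchmark(task, seed=3)
        normalize_scores(table, task)
        overall_score(table)
        return task, table

    def test_roundtrip_equality_with_missing_as_null(self, tmp_path):
        def boom(ds):
            raise RuntimeError

        task = _toy_runnable_task(method_fns={"neg": boom})
        table = run_benchmark(task, seed=3)
        normalize_scores(table, task)
        overall_score(table)
        out = tmp_path / "res.json"
        export_results(table, task, out, seed=3)
        raw_doc = json.loads(out.read_text())
        assert any(r["value"] is None for r in raw_doc["raw"])
        back, doc = load_results(out)
        assert back.raw == table.raw
        assert back.normalized == table.normalized
        assert back.overall == table.overall
        assert back.rank == table.rank
        assert doc.seed == 3

    def test_document_validates_against_shipped_schema(self, tmp_path):
        task, table = self._run()
        out = tmp_path / "res.json"
        export_results(table, task, out, seed=1)
        ResultsDocument.model_validate_json(out.read_text())
        shipped = json.loads(
            (
                pathlib.Path(__import__("sclb.core", fromlist=["x"]).__file__).parent
                / "results_schema.json"
            ).read_text()
        )
        assert shipped == json_schema()
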