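"""Result serialization: a versioned JSON document per benchmark run.

The document carries the task's component roster (names, roles, metric
orientations), the raw and normalized score tables, overall scores,
ranks and resource usage. Missing values serialize as ``null`` and load
back as missing. A JSON schema generated from the pydantic models ships
with the package (``results_schema.json``).
"""

from __future__ import annotations

import datetime
import json
import pathlib
from typing import List, Optional

from pydantic import BaseModel

from .registry import TaskSpec
from .scoring import ScoreTable

__all__ = ["ResultsDocument", "export_results", "load_results", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"


class MethodEntry(BaseModel):
    name: str
    role: str


class MetricEntry(BaseModel):
    name: str
    orientation: str


class Components(BaseModel):
    datasets: List[str]
    methods: List[MethodEntry]
    metrics: List[MetricEntry]


class ScoreRecord(BaseModel):
    dataset: str
    method: str
    metric: str
    value: Optional[float]


class SummaryRecord(BaseModel):
    dataset: str
    method: str
    overall: Optional[float]
    rank: Optional[int]


class ResourceRecord(BaseModel):
    dataset: str
    method: str
    runtime_s: float
    peak_mem_bytes: int


class ResultsDocument(BaseModel):
    schema_version: str
    task: str
    seed: Optional[int]
    timestamp: str
    components: Components
    raw: List[ScoreRecord]
    normalized: List[ScoreRecord]
    summary: List[SummaryRecord]
    resources: List[ResourceRecord]


def _score_records(d) -> List[ScoreRecord]:
    return [
        ScoreRecord(dataset=k[0], method=k[1], metric=k[2], value=v)
        for k, v in sorted(d.items())
    ]


def to_document(
    table: ScoreTable, task: TaskSpec, seed: Optional[int] = None
) -> ResultsDocument:
    return ResultsDocument(
        schema_version=SCHEMA_VERSION,
        task=task.name,
        seed=seed,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        components=Components(
            datasets=[d.name for d in task.datasets],
            methods=[MethodEntry(name=m.name, role=m.role) for m in task.methods],
            metrics=[
                MetricEntry(name=m.name, orientation=m.orientation)
                for m in task.metrics
            ],
        ),
        raw=_score_records(table.raw),
        normalized=_score_records(table.normalized),
        summary=[
            SummaryRecord(
                dataset=k[0],
                method=k[1],
                overall=table.overall.get(k),
                rank=table.rank.get(k),
            )
            for k in sorted(set(table.overall) | set(table.rank))
        ],
        resources=[
            ResourceRecord(
                dataset=k[0],
                method=k[1],
                runtime_s=v["runtime_s"],
                peak_mem_bytes=int(v["peak_mem_bytes"]),
            )
            for k, v in sorted(table.resources.items())
        ],
    )


def export_results(
    table: ScoreTable, task: TaskSpec, path, seed: Optional[int] = None
) -> None:
    """Write a benchmark run to ``path`` as a versioned JSON document."""
    doc = to_document(table, task, seed=seed)
    pathlib.Path(path).write_text(json.dumps(doc.model_dump(), indent=1))


def load_results(path):
    """Load an exported document back into a :class:`ScoreTable`.

    Returns ``(table, document)``; the document keeps the metadata
    (task name, components, seed, timestamp).
    """
    doc = ResultsDocument.model_validate_json(pathlib.Path(path).read_text())
    table = ScoreTable()
    for rec in doc.raw:
        table.raw[(rec.dataset, rec.method, rec.metric)] = rec.value
    for rec in doc.normalized:
        table.normalized[(rec.dataset, rec.method, rec.metric)] = rec.value
    for rec in doc.summary:
        table.overall[(rec.dataset, rec.method)] = rec.overall
        if rec.rank is not None:
            table.rank[(rec.dataset, rec.method)] = rec.rank
    for rec in doc.resources:
        table.resources[(rec.dataset, rec.method)] = {
            "runtime_s": rec.runtime_s,
            "peak_mem_bytes": rec.peak_mem_bytes,
        }
    return table, doc


def json_schema() -> dict:
    """The JSON schema of the results document."""
    return ResultsDocument.model_json_schema()
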