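"""The shipped benchmark tasks."""

from __future__ import annotations

from ..core import TaskSpec
from . import (
    batch_integration,
    ccc,
    denoising,
    dimred,
    label_projection,
    matching_modalities,
    spatial_decomposition,
)

_BUILDERS = {
    "label_projection": label_projection.build_task,
    "denoising": denoising.build_task,
    "dimred": dimred.build_task,
    "batch_integration": batch_integration.build_task,
    "spatial_decomposition": spatial_decomposition.build_task,
    "matching_modalities": matching_modalities.build_task,
    "ccc_source_target": lambda config=None: ccc.build_task("source_target", config),
    "ccc_ligand_target": lambda config=None: ccc.build_task("ligand_target", config),
}


def task_names() -> list:
    return sorted(_BUILDERS)


def get_task(name: str, config: dict | None = None) -> TaskSpec:
    if name not in _BUILDERS:
        raise KeyError(f"unknown task {name!r}; available: {task_names()}")
    return _BUILDERS[name](config=config)
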