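import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sclb import get_task, normalize_scores, overall_score, run_benchmark
from sclb.datamodel import CellByGeneDataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bench():
    """Run a task's full benchmark (test mode) once per session and cache it."""
    cache = {}

    def run(name, seed=1):
        key = (name, seed)
        if key not in cache:
            task = get_task(name)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = run_benchmark(task, test_mode=True, seed=seed)
                normalize_scores(table, task)
                overall_score(table)
            cache[key] = (task, table)
        return cache[key]

    return run


def make_dataset(counts, labels=None, batches=None, **kwargs):
    """Assemble a CellByGeneDataset from a raw count matrix."""
    counts = np.asarray(counts)
    meta = {}
    if labels is not None:
        meta["label"] = list(labels)
    if batches is not None:
        meta["batch"] = list(batches)
    cell_meta = pd.DataFrame(meta, index=[f"c{i}" for i in range(counts.shape[0])])
    gene_meta = pd.DataFrame(index=[f"g{j}" for j in range(counts.shape[1])])
    return CellByGeneDataset(
        counts=counts, cell_meta=cell_meta, gene_meta=gene_meta, **kwargs
    )


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(0)
    return make_dataset(rng.poisson(5.0, size=(10, 5)))
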