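"""Shared fixtures.

The expensive session fixtures (a full-size 62-subject cohort run and a
scaled-grid cohort) are computed once and shared by the acceptance tests;
unit tests use small purpose-built inputs instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from fncpipe import synth
from fncpipe.config import CohortConfig, RunConfig
from fncpipe.pipeline import run_pipeline


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-subject toy cohort on a small grid, short run: fast unit-test input."""
    spec = synth.default_cohort_spec(
        grid_dims=(16, 16, 12), n_volumes=80,
        group_sizes={"HC": 2, "MS": 2, "AS": 2},
    )
    return synth.simulate_cohort(spec, seed=11), spec


@pytest.fixture(scope="session")
def full_cohort_run():
    """The full study-scale cohort (62 subjects, 24x24x18 grid, 255
    volumes, 12 planted networks, default group effects) run end-to-end."""
    cfg = RunConfig(seed=101)
    return run_pipeline(cfg, write_outputs=False)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Small demo configuration executed with file outputs (CLI-scale)."""
    out = tmp_path_factory.mktemp("demo_run")
    cfg = RunConfig(
        seed=5, out_dir=str(out),
        cohort=CohortConfig(grid_dims=(16, 16, 12), n_volumes=80,
                            group_sizes={"HC": 3, "MS": 3, "AS": 3}),
    )
    return run_pipeline(cfg), cfg
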