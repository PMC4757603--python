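import logging

import numpy as np
import pandas as pd
import pytest

from msdrift import PeakMatrix, SimConfig, simulate_dataset, working_set

logging.getLogger("msdrift").setLevel(logging.ERROR)


def make_matrix(intensities, batches, roles, groups=None, rep_sets=None, timepoints=None):
    """Hand-build a PeakMatrix from parallel per-observation lists."""
    intensities = np.asarray(intensities, dtype=float)
    n = intensities.shape[0]
    obs = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1}" for i in range(n)],
            "run_index": range(1, n + 1),
            "batch": batches,
            "role": roles,
            "group": groups if groups is not None else [None] * n,
            "replicate_set": rep_sets if rep_sets is not None else [None] * n,
            "timepoint": timepoints if timepoints is not None else [None] * n,
        }
    )
    return PeakMatrix(intensities, obs)


@pytest.fixture
def two_batch_toy():
    """2 batches x (2 QCs + 3 experimental), 2 features, one replicate set per batch."""
    rng = np.random.default_rng(42)
    vals = rng.uniform(10, 100, size=(10, 2))
    batches = [1] * 5 + [2] * 5
    roles = ["QC", "experimental", "experimental", "experimental", "QC"] * 2
    groups = [None, "C", "C", "C", None, None, "D", "D", "D", None]
    reps = [None, "r1", "r1", "r1", None, None, "r2", "r2", "r2", None]
    return make_matrix(vals, batches, roles, groups, reps)


@pytest.fixture(scope="session")
def small_run():
    """A small but structurally complete simulated run (working set)."""
    cfg = SimConfig(n_batches=3, samples_per_batch=12, n_features=40, seed=7)
    matrix, truth = simulate_dataset(cfg)
    ws, _ = working_set(matrix)
    return ws, truth
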