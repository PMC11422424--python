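import numpy as np
import pandas as pd
import pytest

from ematraj.simulate import (
    CohortSpec,
    TrajectoryModelParams,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_cohort():
    """40 participants, well-separated latent classes, 30% MCAR missingness."""
    spec = CohortSpec(n_hc=12, n_re=8, n_pd=20, seed=11)
    params = TrajectoryModelParams(missing_rate=0.30)
    records, cohort, schedules = simulate_dataset(spec, params)
    return records, cohort, schedules


@pytest.fixture(scope="session")
def blob_distance_matrix():
    """Two far-separated blobs of 12 and 8 points: within-distance << between."""
    rng = np.random.default_rng(42)
    n1, n2 = 12, 8
    labels = np.array([0] * n1 + [1] * n2)
    n = n1 + n2
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = 1.0 if labels[i] == labels[j] else 50.0
            D[i, j] = D[j, i] = base + rng.uniform(0, 0.2)
    return D, labels


@pytest.fixture(scope="session")
def random_distance_matrix():
    """Generic symmetric distance matrix with distinct entries (8 points)."""
    rng = np.random.default_rng(7)
    n = 8
    X = rng.normal(size=(n, 3))
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    return D
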