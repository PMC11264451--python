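import numpy as np
import pandas as pd
import pytest

from pencure import CohortTable


def make_cohort(times, causes, X=None, names=None, cause_set=None):
    """Build a small CohortTable from raw arrays."""
    times = np.asarray(times, dtype=float)
    causes = np.asarray(causes, dtype=int)
    n = times.size
    data = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "time": times,
        "cause": causes,
    })
    if X is None:
        names = []
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        names = names or [f"x{j}" for j in range(X.shape[1])]
        for j, name in enumerate(names):
            data[name] = X[:, j]
    if cause_set is None:
        cause_set = frozenset({0, 1, 2} | set(int(c) for c in causes))
    return CohortTable(data, list(names), frozenset(cause_set))


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_weighted_fixture(rng):
    """20-row, 2-covariate fixture with fractional weights for M-step oracles."""
    n = 20
    X = np.column_stack([rng.integers(0, 2, n).astype(float), rng.normal(0, 1, n)])
    times = rng.exponential(5.0, n) + 0.1
    causes = rng.integers(0, 2, n)
    causes[:4] = 1  # guarantee events
    w = np.where(causes == 1, 1.0, rng.uniform(0.1, 0.9, n))
    cohort = make_cohort(times, causes, X, cause_set={0, 1})
    return cohort, w
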