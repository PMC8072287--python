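import numpy as np
import pandas as pd
import pytest

from cytoratio import SyntheticConfig, build_features, generate_cohort
from cytoratio.cohort import CYTOKINES, TIMEPOINTS


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort drawn from the default generative law (seed 1)."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    cohort, _ = default_cohort
    return build_features(cohort)


@pytest.fixture(scope="session")
def rnr_split(default_cohort, default_features):
    """(X_train, y_train, X_val, y_val) for the responder endpoint."""
    cohort, _ = default_cohort
    disc, val = cohort.split()
    y_d = (disc.labels()["rnr"] == "R").astype(int).to_numpy()
    y_v = (val.labels()["rnr"] == "R").astype(int).to_numpy()
    X = default_features.values
    return X.iloc[: disc.n_patients], y_d, X.iloc[disc.n_patients:], y_v


def make_cohort_frame(n=3, value=5.0):
    """Minimal valid cohort frame with constant concentrations."""
    rows = {
        "patient_id": [f"T{i}" for i in range(n)],
        "cohort": ["discovery"] * n,
        "best_response": ["PR", "SD", "PD"][:n] + ["PD"] * max(0, n - 3),
        "pfs_days": [100.0 + 10 * i for i in range(n)],
        "pfs_event": [1] * n,
        "os_days": [300.0 + 10 * i for i in range(n)],
        "os_event": [0] * n,
    }
    for c in CYTOKINES:
        for t in TIMEPOINTS:
            rows[f"{c}_{t}"] = [value] * n
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_frame():
    return make_cohort_frame()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
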