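import numpy as np
import pandas as pd
import pytest

from dynpred import (LandmarkConfig, LongitudinalDataset, PolynomialBasis,
                     SurvivalTable)
from dynpred.summaries import MarkerModel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def toy_long():
    """Two subjects, one marker, three visits each."""
    frame = pd.DataFrame({
        "id": [1, 1, 1, 2, 2, 2],
        "time": [0.0, 1.0, 2.0, 0.0, 1.5, 3.0],
        "marker": "m1",
        "value": [1.0, 1.5, 2.0, 0.5, 1.1, 2.2],
    })
    return LongitudinalDataset(frame)


@pytest.fixture(scope="session")
def toy_surv():
    return SurvivalTable(pd.DataFrame({
        "id": [1, 2, 3],
        "time": [3.0, 10.0, 5.5],
        "event": [1, 1, 0],
        "age": [60.0, 70.0, 65.0],
    }))


@pytest.fixture(scope="session")
def linear_marker_model():
    """Known-parameter random intercept + slope model, identity link."""
    return MarkerModel(
        marker="m1", family="gaussian",
        fixed_basis=PolynomialBasis(1), random_basis=PolynomialBasis(1),
        beta=np.array([1.0, 2.0]), cov_re=np.eye(2), sigma=0.5,
    )


@pytest.fixture(scope="session")
def small_landmark_cfg():
    return LandmarkConfig(t_landmark=4.0, t_horizon=3.0, cumulative_window=4.0)


@pytest.fixture(scope="session")
def survival_toy(rng):
    """A 200-subject (features, times, events) triple with real signal."""
    n = 200
    X = pd.DataFrame({
        "x1": rng.normal(size=n), "x2": rng.normal(size=n),
        "x3": rng.normal(size=n),
    })
    lp = 1.0 * X["x1"].to_numpy()
    T = rng.exponential(np.exp(-lp))
    C = rng.exponential(2.0, n)
    times = np.minimum(T, C)
    events = (T <= C).astype(int)
    return X, times, events
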