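import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pir_adl as pa

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return pa.default_layout()


@pytest.fixture(scope="session")
def specs():
    return pa.default_activity_specs()


@pytest.fixture(scope="session")
def noise():
    return pa.default_noise()


@pytest.fixture(scope="session")
def small_home(layout, specs, noise):
    """One simulated day of the reference home (fixed seed)."""
    return pa.simulate_home(layout, specs, noise, n_days=1, seed=11, home_id="home_test")


@pytest.fixture(scope="session")
def small_grid(small_home):
    return pa.preprocess_home(small_home)


def build_grid(
    pir: dict[str, np.ndarray],
    continuous: dict[str, np.ndarray] | None = None,
    truth: list[str] | None = None,
    visitor: np.ndarray | None = None,
) -> pd.DataFrame:
    """Hand-made feature grid: room -> PIR train, plus optional extras."""
    n = len(next(iter(pir.values())))
    data: dict[str, np.ndarray] = {}
    for room, v in pir.items():
        data[f"{room}_pir"] = np.asarray(v, dtype=float)
    for col, v in (continuous or {}).items():
        data[col] = np.asarray(v, dtype=float)
    grid = pd.DataFrame(data, index=pd.Index(np.arange(n) * 5, name="time_s"))
    grid["weekday"] = 0
    grid["truth_label"] = truth if truth is not None else pa.NO_ACTIVITY
    grid["truth_visitor"] = visitor if visitor is not None else 0
    return grid


@pytest.fixture
def grid_factory():
    return build_grid
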