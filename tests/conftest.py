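import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_experiment():
    """Two-plant full-schedule synthetic experiment shared across tests."""
    from soynose.simulate import ExperimentConfig, simulate_experiment

    return simulate_experiment(ExperimentConfig(n_plants=2, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240405)


def make_step_trace(sensor_index: int = 1, r0: float = 100.0, peak_pct: float = -25.0,
                    n: int = 12, n_baseline: int = 5):
    """Trace that sits at r0 for ``n_baseline`` samples then steps to the
    resistance corresponding to ``peak_pct`` sensitivity."""
    from soynose.acquisition import SensorId, SensorTrace

    r = np.full(n, r0 * (1.0 + peak_pct / 100.0))
    r[:n_baseline] = r0
    return SensorTrace(SensorId.from_index(sensor_index), np.arange(n, dtype=float), r)


@pytest.fixture()
def step_trace_factory():
    return make_step_trace
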