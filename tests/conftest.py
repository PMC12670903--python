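import numpy as np
import pytest

from ssokit import SimulationConfig, simulate_cohort
from ssokit.curves import PerfusionSeries


@pytest.fixture(scope="session")
def noise_free_config():
    """Deterministic generative conditions: no SI noise, no read errors."""
    return SimulationConfig(n_patients=200, noise_sd=0.0,
                            visual_sso_error_prob=0.0,
                            visual_sso_stress_error_prob=0.0, seed=11)


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_config):
    return simulate_cohort(noise_free_config)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimulationConfig(n_patients=179, seed=3))


def make_series(si, tissue="spleen", condition="stress", n_baseline=3, dt=1.0):
    si = np.asarray(si, dtype=float)
    return PerfusionSeries(tissue, condition, np.arange(len(si)) * dt, si, n_baseline)
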