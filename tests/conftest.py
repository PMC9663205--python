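import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

from gaitlfp import (GaitTimelineSpec, simulate_fsr, simulate_lfp,
                     simulate_timeline)
from gaitlfp.synth import ModulationSpec


@pytest.fixture(scope="session")
def timeline30():
    """30 jittered cycles, fixed seed; shared across detector tests."""
    return simulate_timeline(GaitTimelineSpec(n_cycles=30, seed=7))


@pytest.fixture(scope="session")
def kin30_clean(timeline30):
    return simulate_fsr(timeline30, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def kin30_noisy(timeline30):
    return simulate_fsr(timeline30, noise_sd=0.01, seed=2)


@pytest.fixture(scope="session")
def lfp30_stationary(timeline30):
    """One channel with an ungated (gain 0) 6-12 Hz component."""
    return simulate_lfp(
        timeline30, [ModulationSpec("stn", 6.0, 12.0, (0.0, 35.0), gain=0.0)],
        seed=3,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
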