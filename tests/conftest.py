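import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from phasedecode.simulate import SimConfig, simulate_subject


@pytest.fixture(scope="session")
def demo_config():
    return SimConfig(
        n_trials_per_condition=24, n_channels=8, mod_depth=0.6,
        pattern_snr=0.7, seed=11,
    )


@pytest.fixture(scope="session")
def demo_subject(demo_config):
    """One modulated subject shared across read-only tests."""
    return simulate_subject(demo_config, (11, 0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
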