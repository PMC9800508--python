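import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def surrogate_signal():
    """A fast 12-channel recording from the surrogate (OU) generator."""
    from mdls.simulate import SimulationConfig, simulate_recording

    cfg = SimulationConfig(duration_s=4.0, mode="surrogate", seed=3)
    return simulate_recording(cfg)


@pytest.fixture
def phasor_signal_small():
    """A short phasor-mode recording (2 s) for structural tests."""
    from mdls.simulate import SimulationConfig, simulate_recording

    cfg = SimulationConfig(duration_s=2.0, seed=5)
    return simulate_recording(cfg)
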