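import numpy as np
import pytest

from fatiguekit import SimulationConfig, simulate_recording

# Simulations in tests run at a reduced sampling rate and duration; the
# statistical structure (band powers, blink rates, closure fractions) is the
# package default.
TEST_FS = 200.0


@pytest.fixture(scope="session")
def recording_64s():
    """64 s alternating awake/fatigue recording (32 s each), fs=200."""
    return simulate_recording(SimulationConfig(duration_s=64.0, fs=TEST_FS, seed=7))


@pytest.fixture(scope="session")
def recording_config():
    return SimulationConfig(duration_s=64.0, fs=TEST_FS, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
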