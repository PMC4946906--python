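import numpy as np
import pytest

from swdkit import SimConfig, SWDParams, simulate_recording


@pytest.fixture(scope="session")
def short_benchmark():
    """A 15-minute synthetic recording with 4 injected discharges."""
    config = SimConfig(duration=900.0, seed=101, n_events=4)
    recording, truth = simulate_recording(config)
    return config, recording, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def default_swd():
    return SWDParams()
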