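import numpy as np
import pytest

from sotmr import closed_loop as cl
from sotmr import synthetic as syn
from sotmr.task import Hierarchy


@pytest.fixture(scope="session")
def so_train():
    """Continuous 1 Hz slow-oscillation train (deterministic trough times)."""
    return syn.periodic_so_recording(duration=900, period=1.0, so_freq=1.0,
                                     noise_scale=2.0, seed=3)


@pytest.fixture(scope="session")
def so_train_events(so_train):
    rec, _ = so_train
    schedule = cl.make_tmr_schedule(12, np.random.default_rng(2))
    return cl.run_closed_loop(rec, schedule)


@pytest.fixture(scope="session")
def night():
    """A stochastic simulated N3 night with default generator settings."""
    config = syn.SimConfig(duration=900, n_channels=8, seed=11)
    return syn.generate_sleep_eeg(config)


@pytest.fixture
def hierarchies():
    return [
        Hierarchy("Up", "faces", tuple("ABCDEF")),
        Hierarchy("Down", "scenes", tuple("GHIJKL")),
        Hierarchy("Control", "objects", tuple("MNOPQR")),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
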