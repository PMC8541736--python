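import numpy as np
import pytest

from risetrack.core import EodfTrace
from risetrack.synthetic import TrialConfig, generate_trial


@pytest.fixture(scope="session")
def default_trial():
    """One full-length synthetic trial at study defaults (seed 7)."""
    return generate_trial(TrialConfig(seed=7))


@pytest.fixture(scope="session")
def quiet_trial():
    """A trial with few rises and no triggered events (background only)."""
    cfg = TrialConfig(seed=11, n_rises=(30, 5), trigger_prob=0.0)
    return generate_trial(cfg)


@pytest.fixture
def flat_trace():
    t = np.arange(0.0, 1200.0, 0.33)
    return EodfTrace("flat", t, np.full(t.size, 700.0))


def make_trace(freq, dt=0.33, fish_id="fish"):
    freq = np.asarray(freq, dtype=float)
    return EodfTrace(fish_id, np.arange(freq.size) * dt, freq)
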