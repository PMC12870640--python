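import numpy as np
import pytest

from neuroloop.core import SeizureEvent
from neuroloop.simulate import SimConfig, simulate_eeg


@pytest.fixture(scope="session")
def short_recording():
    """10-minute 4-channel recording with one planted seizure."""
    cfg = SimConfig(
        n_channels=4, fs=64.0, duration=600.0,
        seizure_times=[(100.0, 160.0)], ictal_amplitude=100.0, noise_seed=7,
    )
    rec, truth = simulate_eeg(cfg)
    return rec, truth


@pytest.fixture
def grid_8s():
    """Uniform window grid: 6 hours at 8-s stride (10-s windows, 2-s overlap)."""
    stride = 8.0
    times = np.arange(0.0, 6 * 3600.0 - stride, stride)
    return times, stride


def make_events(intervals, source="model"):
    return [SeizureEvent(s, e, source=source) for s, e in intervals]
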