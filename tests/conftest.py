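import numpy as np
import pytest

from idras.datamodel import TimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ts(rng):
    """Two short 3-channel series of smooth + noisy structure."""
    series = []
    for i in range(2):
        t = np.arange(60)
        z = np.column_stack([
            np.sin(t / 10 + i) + 0.1 * rng.standard_normal(60),
            np.cos(t / 10 + i) + 0.1 * rng.standard_normal(60),
            rng.standard_normal(60),
        ])
        series.append((f"s{i}", z))
    return TimeSeriesSet(series, dt=0.5, channel_names=["a", "b", "c"])


@pytest.fixture
def iid_ts(rng):
    """Temporally structureless data: nothing to regulate."""
    series = [(f"s{i}", rng.standard_normal((200, 3))) for i in range(5)]
    return TimeSeriesSet(series, dt=1.0, channel_names=["x", "y", "z"])
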