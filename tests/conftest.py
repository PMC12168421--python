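import numpy as np
import pytest


@pytest.fixture
def eight_times():
    """The study's 8-point sampling grid: every 6 h over two 24-h cycles."""
    return np.arange(0.0, 48.0, 6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def cosinor_signal(times, mesor=10.0, amplitude=3.0, peak=14.0, period=24.0):
    t = np.asarray(times, dtype=float)
    return mesor + amplitude * np.cos(2.0 * np.pi * (t - peak) / period)
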