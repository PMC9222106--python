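import numpy as np
import pytest

from slowwave.core import TimeSeries
from slowwave.synth import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_cfg():
    """Small but analyzable synthetic configuration (120 s, 1 kHz)."""
    return SynthConfig(seed=7, duration_s=120.0)


def sine(freq, fs=1000.0, duration=60.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return TimeSeries(amplitude * np.sin(2 * np.pi * freq * t + phase), fs=fs, label="sine")


@pytest.fixture
def make_sine():
    return sine
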