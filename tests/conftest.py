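import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chronobench.emulator import SensorTrace

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


def square_wave_trace(epochs, total_ms, sample_hz=3000.0):
    """Binary luminance trace with bright (start_ms, duration_ms) epochs."""
    n = int(np.ceil(total_ms * sample_hz / 1000.0)) + 1
    lum = np.zeros(n)
    for start, dur in epochs:
        i0 = int(np.ceil(start * sample_hz / 1000.0 - 1e-9))
        i1 = int(np.ceil((start + dur) * sample_hz / 1000.0 - 1e-9))
        lum[i0:i1] = 1.0
    return SensorTrace(
        time_ms=np.arange(n) * (1000.0 / sample_hz), luminance=lum, sample_hz=sample_hz
    )


@pytest.fixture
def make_trace():
    return square_wave_trace
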