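import numpy as np
import pytest

from bpvhht.signal_io import LightSchedule, TimeSeriesSignal


@pytest.fixture
def schedule_3h() -> LightSchedule:
    return LightSchedule(light_h=3.0, dark_h=3.0)


@pytest.fixture
def schedule_12h() -> LightSchedule:
    return LightSchedule(light_h=12.0, dark_h=12.0)


def make_sine(period_s: float, dt: float, n_periods: float, amp: float = 1.0,
              phase: float = 0.0) -> TimeSeriesSignal:
    n = int(round(period_s * n_periods / dt))
    t = dt * np.arange(n)
    return TimeSeriesSignal(t=t, x=amp * np.sin(2 * np.pi * t / period_s + phase),
                            dt=dt)


@pytest.fixture
def sine_24h() -> TimeSeriesSignal:
    """Pure diel sinusoid, 4 periods at the chronoamperometry sampling rate."""
    return make_sine(24 * 3600.0, 120.0, 4)
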