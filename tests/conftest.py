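import numpy as np
import pytest

from oscsync.synthdata import ReceptorParams


def trace_from_peak_times(peak_times, fs=97.7, amp=1.0, t_end=None):
    """Unit-amplitude oscillation whose peaks fall exactly at peak_times (ms).

    Cumulative phase is piecewise linear with value 2*pi*k at the k-th peak,
    extended at the edge slopes; the trace is amp * cos(phase).
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if t_end is None:
        t_end = peak_times[-1] + (peak_times[-1] - peak_times[-2])
    t = np.arange(0.0, t_end, 1.0 / fs)
    k = np.arange(peak_times.size)
    slope_lo = (k[1] - k[0]) / (peak_times[1] - peak_times[0])
    slope_hi = (k[-1] - k[-2]) / (peak_times[-1] - peak_times[-2])
    cycles = np.interp(t, peak_times, k)
    before = t < peak_times[0]
    after = t > peak_times[-1]
    cycles[before] = k[0] + slope_lo * (t[before] - peak_times[0])
    cycles[after] = k[-1] + slope_hi * (t[after] - peak_times[-1])
    return t, amp * np.cos(2 * np.pi * cycles)


@pytest.fixture
def osc_params():
    """Standard oscillating receptor used across evoked-response tests."""
    return ReceptorParams(mode="oscillating", f0=2.0, mu=0.25, kappa=0.5, noise_sd=0.1, spont_amp=1.0)


@pytest.fixture
def spiking_params():
    """Noise-free spiking receptor with 1-ms refractory period."""
    return ReceptorParams(
        mode="spiking", latency=0.3, refractory=1.0, threshold_charge=1.0, jitter_sd=0.0
    )
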