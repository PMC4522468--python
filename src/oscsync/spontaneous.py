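"""Spontaneous-activity characterization.

Median filtering, alternating peak/trough detection, averaged-FFT
oscillation frequency, amplitude with the inclusion criterion, interspike
intervals, and differential-recording spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

from .synthdata import EventTrain

__all__ = [
    "SpontaneousStats",
    "median_filter_trace",
    "detect_peaks_troughs",
    "spontaneous_stats",
    "interspike_intervals",
    "differential_psd_peaks",
]


@dataclass(frozen=True)
class SpontaneousStats:
    f_spont: float  # kHz
    period: float  # ms (1 / f_spont)
    amplitude: float  # mV (peak minus following trough, averaged)
    passes_criterion: bool  # amplitude >= max(2.5 * noise_floor, 0.1 mV)
    noise_floor: float  # mV


def median_filter_trace(trace: np.ndarray, sample_rate: float, width: float = 0.1) -> np.ndarray:
    """Running median of ``width`` ms, reflected at the edges; length preserved."""
    trace = np.asarray(trace, dtype=float)
    n_w = int(round(width * sample_rate))
    if n_w % 2 == 0:
        n_w += 1
    if n_w < 3:
        raise ValueError(f"filter width {width} ms is < 3 samples at {sample_rate} kHz")
    return ndimage.median_filter(trace, size=n_w, mode="reflect")


def _refine_extremum(trace: np.ndarray, idx: int, sample_rate: float) -> tuple:
    """Sub-sample parabolic refinement of a local extremum at sample idx."""
    if idx <= 0 or idx >= trace.size - 1:
        return idx / sample_rate, float(trace[idx])
    y0, y1, y2 = trace[idx - 1], trace[idx], trace[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return idx / sample_rate, float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    v = y1 - 0.25 * (y0 - y2) * delta
    return (idx + delta) / sample_rate, float(v)


def detect_peaks_troughs(
    trace: np.ndarray,
    sample_rate: float,
    min_separation: float = 0.0,
    prominence: Optional[float] = None,
) -> dict:
    """Local extrema in strict peak-trough alternation.

    Returns dict with 'peak_times', 'peak_values', 'trough_times',
    'trough_values' (ms / mV; times refined to sub-sample resolution), plus
    an 'empty' flag when no extrema are found. Where two extrema of the
    same kind occur in a row, the more extreme one is kept.
    """
    trace = np.asarray(trace, dtype=float)
    dist = max(int(round(min_separation * sample_rate)), 1)
    if prominence is None:
        prominence = 2.0 * 1.4826 * float(np.median(np.abs(np.diff(trace)))) if trace.size > 1 else 0.0
        prominence = max(prominence, 1e-12)
    pk, _ = signal.find_peaks(trace, distance=dist, prominence=prominence)
    tr, _ = signal.find_peaks(-trace, distance=dist, prominence=prominence)
    if pk.size == 0 and tr.size == 0:
        return {
            "peak_times": np.array([]),
            "peak_values": np.array([]),
            "trough_times": np.array([]),
            "trough_values": np.array([]),
            "empty": True,
        }
    idx = np.concatenate([pk, tr])
    kind = np.concatenate([np.ones(pk.size, dtype=int), -np.ones(tr.size, dtype=int)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    # enforce alternation: within a run of equal kinds keep the most extreme
    keep_idx, keep_kind = [], []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            if k * trace[i] > k * trace[keep_idx[-1]]:
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
            keep_kind.append(k)
    pt, pv, tt, tv = [], [], [], []
    for i, k in zip(keep_idx, keep_kind):
        t, v = _refine_extremum(trace, int(i), sample_rate)
        if k > 0:
            pt.append(t)
            pv.append(v)
        else:
            tt.append(t)
            tv.append(v)
    return {
        "peak_times": np.asarray(pt),
        "peak_values": np.asarray(pv),
        "trough_times": np.asarray(tt),
        "trough_values": np.asarray(tv),
        "empty": False,
    }


def _averaged_magnitude_spectrum(recordings: Sequence[np.ndarray], sample_rate: float):
    n = min(len(r) for r in recordings)
    mags = [np.abs(np.fft.rfft(np.asarray(r[:n], dtype=float) - np.mean(r[:n]))) for r in recordings]
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    return freqs, np.mean(mags, axis=0)


def spontaneous_stats(
    recordings: Sequence[np.ndarray],
    sample_rate: float,
    noise_floor: float,
    n_expected: int = 5,
    f_min: float = 0.3,
    f_max: float = 3.5,
) -> SpontaneousStats:
    """Spontaneous oscillation frequency, period, and amplitude.

    Frequency is the argmax of the magnitude spectrum averaged across the
    (nominally five 1-s) recordings; period is its inverse. Amplitude is
    each trough voltage subtracted from the preceding peak voltage, averaged
    across all pairs and recordings. The inclusion criterion passes when
    amplitude >= max(2.5 * noise_floor, 0.1 mV).
    """
    if len(recordings) == 0:
        raise ValueError("need at least one recording")
    if len(recordings) < n_expected:
        warnings.warn(
            f"spontaneous_stats: {len(recordings)} recordings given, {n_expected} expected; computing anyway",
            stacklevel=2,
        )
    freqs, mag = _averaged_magnitude_spectrum(recordings, sample_rate)
    band = (freqs >= f_min) & (freqs <= f_max)
    if not np.any(band):
        raise ValueError("search band is empty at this sampling rate")
    f_spont = float(freqs[band][np.argmax(mag[band])])

    amps = []
    for rec in recordings:
        filt = median_filter_trace(np.asarray(rec, dtype=float), sample_rate)
        ext = detect_peaks_troughs(filt, sample_rate, min_separation=0.25 / f_spont)
        if ext["empty"]:
            continue
        for tt, tv in zip(ext["trough_times"], ext["trough_values"]):
            before = ext["peak_times"] < tt
            if np.any(before):
                amps.append(ext["peak_values"][before][-1] - tv)
    amplitude = float(np.mean(amps)) if amps else 0.0
    passes = amplitude >= max(2.5 * noise_floor, 0.1)
    return SpontaneousStats(
        f_spont=f_spont,
        period=1.0 / f_spont,
        amplitude=amplitude,
        passes_criterion=bool(passes),
        noise_floor=float(noise_floor),
    )


def amplitude_criterion(amplitude: float, noise_floor: float) -> bool:
    """Inclusion criterion: at least 2.5x baseline noise and >= 0.1 mV."""
    return amplitude >= max(2.5 * noise_floor, 0.1)


def interspike_intervals(events: EventTrain) -> np.ndarray:
    """Successive differences between event times (ms); empty for < 2 events."""
    if events.n_events < 2:
        return np.array([])
    return np.diff(events.times)


def noise_floor_estimate(trace: np.ndarray) -> float:
    """Robust SD (MAD * 1.4826) of a stimulus- and oscillation-free segment."""
    trace = np.asarray(trace, dtype=float)
    return float(1.4826 * np.median(np.abs(trace - np.median(trace))))


def differential_psd_peaks(
    trace: np.ndarray,
    sample_rate: float,
    band: tuple = (0.5, 3.5),
    rel_prominence: float = 0.05,
) -> dict:
    """Welch-spectrum peaks within a band plus an amplitude-envelope report.

    Multiple nearby oscillators produce multiple spectral peaks and beats;
    the modulation index is (max - min)/(max + min) of the Hilbert envelope
    (edges trimmed) and the modulation frequency the spectral peak of the
    envelope fluctuation.
    """
    lo, hi = band
    nyq = sample_rate / 2.0
    if not (0 < lo < hi <= nyq):
        raise ValueError("band must be within (0, Nyquist]")
    trace = np.asarray(trace, dtype=float) - np.mean(trace)
    nper = min(4096, trace.size)
    freqs, psd = signal.welch(trace, fs=sample_rate, nperseg=nper, window="hann")
    m = (freqs >= lo) & (freqs <= hi)
    pk, _ = signal.find_peaks(psd[m], prominence=rel_prominence * psd[m].max())
    peak_freqs = freqs[m][pk]

    env = np.abs(signal.hilbert(trace))
    n_trim = max(int(0.05 * env.size), 1)
    env_in = env[n_trim:-n_trim]
    emax, emin = float(env_in.max()), float(env_in.min())
    mod_index = (emax - emin) / (emax + emin) if (emax + emin) > 0 else 0.0
    fluct = env_in - env_in.mean()
    f_env, p_env = signal.welch(fluct, fs=sample_rate, nperseg=min(8192, fluct.size))
    mod_freq = float(f_env[np.argmax(p_env[1:]) + 1]) if p_env.size > 1 else 0.0
    return {
        "peak_freqs": np.asarray(peak_freqs),
        "n_peaks": int(peak_freqs.size),
        "mod_index": float(mod_index),
        "mod_freq": mod_freq,
    }
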