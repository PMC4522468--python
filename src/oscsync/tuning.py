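"""Frequency tuning: spiking threshold curves, oscillating vector-strength
curves, stimulus peak frequency, EOD spectra/durations, octave distances."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy import signal

__all__ = [
    "TuningCurve",
    "spiking_response_criterion",
    "spiking_threshold_curve",
    "stimulus_peak_frequency",
    "oscillating_tuning_curve",
    "eod_spectrum_duration",
    "octave_distance",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TuningCurve:
    frequencies: np.ndarray  # kHz, strictly increasing
    measure: np.ndarray  # threshold dB re best frequency, or vector strength
    best_frequency: float  # kHz
    mode: str  # threshold | vector_strength
    open_points: Optional[np.ndarray] = None  # frequencies with no response at any intensity


def spiking_response_criterion(
    stim_counts: np.ndarray, prestim_counts: np.ndarray
) -> bool:
    """Response = at least one more spike/sweep during the stimulus window
    than during the equal-length prestimulus window (boundary inclusive)."""
    stim_counts = np.asarray(stim_counts, dtype=float)
    prestim_counts = np.asarray(prestim_counts, dtype=float)
    if stim_counts.shape != prestim_counts.shape:
        raise ValueError("stimulus and prestimulus counts must pair per sweep")
    return bool(stim_counts.mean() - prestim_counts.mean() >= 1.0)


def count_spikes_in_windows(sweep_set, threshold: float, stim_window: float = 90.0) -> tuple:
    """Per-sweep spike counts in the stimulus window and the equal-length
    prestimulus window ending at stimulus onset."""
    from .evoked import _spike_peaks

    t_on = sweep_set.t_stim_on
    total_ms = sweep_set.sweeps.shape[1] / sweep_set.sample_rate
    if t_on < stim_window or t_on + stim_window > total_ms:
        raise ValueError("windows exceed sweep bounds")
    stim_counts, pre_counts = [], []
    for row in sweep_set.sweeps:
        t_sp = _spike_peaks(row, sweep_set.sample_rate, threshold)
        stim_counts.append(np.sum((t_sp >= t_on) & (t_sp < t_on + stim_window)))
        pre_counts.append(np.sum((t_sp >= t_on - stim_window) & (t_sp < t_on)))
    return np.asarray(stim_counts), np.asarray(pre_counts)


def spiking_threshold_curve(responses: Dict[float, Dict[float, bool]]) -> TuningCurve:
    """Threshold tuning from a {frequency: {intensity: responded}} grid.

    Threshold per frequency = lowest responding intensity; best frequency =
    argmin threshold; curve reported as dB = 20 log10(threshold /
    threshold at best frequency). Frequencies with no responding intensity
    become open points (NaN measure).
    """
    freqs = np.asarray(sorted(responses), dtype=float)
    thresholds = np.full(freqs.size, np.nan)
    for i, f in enumerate(freqs):
        responding = [inten for inten, ok in responses[f].items() if ok]
        if responding:
            thresholds[i] = min(responding)
    if np.all(np.isnan(thresholds)):
        raise ValueError("no responding intensity at any frequency")
    finite = np.nanmin(thresholds)
    candidates = np.where(thresholds == finite)[0]
    if candidates.size > 1:
        log.info("threshold tie at %s kHz; choosing the lowest frequency", freqs[candidates])
    best_i = int(candidates[0])
    best_f = float(freqs[best_i])
    db = 20.0 * np.log10(thresholds / thresholds[best_i])
    open_points = freqs[np.isnan(thresholds)]
    return TuningCurve(
        frequencies=freqs,
        measure=db,
        best_frequency=best_f,
        mode="threshold",
        open_points=open_points if open_points.size else None,
    )


def _welch_peak(wave: np.ndarray, sample_rate: float) -> float:
    wave = np.asarray(wave, dtype=float)
    if np.ptp(wave) == 0.0:
        raise ValueError("flat waveform: spectrum has no peak")
    nper = min(4096, wave.size)
    nfft = max(2 * wave.size, 1 << 16)
    freqs, psd = signal.welch(
        wave, fs=sample_rate, window="hann", nperseg=nper, noverlap=nper // 2, nfft=nfft
    )
    i = int(np.argmax(psd[1:]) + 1)  # skip DC
    return float(freqs[i])


def stimulus_peak_frequency(single_cycle_wave: np.ndarray, sample_rate: float) -> float:
    """Welch-spectrum argmax of a sampled stimulus (kHz).

    For a single-cycle bipolar sine this peak sits slightly below the
    inverse of the cycle duration.
    """
    return _welch_peak(single_cycle_wave, sample_rate)


def oscillating_tuning_curve(vs_by_freq: Dict[int, Dict[float, float]]) -> TuningCurve:
    """Vector-strength tuning from {polarity: {frequency: vector strength}}.

    Best frequency per polarity = argmax vector strength (ties resolved to
    the lowest frequency, logged); when polarities disagree the receptor's
    best frequency is the mean of the two.
    """
    bests = {}
    all_freqs, all_vs = None, {}
    for pol, curve in vs_by_freq.items():
        freqs = np.asarray(sorted(curve), dtype=float)
        vs = np.asarray([curve[f] for f in freqs])
        winners = np.where(vs == vs.max())[0]
        if winners.size > 1:
            log.info("vector-strength tie for polarity %d at %s kHz; choosing lowest", pol, freqs[winners])
        bests[pol] = float(freqs[winners[0]])
        all_freqs = freqs if all_freqs is None else all_freqs
        all_vs[pol] = vs
    best_frequency = float(np.mean(list(bests.values())))
    measure = np.mean([all_vs[p] for p in all_vs], axis=0)
    return TuningCurve(
        frequencies=all_freqs, measure=measure, best_frequency=best_frequency, mode="vector_strength"
    )


def eod_spectrum_duration(eod_wave: np.ndarray, sample_rate: float) -> dict:
    """Welch peak-power frequency (kHz) and total duration (ms) of an EOD.

    Duration spans the first through last samples where the absolute value
    exceeds 0.5% of the maximum peak-to-peak amplitude.
    """
    wave = np.asarray(eod_wave, dtype=float)
    if np.all(wave == 0.0):
        raise ValueError("all-zero waveform")
    peak = _welch_peak(wave, sample_rate)
    thresh = 0.005 * (wave.max() - wave.min())
    above = np.nonzero(np.abs(wave) > thresh)[0]
    duration = (above[-1] - above[0] + 1) / sample_rate
    return {"peak_power_freq": peak, "total_duration": float(duration)}


def octave_distance(best_frequency: float, peak_power_freq: float) -> float:
    """log2(best_frequency / peak_power_freq), in octaves."""
    if best_frequency <= 0 or peak_power_freq <= 0:
        raise ValueError("frequencies must be positive")
    return float(np.log2(best_frequency / peak_power_freq))
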