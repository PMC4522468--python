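"""Stimulus-evoked response quantification.

Oscillatory phase resets (phi, vector strength, delta-phi), evoked
amplitudes and enhancement, oscillation-timing and interoscillation
intervals, paired-pulse normalization, population synchrony, and spiking
measures (probability, latency, timing differences, pair intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .circstats import AngleSample, vector_strength
from .spontaneous import detect_peaks_troughs, median_filter_trace, noise_floor_estimate
from .synthdata import SweepSet

__all__ = [
    "PhaseResetMeasurement",
    "PolarityPairMeasurement",
    "EvokedOscillationSummary",
    "measure_poststimulus_oscillation",
    "delta_phase",
    "polarity_pair_measurement",
    "oscillation_timing_difference",
    "interoscillation_interval",
    "paired_pulse_normalized_amplitude",
    "duration_series_amplitude",
    "population_sum",
    "measure_spike_response",
    "spike_timing_difference",
    "pair_interspike_interval",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PhaseResetMeasurement:
    lat: float  # ms, designated first poststimulus peak relative to stimulus offset
    p: float  # ms, first poststimulus period
    phi: float  # radians in [0, 2 pi): 2 pi * (lat mod p) / p
    used_second_peak: bool
    peak_time: float  # ms, absolute time of the designated peak within the sweep
    partial: bool = False  # fewer than 7 poststimulus peaks available


@dataclass(frozen=True)
class PolarityPairMeasurement:
    lat_n: float  # ms (negative polarity)
    p_n: float
    lat_p: float  # ms (positive polarity)
    p_p: float

    def __post_init__(self) -> None:
        if self.p_n <= 0 or self.p_p <= 0:
            raise ValueError("periods must be > 0")


@dataclass(frozen=True)
class EvokedOscillationSummary:
    amplitude: float  # mV, poststimulus (mean of first two peaks minus trough)
    prestim_amplitude: float  # mV
    normalized_amplitude: float
    vector_strength: float
    mean_phase: float  # radians
    n_sweeps: int


def _designated_peak(trace: np.ndarray, sample_rate: float, offset: float,
                     min_separation: float = 0.15, prominence: Optional[float] = None) -> dict:
    """Seven-peak measurement after ``offset`` on a (filtered) trace.

    Measures the first six poststimulus periods; if the first period is
    outside 85-115% of the mean of the next five, the first peak is deemed
    artifact-contaminated and the second peak is designated instead.
    """
    ext = detect_peaks_troughs(trace, sample_rate, min_separation=min_separation, prominence=prominence)
    if ext["empty"]:
        raise ValueError("no oscillatory extrema detected")
    post = ext["peak_times"] > offset
    pk_t = ext["peak_times"][post]
    pk_v = ext["peak_values"][post]
    if pk_t.size < 2:
        raise ValueError("fewer than two poststimulus peaks detected")
    partial = pk_t.size < 7
    if partial:
        warnings.warn(
            f"only {pk_t.size} poststimulus peaks detected (< 7); artifact rule skipped",
            stacklevel=2,
        )
    periods = np.diff(pk_t[: min(pk_t.size, 7)])
    use_second = False
    if not partial:
        mean_next5 = float(np.mean(periods[1:6]))
        if periods[0] < 0.85 * mean_next5 or periods[0] > 1.15 * mean_next5:
            use_second = True
    k0 = 1 if use_second else 0
    if pk_t.size < k0 + 2:
        raise ValueError("not enough peaks after applying the artifact rule")
    lat = float(pk_t[k0] - offset)
    p = float(pk_t[k0 + 1] - pk_t[k0])
    phi = _TWO_PI * ((lat % p) / p)
    # amplitude: mean of the two designated peaks minus the intervening trough
    between = (ext["trough_times"] > pk_t[k0]) & (ext["trough_times"] < pk_t[k0 + 1])
    amp = np.nan
    if np.any(between):
        amp = float(0.5 * (pk_v[k0] + pk_v[k0 + 1]) - ext["trough_values"][between][0])
    return {
        "lat": lat,
        "p": p,
        "phi": float(phi),
        "used_second_peak": use_second,
        "peak_time": float(pk_t[k0]),
        "partial": partial,
        "amplitude": amp,
        "peak_times": pk_t,
        "extrema": ext,
    }


def _prestim_amplitude(ext: dict, t_on: float) -> float:
    """Peak-minus-following-trough amplitudes entirely before stimulus onset."""
    amps = []
    for tt, tv in zip(ext["trough_times"], ext["trough_values"]):
        if tt >= t_on:
            break
        before = ext["peak_times"] < tt
        if np.any(before):
            amps.append(ext["peak_values"][before][-1] - tv)
    return float(np.mean(amps)) if amps else np.nan


def measure_poststimulus_oscillation(
    sweeps: SweepSet,
    offset_ms: Optional[float] = None,
    min_separation: float = 0.15,
    filter_width: float = 0.1,
) -> dict:
    """Per-sweep phase-reset measurements plus the across-sweep summary.

    Each sweep is median filtered (0.1 ms), the first seven poststimulus
    peaks located, the artifact rule applied, and lat / p / phi measured
    from the stimulus offset (or ``offset_ms`` when given, e.g. the offset
    of the second pulse in a pair). Vector strength is computed across the
    per-sweep phi values.
    """
    offset = sweeps.t_stim_off if offset_ms is None else offset_ms
    per_sweep, amps, pre_amps = [], [], []
    for row in sweeps.sweeps:
        filt = median_filter_trace(row, sweeps.sample_rate, width=filter_width)
        meas = _designated_peak(filt, sweeps.sample_rate, offset, min_separation=min_separation)
        per_sweep.append(
            PhaseResetMeasurement(
                lat=meas["lat"],
                p=meas["p"],
                phi=meas["phi"],
                used_second_peak=meas["used_second_peak"],
                peak_time=meas["peak_time"],
                partial=meas["partial"],
            )
        )
        if np.isfinite(meas["amplitude"]):
            amps.append(meas["amplitude"])
        pre = _prestim_amplitude(meas["extrema"], sweeps.t_stim_on)
        if np.isfinite(pre):
            pre_amps.append(pre)
    vs = vector_strength(AngleSample(np.array([m.phi for m in per_sweep])))
    amplitude = float(np.mean(amps)) if amps else np.nan
    pre_amplitude = float(np.mean(pre_amps)) if pre_amps else np.nan
    norm = amplitude / pre_amplitude if pre_amps and pre_amplitude > 0 else np.nan
    summary = EvokedOscillationSummary(
        amplitude=amplitude,
        prestim_amplitude=pre_amplitude,
        normalized_amplitude=norm,
        vector_strength=vs["r"],
        mean_phase=vs["mean_angle"],
        n_sweeps=sweeps.n_sweeps,
    )
    return {"per_sweep": per_sweep, "summary": summary}


def measure_on_average(
    sweeps: SweepSet,
    offset_ms: Optional[float] = None,
    min_separation: float = 0.15,
    filter_width: float = 0.1,
) -> dict:
    """Designated-peak measurement on the across-sweep averaged trace."""
    offset = sweeps.t_stim_off if offset_ms is None else offset_ms
    filt = median_filter_trace(sweeps.average(), sweeps.sample_rate, width=filter_width)
    return _designated_peak(filt, sweeps.sample_rate, offset, min_separation=min_separation)


def delta_phase(pair: PolarityPairMeasurement, reduce: bool = True) -> dict:
    """Opposite-polarity reset phase difference in degrees.

    delta_phi = (lat_N - lat_P) / ((p_N + p_P) / 2) * 360. ``raw`` is the
    unreduced value; ``delta_phi`` is reduced modulo 360 into (-180, 180]
    when ``reduce`` is set.
    """
    raw = (pair.lat_n - pair.lat_p) / ((pair.p_n + pair.p_p) / 2.0) * 360.0
    reduced = raw
    if reduce:
        reduced = ((raw + 180.0) % 360.0) - 180.0
        if reduced == -180.0:
            reduced = 180.0
    return {"delta_phi": float(reduced), "raw": float(raw)}


def polarity_pair_measurement(pos: SweepSet, neg: SweepSet, **kwargs) -> PolarityPairMeasurement:
    """Measure lat/p for each polarity on averaged traces (averaging first)."""
    if pos.stimulus is not None and neg.stimulus is not None:
        if pos.stimulus.polarity != 1 or neg.stimulus.polarity != -1:
            raise ValueError("expected pos with polarity +1 and neg with polarity -1")
    mp = measure_on_average(pos, **kwargs)
    mn = measure_on_average(neg, **kwargs)
    return PolarityPairMeasurement(lat_n=mn["lat"], p_n=mn["p"], lat_p=mp["lat"], p_p=mp["p"])


def _first_peak_after(sweeps: SweepSet, t_ref: float, min_separation: float = 0.15) -> float:
    filt = median_filter_trace(sweeps.average(), sweeps.sample_rate)
    ext = detect_peaks_troughs(filt, sweeps.sample_rate, min_separation=min_separation)
    after = ext["peak_times"][ext["peak_times"] > t_ref]
    if after.size == 0:
        raise ValueError("no oscillatory peak found after the reference time")
    return float(after[0])


def oscillation_timing_difference(pos: SweepSet, neg: SweepSet, pulse_duration: float) -> float:
    """Opposite-polarity first-peak timing difference (ms), averages first.

    For pulse durations > 0.5 ms the positive-polarity peak is referenced to
    stimulus onset and the negative-polarity peak to stimulus offset; the
    negative-referenced peak time is subtracted from the positive-referenced
    one. For durations <= 0.5 ms both are referenced to stimulus offset.
    """
    if pos.stimulus is not None and neg.stimulus is not None:
        if pos.stimulus.polarity == neg.stimulus.polarity:
            raise ValueError("sweep sets must have opposite polarities")
    if pulse_duration > 0.5:
        t_pos = _first_peak_after(pos, pos.t_stim_on)
        t_neg = _first_peak_after(neg, neg.t_stim_off)
    else:
        t_pos = _first_peak_after(pos, pos.t_stim_off)
        t_neg = _first_peak_after(neg, neg.t_stim_off)
    return float(t_pos - t_neg)


def _second_pulse_offset(pair: SweepSet) -> float:
    spec = pair.stimulus
    if spec is None or spec.kind != "pulse_pair":
        raise ValueError("pair sweep set must carry a pulse_pair stimulus")
    fs = spec.sample_rate
    d_eff = np.floor(spec.duration * fs) / fs
    return pair.t_stim_on + round(spec.ipi * fs) / fs + d_eff


def interoscillation_interval(
    single: SweepSet,
    pair: SweepSet,
    offset_single: Optional[float] = None,
    offset_pair: Optional[float] = None,
    min_separation: float = 0.15,
) -> float:
    """Interval between the designated first peak after a single pulse and
    the designated first peak after the second pulse of a pair (ms).

    Both measurements are made on across-sweep averaged traces of sweep
    sets aligned on the first pulse. With a faithful per-pulse reset this
    equals the IPI.
    """
    if single.stimulus is not None and pair.stimulus is not None:
        if single.stimulus.polarity != pair.stimulus.polarity:
            raise ValueError("single and pair must share polarity")
        if single.stimulus.duration != pair.stimulus.duration:
            raise ValueError("single and pair must share pulse duration")
    if offset_single is None:
        offset_single = single.t_stim_off
    if offset_pair is None:
        offset_pair = _second_pulse_offset(pair) if pair.stimulus is not None else pair.t_stim_off
    m_single = measure_on_average(single, offset_ms=offset_single, min_separation=min_separation)
    m_pair = measure_on_average(pair, offset_ms=offset_pair, min_separation=min_separation)
    return float(m_pair["peak_time"] - m_single["peak_time"])


def paired_pulse_normalized_amplitude(pair: SweepSet, single_ref: SweepSet) -> float:
    """Mean oscillation amplitude after the second pulse of a pair divided by
    the mean amplitude after a single matching-polarity 0.2-ms pulse."""
    if pair.stimulus is not None and single_ref.stimulus is not None:
        if pair.stimulus.polarity != single_ref.stimulus.polarity:
            raise ValueError("pair and single reference must share polarity")
    amp_pair = measure_poststimulus_oscillation(pair, offset_ms=_second_pulse_offset(pair))[
        "summary"
    ].amplitude
    amp_single = measure_poststimulus_oscillation(single_ref)["summary"].amplitude
    if not np.isfinite(amp_single) or amp_single == 0.0:
        raise ValueError("zero or unmeasurable single-pulse reference amplitude")
    return float(amp_pair / amp_single)


def duration_series_amplitude(sweep_sets: Dict[float, SweepSet]) -> dict:
    """Normalized (post/pre) oscillation amplitude vs square-pulse duration."""
    durations = sorted(sweep_sets)
    ratios = []
    for d in durations:
        summary = measure_poststimulus_oscillation(sweep_sets[d])["summary"]
        ratios.append(summary.normalized_amplitude)
    ratios = np.asarray(ratios)
    best = durations[int(np.nanargmax(ratios))]
    return {"durations": np.asarray(durations), "normalized_amplitude": ratios, "peak_duration": best}


def population_sum(receptor_sweeps: Sequence[SweepSet], offset_ms: Optional[float] = None) -> dict:
    """Sum of per-receptor averaged traces normalized to the first
    poststimulus oscillation amplitude of each receptor."""
    if len(receptor_sweeps) < 2:
        raise ValueError("need at least 2 receptors")
    total = None
    used = 0
    for i, ss in enumerate(receptor_sweeps):
        avg = ss.average()
        try:
            meas = measure_on_average(ss, offset_ms=offset_ms)
            amp = meas["amplitude"]
        except ValueError:
            amp = np.nan
        if not np.isfinite(amp) or amp == 0.0:
            warnings.warn(f"receptor {i}: zero/unmeasurable normalization amplitude, excluded", stacklevel=2)
            continue
        norm = avg / amp
        total = norm if total is None else total + norm
        used += 1
    if total is None:
        raise ValueError("no receptor had a measurable normalization amplitude")
    return {"sum": total, "n_receptors": used, "sample_rate": receptor_sweeps[0].sample_rate}


def _spike_peaks(trace: np.ndarray, sample_rate: float, threshold: float) -> np.ndarray:
    """Times of peaks whose voltage crosses the threshold, sub-sample refined."""
    from scipy import signal as _sig

    pk, _ = _sig.find_peaks(trace, height=threshold)
    times = []
    for i in pk:
        if 0 < i < trace.size - 1:
            y0, y1, y2 = trace[i - 1], trace[i], trace[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            times.append((i + float(np.clip(delta, -0.5, 0.5))) / sample_rate)
        else:
            times.append(i / sample_rate)
    return np.asarray(times)


def _response_edge(sweeps: SweepSet) -> float:
    """Polarity-appropriate stimulus edge: onset for positive, offset for negative."""
    spec = sweeps.stimulus
    if spec is not None and spec.polarity < 0:
        if spec.kind in ("square_pulse", "pulse_pair"):
            fs = spec.sample_rate
            return sweeps.t_stim_on + np.floor(spec.duration * fs) / fs
        return sweeps.t_stim_off
    return sweeps.t_stim_on


def measure_spike_response(
    sweeps: SweepSet, threshold: float, window: float = 5.0
) -> dict:
    """Threshold-crossing spike detection per sweep.

    probability = fraction of sweeps with >= 1 spike between the
    polarity-appropriate stimulus edge and edge + ``window`` ms; latency is
    the mean first-spike time relative to that edge.
    """
    pre_end = max(int(sweeps.t_stim_on * sweeps.sample_rate) - 1, 1)
    floor = noise_floor_estimate(sweeps.sweeps[:, :pre_end].ravel())
    if threshold <= floor:
        raise ValueError(f"threshold {threshold} mV is below the noise floor ({floor:.3g} mV)")
    edge = _response_edge(sweeps)
    spike_times, latencies, responded = [], [], 0
    for row in sweeps.sweeps:
        t_sp = _spike_peaks(row, sweeps.sample_rate, threshold)
        spike_times.append(t_sp)
        in_win = t_sp[(t_sp >= edge) & (t_sp <= edge + window)]
        if in_win.size:
            responded += 1
            latencies.append(in_win[0] - edge)
    probability = responded / sweeps.n_sweeps
    latency = float(np.mean(latencies)) if latencies else np.nan
    return {
        "spike_times": spike_times,
        "probability": float(probability),
        "mean_first_spike_latency": latency,
        "edge": float(edge),
        "no_response": responded == 0,
    }


def spike_timing_difference(pos: SweepSet, neg: SweepSet, threshold: float, window: float = 5.0) -> float:
    """Mean first-spike time after the negative-pulse offset minus mean
    first-spike time after the positive-pulse onset (averaging precedes
    differencing). Equals the pulse duration for edge-locked receptors."""
    if pos.stimulus is not None and neg.stimulus is not None:
        if pos.stimulus.polarity == neg.stimulus.polarity:
            raise ValueError("sweep sets must have opposite polarities")
    rp = measure_spike_response(pos, threshold, window=window)
    rn = measure_spike_response(neg, threshold, window=window)
    if rp["no_response"] and rn["no_response"]:
        raise ValueError("no spikes detected in either sweep set")
    t_pos = rp["edge"] + rp["mean_first_spike_latency"]
    t_neg = rn["edge"] + rn["mean_first_spike_latency"]
    return float(t_neg - t_pos)


def pair_interspike_interval(
    sweeps: SweepSet, threshold: float, window: float = 2.0
) -> dict:
    """Paired-pulse spiking: probability of firing to both pulses, and the
    interval between the two edge-locked spikes when both are present."""
    spec = sweeps.stimulus
    if spec is None or spec.kind != "pulse_pair":
        raise ValueError("requires a pulse_pair stimulus")
    fs = spec.sample_rate
    d_eff = np.floor(spec.duration * fs) / fs
    if spec.polarity > 0:
        edges = [sweeps.t_stim_on, sweeps.t_stim_on + round(spec.ipi * fs) / fs]
    else:
        edges = [sweeps.t_stim_on + d_eff, sweeps.t_stim_on + round(spec.ipi * fs) / fs + d_eff]
    both, intervals = 0, []
    p_first = p_second = 0
    for row in sweeps.sweeps:
        t_sp = _spike_peaks(row, sweeps.sample_rate, threshold)
        w1 = t_sp[(t_sp >= edges[0]) & (t_sp < min(edges[0] + window, edges[1]))]
        w2 = t_sp[(t_sp >= edges[1]) & (t_sp <= edges[1] + window)]
        p_first += w1.size > 0
        p_second += w2.size > 0
        if w1.size and w2.size:
            both += 1
            intervals.append(w2[0] - w1[0])
    n = sweeps.n_sweeps
    return {
        "first_pulse_probability": p_first / n,
        "second_pulse_probability": p_second / n,
        "both_pulse_probability": both / n,
        "mean_interval": float(np.mean(intervals)) if intervals else np.nan,
    }
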