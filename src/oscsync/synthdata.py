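"""Synthetic stimuli, receptor simulations, EOD trains, and behavioral sessions.

Conventions: times in ms, sampling rates in kHz, voltages in mV, stimulus
intensities in nA. Stimuli default to a 195.31-kHz grid, recordings to
97.7 kHz. All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "StimulusSpec",
    "ReceptorParams",
    "SweepSet",
    "EventTrain",
    "make_pulse_stimulus",
    "make_bipolar_sine",
    "synth_eod",
    "make_eod_train",
    "simulate_oscillating_receptor",
    "simulate_spiking_receptor",
    "generate_eod_population_train",
    "simulate_behavioral_session",
    "add_artifact",
]

STIM_RATE_KHZ = 195.31
REC_RATE_KHZ = 97.7


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StimulusSpec:
    kind: str  # square_pulse | pulse_pair | bipolar_sine | eod | eod_train
    duration: float  # ms (per pulse for pulse kinds; full cycle for bipolar_sine)
    polarity: int = 1
    intensity: float = 1.0  # nA
    ipi: Optional[float] = None  # ms, onset-to-onset (pairs/trains)
    n_pulses: int = 1
    sample_rate: float = STIM_RATE_KHZ  # kHz

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.kind in ("pulse_pair", "eod_train") and (self.ipi is None or self.ipi <= 0):
            raise ValueError(f"{self.kind} requires ipi > 0")

    @property
    def span(self) -> float:
        """Total extent of the stimulus in ms (onset of first to end of last)."""
        if self.kind == "pulse_pair":
            return self.ipi + self.duration
        if self.kind == "eod_train":
            return (self.n_pulses - 1) * self.ipi + self.duration
        return self.duration


@dataclass(frozen=True)
class ReceptorParams:
    """Generative parameters of a simulated receptor.

    Oscillating receptors are forced Stuart-Landau oscillators; spiking
    receptors fire in response to inward current transients (positive-going
    stimulus edges) with latency, jitter, and refractoriness.
    """

    mode: str  # oscillating | spiking
    f0: float = 2.0  # kHz; intrinsic oscillation / resonance frequency
    mu: float = 2.0  # 1/ms limit-cycle growth rate
    kappa: float = 1.0  # coupling gain (z units per nA of edge step)
    noise_sd: float = 0.05  # intrinsic noise, z units per sqrt(ms)
    spont_amp: float = 1.0  # mV peak-to-trough spontaneous amplitude
    meas_noise_sd: float = 0.02  # mV measurement noise on the trace
    latency: float = 0.3  # ms (spiking)
    refractory: float = 1.0  # ms (spiking)
    threshold_charge: float = 1.0  # nA*ms (spiking)
    jitter_sd: float = 0.0  # ms (spiking)
    spont_rate: float = 0.0  # events/s (spiking)
    spike_amp: float = 2.0  # mV template amplitude (cosmetic)

    def __post_init__(self) -> None:
        if self.mode not in ("oscillating", "spiking"):
            raise ValueError("mode must be 'oscillating' or 'spiking'")
        if self.mode == "oscillating" and not (0.5 < self.f0 <= 3.5):
            raise ValueError("oscillating f0 must be in (0.5, 3.5] kHz")
        if self.mode == "oscillating" and self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.mode == "spiking" and self.refractory <= 0:
            raise ValueError("spiking refractory must be > 0")
        if self.noise_sd < 0 or self.jitter_sd < 0 or self.meas_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SweepSet:
    """Repeated stimulus-aligned trace segments plus the evoking stimulus."""

    sweeps: np.ndarray  # (n_sweeps, n_samples) mV
    sample_rate: float  # kHz
    stimulus: Optional[StimulusSpec]
    t_stim_on: float  # ms within sweep
    t_stim_off: float  # ms within sweep
    seed: int = 0
    events: Optional[list] = None  # per-sweep arrays of exact event times (ms)
    stim_trace: Optional[np.ndarray] = None  # stimulus on the recording grid (nA)

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.t_stim_off < self.t_stim_on:
            raise ValueError("t_stim_off must be >= t_stim_on")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) / self.sample_rate

    def average(self) -> np.ndarray:
        return self.sweeps.mean(axis=0)


@dataclass(frozen=True)
class EventTrain:
    """Ordered event times (spikes or EODs) in ms."""

    times: np.ndarray
    duration: float  # ms
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("event times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("event times must lie within [0, duration]")
        object.__setattr__(self, "times", t)

    @property
    def n_events(self) -> int:
        return int(self.times.size)


# ---------------------------------------------------------------------------
# stimulus construction


def make_pulse_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Sample a monopolar square pulse or pulse pair.

    A pulse of duration d occupies floor(d * fs) nonzero samples starting at
    index 0; for a pair the second onset sits round(ipi * fs) samples after
    the first (onset-to-onset).
    """
    if spec.kind not in ("square_pulse", "pulse_pair"):
        raise ValueError("make_pulse_stimulus handles square_pulse / pulse_pair")
    fs = spec.sample_rate
    n_pulse = int(np.floor(spec.duration * fs))
    if n_pulse < 1:
        raise ValueError("pulse shorter than one sample at this rate")
    amp = spec.polarity * spec.intensity
    if spec.kind == "square_pulse":
        out = np.zeros(n_pulse + 1)
        out[:n_pulse] = amp
        return out
    i2 = int(round(spec.ipi * fs))
    out = np.zeros(i2 + n_pulse + 1)
    out[:n_pulse] = amp
    out[i2 : i2 + n_pulse] += amp
    return out


def make_bipolar_sine(
    frequency: Optional[float] = None,
    duration: Optional[float] = None,
    polarity: int = 1,
    intensity: float = 1.0,
    sample_rate: float = STIM_RATE_KHZ,
    pad_ms: float = 0.0,
) -> np.ndarray:
    """One full cycle of a bipolar sine; positive polarity = peak leading trough.

    Exactly one of ``frequency`` (kHz) or ``duration`` (ms) must be given;
    they are reciprocal. The trace is zero outside the cycle.
    """
    if (frequency is None) == (duration is None):
        raise ValueError("give exactly one of frequency or duration")
    if duration is None:
        duration = 1.0 / frequency
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n_pad = int(round(pad_ms * sample_rate))
    n_cyc = int(np.floor(duration * sample_rate))
    t = np.arange(n_cyc) / sample_rate
    cycle = polarity * intensity * np.sin(2 * np.pi * t / duration)
    return np.concatenate([np.zeros(n_pad), cycle, np.zeros(n_pad + 1)])


def _eod_candidate(f_c: float, length: float, sample_rate: float) -> np.ndarray:
    from scipy.signal import windows

    n = max(int(length * sample_rate), 8)
    t = np.arange(n) / sample_rate
    core = np.sin(2 * np.pi * f_c * t) * windows.hann(n)
    pad = np.zeros(n)
    return np.concatenate([pad, core, pad])


def synth_eod(duration: float, peak_freq: float, sample_rate: float = STIM_RATE_KHZ) -> np.ndarray:
    """Synthesize a biphasic EOD-like waveform.

    A Hann-windowed sine burst, iteratively calibrated so the Welch spectral
    peak is within 10% of ``peak_freq`` (kHz) and the 0.5% peak-to-peak
    total duration is within 10% of ``duration`` (ms). Combinations below
    half a cycle (peak_freq * duration < 0.5) are rejected; products near
    the bound calibrate best-effort (a single cycle, product ~1, is the
    practical floor of the spectral peak for a zero-mean burst).
    """
    from . import tuning  # late import: tuning does not import synthdata

    if duration <= 0 or peak_freq <= 0:
        raise ValueError("duration and peak_freq must be > 0")
    if peak_freq * duration < 0.5:
        raise ValueError("unattainable: peak_freq * duration < 0.5 (less than half a cycle)")
    f_c = peak_freq
    length = duration / 0.88  # 0.5% crossings sit just inside the Hann window
    wave = _eod_candidate(f_c, length, sample_rate)
    for _ in range(12):
        meas = tuning.eod_spectrum_duration(wave, sample_rate)
        err_f = meas["peak_power_freq"] / peak_freq
        err_d = meas["total_duration"] / duration
        if abs(err_f - 1.0) < 0.03 and abs(err_d - 1.0) < 0.03:
            break
        f_c *= err_f**-0.7  # damped fixed-point updates
        length *= err_d**-0.7
        wave = _eod_candidate(f_c, length, sample_rate)
    return wave


def make_eod_train(
    eod: np.ndarray, ipi: float, n_pulses: int, sample_rate: float = STIM_RATE_KHZ
) -> np.ndarray:
    """Concatenate identical EODs at a fixed onset-to-onset IPI.

    The EOD's start/end are located by the 0.5% peak-to-peak criterion and
    the waveform trimmed to that support; zero padding fills the gaps. If
    the EOD outlasts the IPI, every copy is truncated at the IPI.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    if ipi <= 0:
        raise ValueError("ipi must be > 0")
    eod = np.asarray(eod, dtype=float)
    thresh = 0.005 * (eod.max() - eod.min())
    above = np.nonzero(np.abs(eod) > thresh)[0]
    if above.size == 0:
        raise ValueError("EOD waveform is all below the 0.5% criterion")
    seg = eod[above[0] : above[-1] + 1]
    n_ipi = int(round(ipi * sample_rate))
    if seg.size > n_ipi:
        seg = seg[:n_ipi]
    out = np.zeros((n_pulses - 1) * n_ipi + seg.size)
    for k in range(n_pulses):
        out[k * n_ipi : k * n_ipi + seg.size] += seg
    return out


def _resolve_stimulus(stimulus, pre_ms, post_ms, fs_rec):
    """Build the recording-grid stimulus array and sweep geometry.

    Returns (spec_or_None, s_rec, n_samples, t_on, t_off).
    """
    if stimulus is None:
        n = int(round((pre_ms + post_ms) * fs_rec))
        return None, np.zeros(n), n, pre_ms, pre_ms
    if isinstance(stimulus, StimulusSpec):
        spec = stimulus
        if spec.kind in ("square_pulse", "pulse_pair"):
            trace = make_pulse_stimulus(spec)
        elif spec.kind == "bipolar_sine":
            trace = make_bipolar_sine(
                duration=spec.duration,
                polarity=spec.polarity,
                intensity=spec.intensity,
                sample_rate=spec.sample_rate,
            )
        else:
            raise ValueError(f"cannot materialize stimulus kind {spec.kind!r}")
        fs_stim = spec.sample_rate
        span = spec.span
    else:
        spec = None
        trace, fs_stim = stimulus
        trace = np.asarray(trace, dtype=float)
        span = trace.size / fs_stim
    n = int(round((pre_ms + span + post_ms) * fs_rec))
    t_rec = np.arange(n) / fs_rec
    t_stim = np.arange(trace.size) / fs_stim + pre_ms
    s_rec = np.interp(t_rec, t_stim, trace, left=0.0, right=0.0)
    return spec, s_rec, n, pre_ms, pre_ms + span


# ---------------------------------------------------------------------------
# receptor simulators


def simulate_oscillating_receptor(
    params: ReceptorParams,
    stimulus=None,
    n_sweeps: int = 1,
    seed: int = 0,
    pre_ms: float = 5.0,
    post_ms: float = 10.0,
    artifact_gains: Optional[tuple] = None,
    sample_rate: float = REC_RATE_KHZ,
) -> SweepSet:
    """Integrate a stochastically perturbed, transient-forced Stuart-Landau oscillator.

    dz = [(mu + i 2 pi f0) z - |z|^2 z] dt + kappa ds + noise dW

    The forcing couples to stimulus *transients* (ds: steps of the stimulus
    current), so a square pulse delivers one kick at each edge; opposite
    polarity flips the kick sign, producing ~180-degree-opposed resets.
    Amplitude is rotated exactly per step (exponential integrator), so the
    deterministic oscillation frequency is exactly f0. Recorded potential is
    Re(z) scaled so the spontaneous peak-to-trough amplitude is spont_amp,
    plus measurement noise and an optional residual artifact.
    """
    if params.mode != "oscillating":
        raise ValueError("params.mode must be 'oscillating'")
    if params.f0 <= 0:
        raise ValueError("f0 must be positive")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    fs = sample_rate
    dt = 1.0 / fs
    spec, s_rec, n, t_on, t_off = _resolve_stimulus(stimulus, pre_ms, post_ms, fs)
    kicks = np.diff(s_rec, prepend=0.0)  # nA steps between samples

    R = np.sqrt(params.mu)
    theta0 = rng.uniform(0.0, 2 * np.pi, size=n_sweeps)
    z = R * np.exp(1j * theta0)
    rot = np.exp(1j * 2 * np.pi * params.f0 * dt)
    sd = params.noise_sd * np.sqrt(dt)
    noise = (rng.standard_normal((n, n_sweeps)) + 1j * rng.standard_normal((n, n_sweeps))) * sd

    re = np.empty((n, n_sweeps))
    mu, kap = params.mu, params.kappa
    for k in range(n):
        z = z * (rot * np.exp((mu - np.abs(z) ** 2) * dt)) + kap * kicks[k] + noise[k]
        re[k] = z.real

    scale = params.spont_amp / (2.0 * R)
    sweeps = scale * re.T
    if params.meas_noise_sd > 0:
        sweeps = sweeps + rng.normal(0.0, params.meas_noise_sd, size=sweeps.shape)
    if artifact_gains is not None:
        rg, cg = artifact_gains
        sweeps = np.array([add_artifact(s, s_rec, rg, cg, sample_rate=fs) for s in sweeps])
    return SweepSet(
        sweeps=sweeps,
        sample_rate=fs,
        stimulus=spec,
        t_stim_on=t_on,
        t_stim_off=t_off,
        seed=seed,
        stim_trace=s_rec,
    )


def _spike_template(params: ReceptorParams, dt_rel: np.ndarray) -> np.ndarray:
    # smooth biphasic-looking ~0.5 ms shape, maximum exactly at dt_rel = 0
    s = 0.1  # ms
    x = dt_rel / s
    return params.spike_amp * (1.0 - x**2) * np.exp(-(x**2) / 2.0)


def _square_pulse_edges(spec: StimulusSpec, t_on: float) -> list:
    """Exact times (ms) of positive-going stimulus edges: onset of a
    positive pulse, offset of a negative pulse (the inward transients)."""
    fs = spec.sample_rate
    d_eff = np.floor(spec.duration * fs) / fs
    onsets = [t_on]
    if spec.kind == "pulse_pair":
        onsets.append(t_on + round(spec.ipi * fs) / fs)
    if spec.polarity > 0:
        return [(t, spec.intensity) for t in onsets]
    return [(t + d_eff, spec.intensity) for t in onsets]


def _drive_transients(s_rec: np.ndarray, fs: float, f0: float, tau_int: float) -> list:
    """Qualifying transients of an arbitrary stimulus: positive peaks of the
    resonator-filtered drive. Returns (time, equivalent charge) pairs."""
    from scipy import signal

    nyq = fs / 2.0
    lo, hi = f0 / np.sqrt(2.0), min(f0 * np.sqrt(2.0), 0.95 * nyq)
    sos = signal.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    drive = signal.sosfilt(sos, s_rec)
    peaks, props = signal.find_peaks(drive, height=1e-9)
    return [(p / fs, props["peak_heights"][i] * tau_int) for i, p in enumerate(peaks)]


def simulate_spiking_receptor(
    params: ReceptorParams,
    stimulus=None,
    n_sweeps: int = 1,
    seed: int = 0,
    pre_ms: float = 5.0,
    post_ms: float = 10.0,
    tau_int: float = 0.2,
    artifact_gains: Optional[tuple] = None,
) -> SweepSet:
    """Simulate a spiking receptor responding to inward current transients.

    A spike is emitted at transient + latency + Gaussian jitter with
    probability sigmoid in the transient charge; spikes within the
    refractory window of a previous spike are suppressed. Square pulses use
    exact edge times (onset for positive, offset for negative polarity);
    other stimuli go through a resonator filter centered on f0, giving
    bandpass frequency sensitivity. Spontaneous spikes arise from a renewal
    process at spont_rate.
    """
    if params.mode != "spiking":
        raise ValueError("params.mode must be 'spiking'")
    if params.refractory <= 0:
        raise ValueError("refractory must be > 0")
    rng = np.random.default_rng(seed)
    fs = REC_RATE_KHZ
    spec, s_rec, n, t_on, t_off = _resolve_stimulus(stimulus, pre_ms, post_ms, fs)
    total_ms = n / fs

    if spec is not None and spec.kind in ("square_pulse", "pulse_pair"):
        transients = [(t, spec.intensity * min(spec.duration, tau_int)) for t, _ in _square_pulse_edges(spec, t_on)]
    elif np.any(s_rec != 0.0):
        transients = _drive_transients(s_rec, fs, params.f0, tau_int)
    else:
        transients = []

    sweeps = rng.normal(0.0, max(params.meas_noise_sd, 1e-12), size=(n_sweeps, n))
    t_grid = np.arange(n) / fs
    events = []
    slope = params.threshold_charge / 16.0
    for i in range(n_sweeps):
        cand = []
        # spontaneous renewal: exponential intervals with a refractory floor
        if params.spont_rate > 0:
            t = 0.0
            mean_gap = 1000.0 / params.spont_rate  # ms
            while True:
                t += params.refractory + rng.exponential(max(mean_gap - params.refractory, 1e-6))
                if t >= total_ms:
                    break
                cand.append(t)
        for t_edge, q in transients:
            p = expit((q - params.threshold_charge) / slope)
            if rng.random() < p:
                t_sp = t_edge + params.latency
                if params.jitter_sd > 0:
                    t_sp += rng.normal(0.0, params.jitter_sd)
                if 0.0 <= t_sp < total_ms:
                    cand.append(t_sp)
        cand.sort()
        kept = []
        for t_sp in cand:
            if not kept or t_sp - kept[-1] >= params.refractory:
                kept.append(t_sp)
        ev = np.asarray(kept)
        events.append(ev)
        for t_sp in ev:
            lo = max(int((t_sp - 0.4) * fs), 0)
            hi = min(int((t_sp + 0.4) * fs) + 1, n)
            sweeps[i, lo:hi] += _spike_template(params, t_grid[lo:hi] - t_sp)
    if artifact_gains is not None:
        rg, cg = artifact_gains
        sweeps = np.array([add_artifact(s, s_rec, rg, cg, sample_rate=fs) for s in sweeps])
    return SweepSet(
        sweeps=sweeps,
        sample_rate=fs,
        stimulus=spec,
        t_stim_on=t_on,
        t_stim_off=t_off,
        seed=seed,
        events=events,
        stim_trace=s_rec,
    )


# ---------------------------------------------------------------------------
# EOD trains and behavior


def generate_eod_population_train(
    n_fish: int,
    duration: float,
    min_ipi: float = 8.0,
    mean_ipi: float = 120.0,
    gamma_shape: float = 2.0,
    seed: int = 0,
) -> dict:
    """Independent shifted-gamma renewal EOD trains for each fish, plus the
    pooled (sorted merge) train. All IPIs within a fish are >= min_ipi;
    pooled trains of many fish can contain arbitrarily short IPIs."""
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    if min_ipi <= 0:
        raise ValueError("min_ipi must be > 0")
    if mean_ipi <= min_ipi:
        raise ValueError("mean_ipi must exceed min_ipi")
    rng = np.random.default_rng(seed)
    scale = (mean_ipi - min_ipi) / gamma_shape
    per_fish = []
    for i in range(n_fish):
        times = []
        t = rng.uniform(0.0, mean_ipi)
        while t < duration:
            times.append(t)
            t += min_ipi + rng.gamma(gamma_shape, scale)
        per_fish.append(EventTrain(np.asarray(times), duration, label=f"fish{i}"))
    pooled_times = np.sort(np.concatenate([tr.times for tr in per_fish])) if per_fish else np.array([])
    # break exact ties (probability ~0) to keep strict monotonicity
    if pooled_times.size > 1:
        eq = np.diff(pooled_times) <= 0
        while np.any(eq):
            pooled_times[1:][eq] += 1e-9
            pooled_times.sort()
            eq = np.diff(pooled_times) <= 0
    pooled = EventTrain(pooled_times, duration, label="pooled")
    return {"per_fish": per_fish, "pooled": pooled}


def _alpha_kernel(t: np.ndarray, tau: float) -> np.ndarray:
    out = np.zeros_like(t)
    m = t > 0
    out[m] = (t[m] / tau) * np.exp(1.0 - t[m] / tau)
    return out


def simulate_behavioral_session(
    baseline_rate: float,
    inc_amp: float,
    dec_amp: float,
    stimulus_times: Sequence[float],
    duration: float,
    tau_inc: float = 300.0,
    tau_dec: float = 1000.0,
    delay_dec: float = 0.0,
    kernel: str = "alpha",
    seed: int = 0,
) -> EventTrain:
    """EOD times from an inhomogeneous renewal (thinned Poisson) process.

    rate(t) [events/s] = baseline + inc_amp * K+(t - ts) - dec_amp * K-(t - ts)
    summed over stimulus times ts, with unit-peak kernels (time constants in
    ms) and the rate floored at zero. ``kernel`` selects alpha-function
    ("alpha") or rectangular ("boxcar", width tau) response kernels.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if kernel not in ("alpha", "boxcar"):
        raise ValueError("kernel must be 'alpha' or 'boxcar'")
    rng = np.random.default_rng(seed)
    stimulus_times = np.asarray(stimulus_times, dtype=float)

    def _k(t: np.ndarray, tau: float) -> np.ndarray:
        if kernel == "boxcar":
            return ((t >= 0) & (t <= tau)).astype(float)
        return _alpha_kernel(t, tau)

    def rate(t: np.ndarray) -> np.ndarray:
        lam = np.full_like(t, baseline_rate, dtype=float)
        for ts in stimulus_times:
            lam += inc_amp * _k(t - ts, tau_inc)
            lam -= dec_amp * _k(t - ts - delay_dec, tau_dec)
        return np.maximum(lam, 0.0)

    lam_max = float(rate(np.arange(0.0, duration, 1.0)).max()) * 1.05 + 1e-9
    n_exp = int(lam_max / 1000.0 * duration * 1.5 + 50)
    t, times = 0.0, []
    gaps = rng.exponential(1000.0 / lam_max, size=n_exp)
    accept = rng.uniform(size=n_exp)
    i = 0
    while True:
        if i >= gaps.size:  # top up, rare
            gaps = np.concatenate([gaps, rng.exponential(1000.0 / lam_max, size=n_exp)])
            accept = np.concatenate([accept, rng.uniform(size=n_exp)])
        t += gaps[i]
        if t >= duration:
            break
        if accept[i] * lam_max < rate(np.array([t]))[0]:
            times.append(t)
        i += 1
    return EventTrain(np.asarray(times), duration, label="behavior")


def add_artifact(
    trace: np.ndarray,
    stimulus: np.ndarray,
    resistive_gain: float,
    capacitive_gain: float,
    sample_rate: float = REC_RATE_KHZ,
) -> np.ndarray:
    """Add a residual stimulus artifact: resistive + capacitive coupling.

    out = trace + resistive_gain * s(t) + capacitive_gain * ds/dt
    """
    trace = np.asarray(trace, dtype=float)
    stimulus = np.asarray(stimulus, dtype=float)
    if trace.shape != stimulus.shape:
        raise ValueError("trace and stimulus must be time-aligned (equal length)")
    ds = np.gradient(stimulus) * sample_rate
    return trace + resistive_gain * stimulus + capacitive_gain * ds
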