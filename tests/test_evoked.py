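import numpy as np
import pytest

from conftest import trace_from_peak_times
from oscsync.evoked import (
    PolarityPairMeasurement,
    delta_phase,
    duration_series_amplitude,
    interoscillation_interval,
    measure_poststimulus_oscillation,
    measure_spike_response,
    oscillation_timing_difference,
    pair_interspike_interval,
    paired_pulse_normalized_amplitude,
    polarity_pair_measurement,
    population_sum,
    spike_timing_difference,
)
from oscsync.synthdata import ReceptorParams, StimulusSpec, SweepSet, simulate_oscillating_receptor, simulate_spiking_receptor

FS = 97.7


def sweepset_from_trace(trace, t_on=5.0, t_off=5.2, stimulus=None, n_copies=1):
    return SweepSet(
        sweeps=np.tile(trace, (n_copies, 1)),
        sample_rate=FS,
        stimulus=stimulus,
        t_stim_on=t_on,
        t_stim_off=t_off,
    )


def make_osc_sweepset(peak_times, t_off=5.0, t_end=None, amp=1.0):
    _, trace = trace_from_peak_times(peak_times, fs=FS, amp=amp, t_end=t_end)
    return sweepset_from_trace(trace, t_on=t_off - 0.2, t_off=t_off)


class TestArtifactRule:
    def test_regular_periods_use_first_peak(self):
        peaks = 5.1 + 0.5 * np.arange(9)
        ss = make_osc_sweepset(peaks)
        res = measure_poststimulus_oscillation(ss)
        m = res["per_sweep"][0]
        assert not m.used_second_peak
        assert m.lat == pytest.approx(0.1, abs=0.01)
        assert m.p == pytest.approx(0.5, abs=0.01)

    def test_first_period_80pct_uses_second_peak(self):
        # first period 0.40 = 0.80 x the 0.50 average of the next five
        peaks = np.array([5.1, 5.5]) .tolist() + list(5.5 + 0.5 * np.arange(1, 8))
        ss = make_osc_sweepset(np.array(peaks))
        res = measure_poststimulus_oscillation(ss)
        m = res["per_sweep"][0]
        assert m.used_second_peak
        assert m.lat == pytest.approx(0.5, abs=0.01)

    def test_boundary_equal_average_uses_first_peak(self):
        peaks = 5.2 + 0.5 * np.arange(9)  # all periods identical
        res = measure_poststimulus_oscillation(make_osc_sweepset(peaks))
        assert not res["per_sweep"][0].used_second_peak

    def test_long_first_period_uses_second_peak(self):
        peaks = [5.1, 5.7] + list(5.7 + 0.5 * np.arange(1, 8))  # first period 0.6 > 115%
        res = measure_poststimulus_oscillation(make_osc_sweepset(np.array(peaks)))
        assert res["per_sweep"][0].used_second_peak

    def test_never_triggers_on_iid_jittered_periods(self):
        # periods i.i.d. within +/-5% of 0.5 ms over 200 seeded sweeps
        rng = np.random.default_rng(99)
        triggered = 0
        for _ in range(200):
            periods = 0.5 * rng.uniform(0.95, 1.05, 10)
            peaks = 5.05 + np.concatenate([[0.0], np.cumsum(periods)])
            res = measure_poststimulus_oscillation(make_osc_sweepset(peaks))
            triggered += res["per_sweep"][0].used_second_peak
        assert triggered == 0


class TestPhaseGeometry:
    def test_sine_burst_quarter_period_phase(self):
        # amplitude-A sine burst starting exactly at stimulus offset
        t = np.arange(int(15.0 * FS)) / FS
        a = 0.8
        trace = np.where(t >= 5.0, a * np.sin(2 * np.pi * 2.0 * (t - 5.0)), 0.0)
        ss = sweepset_from_trace(trace, t_on=4.8, t_off=5.0)
        res = measure_poststimulus_oscillation(ss)
        m = res["per_sweep"][0]
        assert m.lat == pytest.approx(0.125, abs=0.01)
        assert m.phi == pytest.approx(np.pi / 2, abs=0.15)
        assert res["summary"].amplitude == pytest.approx(2 * a, rel=0.1)

    def test_phi_invariant_to_scaling(self):
        peaks = 5.12 + 0.5 * np.arange(9)
        m1 = measure_poststimulus_oscillation(make_osc_sweepset(peaks, amp=1.0))["per_sweep"][0]
        m2 = measure_poststimulus_oscillation(make_osc_sweepset(peaks, amp=5.0))["per_sweep"][0]
        assert m2.phi == pytest.approx(m1.phi, abs=1e-9)


class TestDeltaPhase:
    def test_half_period_gives_180(self):
        pm = PolarityPairMeasurement(lat_n=0.35, p_n=0.5, lat_p=0.10, p_p=0.5)
        assert delta_phase(pm)["delta_phi"] == pytest.approx(180.0)

    def test_equal_latencies_zero(self):
        pm = PolarityPairMeasurement(lat_n=0.2, p_n=0.5, lat_p=0.2, p_p=0.4)
        assert delta_phase(pm)["delta_phi"] == 0.0

    def test_mixed_periods_arithmetic(self):
        pm = PolarityPairMeasurement(lat_n=0.3, p_n=0.4, lat_p=0.2, p_p=0.6)
        assert delta_phase(pm)["raw"] == pytest.approx(0.1 / 0.5 * 360.0)
        assert delta_phase(pm)["delta_phi"] == pytest.approx(72.0)

    def test_antisymmetric_under_polarity_swap(self):
        pm = PolarityPairMeasurement(lat_n=0.31, p_n=0.52, lat_p=0.12, p_p=0.48)
        swapped = PolarityPairMeasurement(lat_n=0.12, p_n=0.48, lat_p=0.31, p_p=0.52)
        d1 = delta_phase(pm)["delta_phi"]
        d2 = delta_phase(swapped)["delta_phi"]
        assert (d1 + d2) % 360.0 == pytest.approx(0.0, abs=1e-9)


class TestOscillationTimingDifference:
    def test_identical_sweepsets_zero(self):
        peaks = 5.1 + 0.5 * np.arange(10)
        a = make_osc_sweepset(peaks)
        b = make_osc_sweepset(peaks)
        assert oscillation_timing_difference(a, b, 0.2) == pytest.approx(0.0, abs=1e-9)

    def test_short_pulse_half_period_not_duration(self, osc_params):
        pos = StimulusSpec(kind="square_pulse", duration=0.10, polarity=1, intensity=2.0)
        neg = StimulusSpec(kind="square_pulse", duration=0.10, polarity=-1, intensity=2.0)
        sp = simulate_oscillating_receptor(osc_params, pos, n_sweeps=10, seed=1)
        sn = simulate_oscillating_receptor(osc_params, neg, n_sweeps=10, seed=2)
        d = abs(oscillation_timing_difference(sp, sn, 0.10))
        d = min(d, abs(d - 0.5))  # modulo one intrinsic period
        assert d == pytest.approx(0.25, abs=0.06)
        assert abs(d - 0.10) > 0.05

    def test_long_pulse_onset_offset_convention(self, osc_params):
        pos = StimulusSpec(kind="square_pulse", duration=2.0, polarity=1, intensity=5.0)
        neg = StimulusSpec(kind="square_pulse", duration=2.0, polarity=-1, intensity=5.0)
        sp = simulate_oscillating_receptor(osc_params, pos, n_sweeps=10, seed=3)
        sn = simulate_oscillating_receptor(osc_params, neg, n_sweeps=10, seed=4)
        d = oscillation_timing_difference(sp, sn, 2.0)
        # hand-computed references: first peaks after pos onset / neg offset
        from oscsync.evoked import _first_peak_after

        t_pos = _first_peak_after(sp, sp.t_stim_on)
        t_neg = _first_peak_after(sn, sn.t_stim_off)
        assert d == pytest.approx(t_pos - t_neg, abs=1e-9)


class TestInteroscillationInterval:
    def test_time_shifted_response_exact(self):
        base_peaks = 5.2 + 0.5 * np.arange(12)
        single = make_osc_sweepset(base_peaks, t_off=5.0, t_end=30.0)
        pair_spec = StimulusSpec(kind="pulse_pair", duration=0.2, intensity=1.0, ipi=3.0)
        _, trace = trace_from_peak_times(base_peaks + 3.0, fs=FS, t_end=30.0)
        pair = SweepSet(sweeps=trace[None, :], sample_rate=FS, stimulus=pair_spec, t_stim_on=4.8, t_stim_off=8.0)
        iv = interoscillation_interval(single, pair, offset_single=5.0, offset_pair=8.0)
        assert iv == pytest.approx(3.0, abs=1.5 / FS)

    def test_simulated_ipi_3ms(self, osc_params):
        single = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=1.5)
        pair = StimulusSpec(kind="pulse_pair", duration=0.2, polarity=1, intensity=1.5, ipi=3.0)
        ssw = simulate_oscillating_receptor(osc_params, single, n_sweeps=10, seed=5, post_ms=12)
        psw = simulate_oscillating_receptor(osc_params, pair, n_sweeps=10, seed=6, post_ms=12)
        assert interoscillation_interval(ssw, psw) == pytest.approx(3.0, abs=0.05)

    def test_short_ipi_not_tracked(self, osc_params):
        single = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=1.5)
        pair = StimulusSpec(kind="pulse_pair", duration=0.2, polarity=1, intensity=1.5, ipi=0.3)
        ssw = simulate_oscillating_receptor(osc_params, single, n_sweeps=10, seed=7, post_ms=12)
        psw = simulate_oscillating_receptor(osc_params, pair, n_sweeps=10, seed=8, post_ms=12)
        assert abs(interoscillation_interval(ssw, psw) - 0.3) > 0.04

    def test_polarity_mismatch_raises(self, osc_params):
        s1 = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=1.0)
        s2 = StimulusSpec(kind="pulse_pair", duration=0.2, polarity=-1, intensity=1.0, ipi=3.0)
        a = simulate_oscillating_receptor(osc_params, s1, n_sweeps=2, seed=1)
        b = simulate_oscillating_receptor(osc_params, s2, n_sweeps=2, seed=2)
        with pytest.raises(ValueError, match="polarity"):
            interoscillation_interval(a, b)


class TestPairedPulseAmplitude:
    def test_identical_responses_ratio_one(self):
        peaks = 8.4 + 0.5 * np.arange(10)
        pair_spec = StimulusSpec(kind="pulse_pair", duration=0.2, intensity=1.0, ipi=3.0)
        _, trace = trace_from_peak_times(peaks, fs=FS, t_end=25.0)
        pair = SweepSet(sweeps=trace[None, :], sample_rate=FS, stimulus=pair_spec, t_stim_on=5.0, t_stim_off=8.2)
        single_spec = StimulusSpec(kind="square_pulse", duration=0.2, intensity=1.0)
        single = SweepSet(sweeps=trace[None, :], sample_rate=FS, stimulus=single_spec, t_stim_on=5.0, t_stim_off=8.2)
        # same trace measured after the same offset in both
        assert paired_pulse_normalized_amplitude(pair, single) == pytest.approx(1.0, abs=1e-9)

    def test_scaling_invariance(self):
        peaks = 8.4 + 0.5 * np.arange(10)
        pair_spec = StimulusSpec(kind="pulse_pair", duration=0.2, intensity=1.0, ipi=3.0)
        _, trace = trace_from_peak_times(peaks, fs=FS, t_end=25.0)
        single_spec = StimulusSpec(kind="square_pulse", duration=0.2, intensity=1.0)
        single = SweepSet(sweeps=trace[None, :], sample_rate=FS, stimulus=single_spec, t_stim_on=5.0, t_stim_off=8.2)
        r1 = paired_pulse_normalized_amplitude(
            SweepSet(sweeps=2 * trace[None, :], sample_rate=FS, stimulus=pair_spec, t_stim_on=5.0, t_stim_off=8.2),
            single,
        )
        r2 = paired_pulse_normalized_amplitude(
            SweepSet(sweeps=4 * trace[None, :], sample_rate=FS, stimulus=pair_spec, t_stim_on=5.0, t_stim_off=8.2),
            SweepSet(sweeps=2 * trace[None, :], sample_rate=FS, stimulus=single_spec, t_stim_on=5.0, t_stim_off=8.2),
        )
        assert r1 == pytest.approx(2.0, rel=0.01)
        assert r2 == pytest.approx(r1, rel=0.01)

    def test_resonant_ipi_beats_off_resonance(self):
        params = ReceptorParams(mode="oscillating", f0=2.0, mu=0.05, kappa=0.5, noise_sd=0.03, spont_amp=1.0)
        single = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=0.8)
        ssw = simulate_oscillating_receptor(params, single, n_sweeps=25, seed=1, post_ms=12)
        ratios = {}
        for mult in (1, 4):
            pair = StimulusSpec(kind="pulse_pair", duration=0.2, polarity=1, intensity=0.8, ipi=mult * 0.5)
            psw = simulate_oscillating_receptor(params, pair, n_sweeps=25, seed=1001, post_ms=12)
            ratios[mult] = paired_pulse_normalized_amplitude(psw, ssw)
        assert ratios[1] > ratios[4]


class TestDurationSeries:
    def test_stimulus_free_ratio_one(self, osc_params):
        ss = {
            d: simulate_oscillating_receptor(
                osc_params,
                StimulusSpec(kind="square_pulse", duration=d, intensity=0.0),
                n_sweeps=10,
                seed=int(d * 10),
            )
            for d in (0.1, 0.5)
        }
        out = duration_series_amplitude(ss)
        assert np.all(np.abs(out["normalized_amplitude"] - 1.0) < 0.35)

    def test_driven_ratio_elevated(self, osc_params):
        ss = {
            d: simulate_oscillating_receptor(
                osc_params,
                StimulusSpec(kind="square_pulse", duration=d, intensity=5.0),
                n_sweeps=10,
                seed=int(d * 10),
            )
            for d in (0.1, 0.25)
        }
        out = duration_series_amplitude(ss)
        assert np.all(out["normalized_amplitude"] > 1.3)


class TestPopulationSum:
    def test_identical_receptors_sum(self):
        peaks = 5.3 + 0.5 * np.arange(10)
        ss = make_osc_sweepset(peaks, t_end=12.0)
        out = population_sum([ss] * 36)
        single = measure_poststimulus_oscillation(ss)
        amp = single["summary"].amplitude
        assert np.allclose(out["sum"], 36 * ss.average() / amp, atol=1e-9)

    def test_spread_f0_transient_synchrony(self):
        stim = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=2.0)
        sets = []
        for i, f0 in enumerate(np.linspace(1.5, 2.0, 12)):
            p = ReceptorParams(mode="oscillating", f0=float(f0), mu=0.25, kappa=0.5, noise_sd=0.1, spont_amp=1.0)
            sets.append(simulate_oscillating_receptor(p, stim, n_sweeps=5, seed=50 + i, post_ms=10.0))
        out = population_sum(sets)
        from scipy.signal import hilbert

        env = np.abs(hilbert(out["sum"] - np.mean(out["sum"])))
        fs = out["sample_rate"]
        t_off = sets[0].t_stim_off
        t_peak = np.argmax(env) / fs
        assert t_off - 0.1 <= t_peak <= t_off + 1.0  # largest peak at first poststimulus oscillation
        pre = env[int(0.5 * fs) : int((sets[0].t_stim_on - 0.5) * fs)].max()
        assert env.max() / pre > 3.0

    def test_too_few_receptors_raises(self):
        peaks = 5.3 + 0.5 * np.arange(10)
        with pytest.raises(ValueError):
            population_sum([make_osc_sweepset(peaks)])


class TestSpikeResponse:
    def test_probability_one_and_latency(self, spiking_params):
        stim = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=10.0)
        sw = simulate_spiking_receptor(spiking_params, stim, n_sweeps=10, seed=1)
        out = measure_spike_response(sw, threshold=0.6)
        assert out["probability"] == 1.0
        assert out["mean_first_spike_latency"] == pytest.approx(0.3, abs=1.0 / FS)

    def test_no_crossings_flagged(self, spiking_params):
        stim = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=0.0)
        sw = simulate_spiking_receptor(spiking_params, stim, n_sweeps=5, seed=2)
        out = measure_spike_response(sw, threshold=0.6)
        assert out["probability"] == 0.0
        assert out["no_response"]
        assert np.isnan(out["mean_first_spike_latency"])

    def test_threshold_below_noise_floor_raises(self, spiking_params):
        stim = StimulusSpec(kind="square_pulse", duration=0.2, intensity=10.0)
        sw = simulate_spiking_receptor(spiking_params, stim, n_sweeps=3, seed=3)
        with pytest.raises(ValueError, match="noise floor"):
            measure_spike_response(sw, threshold=1e-6)


class TestSpikeTimingDifference:
    @pytest.mark.parametrize("duration", [0.10, 0.20])
    def test_matches_pulse_duration(self, spiking_params, duration):
        pos = StimulusSpec(kind="square_pulse", duration=duration, polarity=1, intensity=10.0)
        neg = StimulusSpec(kind="square_pulse", duration=duration, polarity=-1, intensity=10.0)
        sp = simulate_spiking_receptor(spiking_params, pos, n_sweeps=10, seed=4)
        sn = simulate_spiking_receptor(spiking_params, neg, n_sweeps=10, seed=5)
        d = spike_timing_difference(sp, sn, threshold=0.6)
        assert d == pytest.approx(duration, abs=1.0 / 195.31)

    def test_same_polarity_raises(self, spiking_params):
        pos = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=10.0)
        sw = simulate_spiking_receptor(spiking_params, pos, n_sweeps=3, seed=6)
        with pytest.raises(ValueError):
            spike_timing_difference(sw, sw, threshold=0.6)


class TestPairInterspikeInterval:
    def test_ipi_3ms_exact(self, spiking_params):
        pair = StimulusSpec(kind="pulse_pair", duration=0.2, polarity=1, intensity=10.0, ipi=3.0)
        sw = simulate_spiking_receptor(spiking_params, pair, n_sweeps=10, seed=7)
        out = pair_interspike_interval(sw, threshold=0.6)
        assert out["both_pulse_probability"] == 1.0
        assert out["mean_interval"] == pytest.approx(3.0, abs=1.5 / FS)

    def test_ipi_below_refractory_no_second(self, spiking_params):
        pair = StimulusSpec(kind="pulse_pair", duration=0.2, polarity=1, intensity=10.0, ipi=0.5)
        sw = simulate_spiking_receptor(spiking_params, pair, n_sweeps=10, seed=8)
        out = pair_interspike_interval(sw, threshold=0.6)
        assert out["both_pulse_probability"] == 0.0
        assert np.isnan(out["mean_interval"])

    def test_ipi_8ms_reliable(self, spiking_params):
        pair = StimulusSpec(kind="pulse_pair", duration=0.2, polarity=1, intensity=10.0, ipi=8.0)
        sw = simulate_spiking_receptor(spiking_params, pair, n_sweeps=10, seed=9)
        out = pair_interspike_interval(sw, threshold=0.6)
        assert out["both_pulse_probability"] == 1.0


class TestPolarityPairFromSimulation:
    def test_delta_phi_near_180(self, osc_params):
        pos = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=2.0)
        neg = StimulusSpec(kind="square_pulse", duration=0.2, polarity=-1, intensity=2.0)
        sp = simulate_oscillating_receptor(osc_params, pos, n_sweeps=10, seed=21)
        sn = simulate_oscillating_receptor(osc_params, neg, n_sweeps=10, seed=22)
        d = delta_phase(polarity_pair_measurement(sp, sn))
        assert abs(abs(d["delta_phi"]) - 180.0) < 15.0

    def test_vector_strength_scale_invariance(self, osc_params):
        stim = StimulusSpec(kind="square_pulse", duration=0.2, polarity=1, intensity=5.0)
        sw = simulate_oscillating_receptor(osc_params, stim, n_sweeps=10, seed=23)
        r1 = measure_poststimulus_oscillation(sw)["summary"].vector_strength
        sw.sweeps = sw.sweeps * 7.0
        r2 = measure_poststimulus_oscillation(sw)["summary"].vector_strength
        assert r2 == pytest.approx(r1, abs=1e-9)
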