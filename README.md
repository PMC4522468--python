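# oscsync

Analysis and simulation of oscillatory and spiking electroreceptor
responses in mormyrid-like weakly electric fish: stimulus-evoked phase
resets, vector strength and circular statistics, interpulse-interval (IPI)
coding, population synchrony, frequency tuning, EOD event detection, and
behavioral EOD-rate quantification via spike-density functions.

Every analysis stage is paired with a first-class synthetic-data module
(`oscsync.synthdata`) that simulates oscillating receptors (forced
Stuart-Landau limit cycles), spiking receptors (edge-locked spikes with
latency, jitter, and refractoriness), stimulus artifacts, EOD waveforms and
trains, single-fish and group IPI trains, and behavioral EOD-time series —
so the whole pipeline is exercisable without any recorded data.

## Layout

| module | role |
| --- | --- |
| `oscsync.circstats` | vector strength, circular mean ± S.E.M., circular correlation, paired second-order Hotelling test |
| `oscsync.synthdata` | stimuli, receptor simulators, EOD trains, behavioral sessions, artifacts |
| `oscsync.spontaneous` | median filtering, peak/trough detection, spontaneous frequency/amplitude, ISIs, differential spectra |
| `oscsync.phase_independence` | Hilbert phases, joint phase distributions, surrogate pairings, phase-coupling test |
| `oscsync.evoked` | phase resets (phi, r, delta-phi), evoked amplitudes, interoscillation intervals, paired pulses, population sums, spike measures |
| `oscsync.tuning` | threshold and vector-strength tuning curves, stimulus peak frequency, EOD spectrum/duration, octaves |
| `oscsync.event_behavior` | EOD event detection, IPI histograms, spike-density functions, behavioral response metrics, species comparison |
| `oscsync.cli` | `oscsync` command: `simulate`, `analyze`, `demo` |

Conventions: time in ms, rates in kHz, voltage in mV, current in nA; angles
in radians (degrees only in reports). Stimuli default to a 195.31-kHz grid,
recordings to 97.7 kHz. All randomness flows through explicit seeds.

## CLI

```sh
# one experiment from a YAML config ({"experiment": "ipi_coding", ...})
oscsync simulate --config config.yaml --seed 1 --out results/ipi

# phase-reset analysis of a stored sweep container (HDF5 + JSON sidecar)
oscsync analyze --sweeps sweeps.h5 --out resets.csv

# small versions of all eight experiment kinds, with plots
oscsync demo --out demo/ --seed 0
```

Experiment kinds: `spontaneous`, `phase_independence`, `duration_coding`,
`tuning`, `ipi_coding`, `synchrony`, `group_ipi`, `behavior`. Each run
writes CSV summaries stamped with a config hash plus a `manifest.json`
(seed, config, versions); reruns with the same config and seed are
byte-identical.

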