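"""EOD event detection, IPI statistics, and behavioral playback metrics.

Event times are in ms (matching EventTrain); spike-density functions are
expressed in events/s on a grid in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthdata import EventTrain

__all__ = [
    "SdfResult",
    "detect_eod_events",
    "ipi_histogram",
    "spike_density_function",
    "behavioral_response_metrics",
    "normalized_response",
    "species_comparison",
]


@dataclass(frozen=True)
class SdfResult:
    time: np.ndarray  # s
    rate: np.ndarray  # events/s
    kernel_width: float  # ms (Gaussian sigma)
    baseline: Optional[float] = None  # events/s
    max_increase: Optional[float] = None
    max_decrease: Optional[float] = None
    baseline_window: Optional[tuple] = None  # s, relative to stimulus onset
    response_window: Optional[tuple] = None


def detect_eod_events(
    trace: np.ndarray,
    sample_rate: float,
    threshold: float = 0.6,
    dead_time: float = 0.25,
    saturation: Optional[float] = None,
) -> EventTrain:
    """Events where the rectified potential rises through ``threshold`` mV.

    Crossings within ``dead_time`` ms of the previous event are suppressed
    (multiphasic waveforms would otherwise double-count).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    x = np.abs(np.asarray(trace, dtype=float))
    if saturation is not None and np.any(x >= saturation):
        warnings.warn("trace contains saturated samples", stacklevel=2)
    above = x >= threshold
    rising = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    times = rising / sample_rate
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= dead_time:
            kept.append(t)
    duration = x.size / sample_rate
    return EventTrain(np.asarray(kept), duration, label="eod")


def ipi_histogram(events: EventTrain, bin_edges: np.ndarray) -> dict:
    """Histogram of successive interpulse intervals (ms).

    Sum of counts equals n_events - 1 when the edges cover all IPIs; the
    summary reports the fraction of IPIs below 1 ms.
    """
    if events.n_events < 2:
        return {"counts": np.zeros(max(len(bin_edges) - 1, 0), dtype=int), "ipis": np.array([]), "fraction_below_1ms": np.nan}
    ipis = np.diff(events.times)
    counts, _ = np.histogram(ipis, bins=bin_edges)
    return {
        "counts": counts,
        "ipis": ipis,
        "fraction_below_1ms": float(np.mean(ipis < 1.0)),
    }


def spike_density_function(
    events: EventTrain,
    width: float = 200.0,
    grid_step: float = 1.0,
    t_start: Optional[float] = None,
    t_stop: Optional[float] = None,
) -> SdfResult:
    """Sum of unit-area Gaussians (sigma = ``width`` ms) on a regular grid.

    Output rate is in events/s on a grid in seconds with ``grid_step`` ms
    spacing. Integrates to the event count up to edge effects.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    t0 = 0.0 if t_start is None else t_start
    t1 = events.duration if t_stop is None else t_stop
    grid_ms = np.arange(t0, t1 + grid_step / 2, grid_step)
    rate = np.zeros_like(grid_ms)
    sig = width
    norm = 1000.0 / (sig * np.sqrt(2 * np.pi))  # unit area in events, rate in events/s
    for t_ev in events.times:
        rate += norm * np.exp(-((grid_ms - t_ev) ** 2) / (2 * sig**2))
    return SdfResult(time=grid_ms / 1000.0, rate=rate, kernel_width=width)


def behavioral_response_metrics(
    sdfs: Sequence[SdfResult],
    stim_on: float,
    stim_off: float,
    baseline_window: tuple = (-4.8, -0.2),
    response_pad: tuple = (-0.2, 1.2),
) -> SdfResult:
    """Baseline and extrema of the repetition-averaged SDF.

    ``stim_on``/``stim_off`` in seconds on each SDF's grid. Baseline is the
    mean rate over [stim_on - 4.8 s, stim_on - 0.2 s]; max_increase /
    max_decrease are measured between 0.2 s before onset and 1.2 s after
    offset, relative to baseline. SDFs are averaged across repetitions
    before anything is measured.
    """
    grid = sdfs[0].time
    for s in sdfs[1:]:
        if s.time.shape != grid.shape or not np.allclose(s.time, grid):
            raise ValueError("all SDFs must share the same time grid")
    if stim_on + baseline_window[0] < grid[0] - 1e-9:
        raise ValueError("insufficient prestimulus span for the baseline window")
    mean_rate = np.mean([s.rate for s in sdfs], axis=0)
    b = (grid >= stim_on + baseline_window[0]) & (grid <= stim_on + baseline_window[1])
    baseline = float(mean_rate[b].mean())
    w = (grid >= stim_on + response_pad[0]) & (grid <= stim_off + response_pad[1])
    seg = mean_rate[w]
    return SdfResult(
        time=grid,
        rate=mean_rate,
        kernel_width=sdfs[0].kernel_width,
        baseline=baseline,
        max_increase=float(seg.max() - baseline),
        max_decrease=float(baseline - seg.min()),
        baseline_window=(stim_on + baseline_window[0], stim_on + baseline_window[1]),
        response_window=(stim_on + response_pad[0], stim_off + response_pad[1]),
    )


def normalized_response(r_ipi: float, r_single: float) -> float:
    """(r_ipi - r_single) / (r_ipi + r_single), in [-1, 1] for nonnegative inputs."""
    denom = r_ipi + r_single
    if denom == 0:
        raise ValueError("zero denominator: r_ipi + r_single = 0")
    return float((r_ipi - r_single) / denom)


def species_comparison(responses: pd.DataFrame) -> pd.DataFrame:
    """Two-factor repeated-measures comparison of normalized responses.

    ``responses`` needs columns fish, species, ipi, response; species is a
    between-subject factor, IPI a within-subject (repeated) factor. The
    design must be balanced within fish. Delegated to pingouin's mixed
    ANOVA; returns the ANOVA table (the interaction row is the comparison
    of interest).
    """
    import pingouin as pg

    required = {"fish", "species", "ipi", "response"}
    if not required.issubset(responses.columns):
        raise ValueError(f"responses must have columns {sorted(required)}")
    counts = responses.groupby("fish")["ipi"].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: fish differ in their IPI factor levels")
    per_cell = responses.groupby(["fish", "ipi"]).size()
    if (per_cell != 1).any():
        raise ValueError("unbalanced design: expected exactly one response per fish x IPI cell")
    table = pg.mixed_anova(
        data=responses, dv="response", within="ipi", between="species", subject="fish"
    )
    return table.rename(columns={"p-unc": "p_unc"})
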