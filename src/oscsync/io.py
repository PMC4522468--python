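"""Persistence: SweepSet as HDF5 + JSON sidecar, EventTrain as CSV."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthdata import EventTrain, StimulusSpec, SweepSet

__all__ = ["save_sweepset", "load_sweepset", "save_event_train", "load_event_train"]


def save_sweepset(sweeps: SweepSet, path) -> None:
    """Write sweeps to ``path`` (HDF5) with a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("sweeps", data=sweeps.sweeps, compression="gzip")
        if sweeps.stim_trace is not None:
            f.create_dataset("stim_trace", data=sweeps.stim_trace, compression="gzip")
        if sweeps.events is not None:
            flat = np.concatenate([np.asarray(e, dtype=float) for e in sweeps.events]) if sweeps.events else np.array([])
            offsets = np.cumsum([0] + [len(e) for e in sweeps.events])
            f.create_dataset("event_times", data=flat)
            f.create_dataset("event_offsets", data=offsets)
    meta = {
        "sample_rate_khz": sweeps.sample_rate,
        "t_stim_on_ms": sweeps.t_stim_on,
        "t_stim_off_ms": sweeps.t_stim_off,
        "seed": sweeps.seed,
        "stimulus": dataclasses.asdict(sweeps.stimulus) if sweeps.stimulus is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_sweepset(path) -> SweepSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with h5py.File(path, "r") as f:
        sweeps = f["sweeps"][...]
        stim_trace = f["stim_trace"][...] if "stim_trace" in f else None
        events = None
        if "event_times" in f:
            flat = f["event_times"][...]
            offsets = f["event_offsets"][...].astype(int)
            events = [flat[offsets[i] : offsets[i + 1]] for i in range(len(offsets) - 1)]
    spec = StimulusSpec(**meta["stimulus"]) if meta["stimulus"] is not None else None
    return SweepSet(
        sweeps=sweeps,
        sample_rate=meta["sample_rate_khz"],
        stimulus=spec,
        t_stim_on=meta["t_stim_on_ms"],
        t_stim_off=meta["t_stim_off_ms"],
        seed=meta["seed"],
        events=events,
        stim_trace=stim_trace,
    )


def save_event_train(train: EventTrain, path) -> None:
    """EventTrain as CSV with columns time_ms, label."""
    pd.DataFrame({"time_ms": train.times, "label": train.label}).to_csv(path, index=False)


def load_event_train(path, duration: float | None = None) -> EventTrain:
    df = pd.read_csv(path)
    times = df["time_ms"].to_numpy(dtype=float)
    label = str(df["label"].iloc[0]) if len(df) else ""
    if duration is None:
        duration = float(times[-1]) if times.size else 0.0
    return EventTrain(times, duration, label=label)
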