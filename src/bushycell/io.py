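"""Serialization of spike trains and conductance traces.

Spike trains travel as a tidy table (fiber, repetition, time_ms) in CSV or
HDF5, with the stimulus specification embedded as metadata (JSON header
comment for CSV, attributes for HDF5).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .an_surrogate import SpikeTrainSet, StimulusSpec
from .synaptic_input import ConductanceTrace

__all__ = [
    "trains_to_frame",
    "frame_to_trains",
    "save_trains_csv",
    "load_trains_csv",
    "save_trains_hdf5",
    "load_trains_hdf5",
    "save_conductance_csv",
]


def trains_to_frame(trains: SpikeTrainSet) -> pd.DataFrame:
    rows = []
    for f in range(trains.n_fibers):
        for r in range(trains.n_reps):
            for t in trains.spikes[f][r]:
                rows.append((f, r, t))
    return pd.DataFrame(rows, columns=["fiber", "repetition", "time_ms"])


def frame_to_trains(df: pd.DataFrame, stim: StimulusSpec, n_fibers: int,
                    seed: int | None = None) -> SpikeTrainSet:
    fib = df["fiber"].to_numpy()
    rep = df["repetition"].to_numpy()
    t = df["time_ms"].to_numpy(dtype=float)
    spikes = [[np.sort(t[(fib == f) & (rep == r)])
               for r in range(stim.n_reps)] for f in range(n_fibers)]
    return SpikeTrainSet(spikes=spikes, stimulus=stim, n_fibers=n_fibers,
                         seed=seed)


def _stim_to_json(stim: StimulusSpec) -> str:
    return json.dumps(dataclasses.asdict(stim))


def _stim_from_json(payload: str) -> StimulusSpec:
    return StimulusSpec(**json.loads(payload))


def save_trains_csv(trains: SpikeTrainSet, path: str | Path) -> None:
    path = Path(path)
    header = {"stimulus": dataclasses.asdict(trains.stimulus),
              "n_fibers": trains.n_fibers, "seed": trains.seed}
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(header)}\n")
        trains_to_frame(trains).to_csv(fh, index=False)


def load_trains_csv(path: str | Path) -> SpikeTrainSet:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip())
        df = pd.read_csv(fh)
    stim = StimulusSpec(**meta["stimulus"])
    return frame_to_trains(df, stim, meta["n_fibers"], meta.get("seed"))


def save_trains_hdf5(trains: SpikeTrainSet, path: str | Path) -> None:
    df = trains_to_frame(trains)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("fiber", data=df["fiber"].to_numpy(np.int32))
        fh.create_dataset("repetition",
                          data=df["repetition"].to_numpy(np.int32))
        fh.create_dataset("time_ms", data=df["time_ms"].to_numpy(float))
        fh.attrs["stimulus"] = _stim_to_json(trains.stimulus)
        fh.attrs["n_fibers"] = trains.n_fibers
        if trains.seed is not None:
            fh.attrs["seed"] = trains.seed


def load_trains_hdf5(path: str | Path) -> SpikeTrainSet:
    with h5py.File(path, "r") as fh:
        df = pd.DataFrame({
            "fiber": fh["fiber"][:],
            "repetition": fh["repetition"][:],
            "time_ms": fh["time_ms"][:],
        })
        stim = _stim_from_json(fh.attrs["stimulus"])
        n_fibers = int(fh.attrs["n_fibers"])
        seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
    return frame_to_trains(df, stim, n_fibers, seed)


def save_conductance_csv(trace: ConductanceTrace, path: str | Path) -> None:
    """Two-column (time_ms, G_nS) export, the shape a clamp rig consumes."""
    df = pd.DataFrame({"time_ms": trace.t, "G_nS": trace.samples})
    df.to_csv(path, index=False)
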