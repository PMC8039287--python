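"""File dialects shared across the pipeline.

Traces travel as HDF5 (``/traces`` neurons x frames, ``/positions``,
``/time``) or long CSV (neuron_id, t, F); spike/event trains as CSV
(neuron_id, t_s); metric bundles and ground truth as JSON.  Every
writer records the generator seed when one is known.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .netmetrics import SpikeTrainSet
from .synth import CalciumTraceSet

__all__ = [
    "save_traces_h5", "load_traces_h5",
    "save_traces_csv", "load_traces_csv",
    "save_spikes_csv", "load_spikes_csv",
    "save_json", "load_json", "file_sha256",
]


def save_traces_h5(path: str | Path, traces: CalciumTraceSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=traces.traces, track_times=False)
        f.create_dataset("positions", data=traces.positions, track_times=False)
        f.create_dataset("time", data=traces.time, track_times=False)
        f.attrs["frame_rate"] = traces.frame_rate
        f.attrs["f0"] = traces.f0
        if traces.seed is not None:
            f.attrs["seed"] = traces.seed


def load_traces_h5(path: str | Path) -> CalciumTraceSet:
    with h5py.File(path, "r") as f:
        return CalciumTraceSet(
            traces=f["traces"][...],
            positions=f["positions"][...],
            time=f["time"][...],
            frame_rate=float(f.attrs["frame_rate"]),
            f0=float(f.attrs.get("f0", 100.0)),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_traces_csv(path: str | Path, traces: CalciumTraceSet) -> None:
    m, t = traces.traces.shape
    df = pd.DataFrame(
        {
            "neuron_id": np.repeat(np.arange(m), t),
            "t": np.tile(traces.time, m),
            "F": traces.traces.ravel(),
        }
    )
    df.to_csv(path, index=False)


def load_traces_csv(path: str | Path, frame_rate: float = 10.0) -> CalciumTraceSet:
    df = pd.read_csv(path)
    wide = df.pivot(index="neuron_id", columns="t", values="F").sort_index()
    time = wide.columns.to_numpy(dtype=float)
    traces = wide.to_numpy(dtype=float)
    if time.size > 1:
        frame_rate = 1.0 / float(np.median(np.diff(time)))
    positions = np.zeros((traces.shape[0], 2))
    return CalciumTraceSet(traces=traces, time=time, positions=positions,
                           frame_rate=frame_rate)


def save_spikes_csv(path: str | Path, trains: SpikeTrainSet) -> None:
    rows = [
        {"neuron_id": i, "t_s": t}
        for i, train in enumerate(trains.trains)
        for t in train
    ]
    pd.DataFrame(rows, columns=["neuron_id", "t_s"]).to_csv(path, index=False)


def load_spikes_csv(path: str | Path, duration: float | None = None,
                    n_neurons: int | None = None) -> SpikeTrainSet:
    df = pd.read_csv(path)
    if n_neurons is None:
        n_neurons = int(df["neuron_id"].max()) + 1 if len(df) else 0
    trains = [
        np.sort(df.loc[df["neuron_id"] == i, "t_s"].to_numpy(dtype=float))
        for i in range(n_neurons)
    ]
    if duration is None:
        duration = float(df["t_s"].max()) if len(df) else 1.0
    return SpikeTrainSet(trains=trains, duration=duration)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def save_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
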