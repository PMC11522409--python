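"""File I/O: HDF5 raw recordings, CSV spike tables, JSON results.

The native raw format is a plain HDF5 layout::

    /signals            channels x samples, float32, microvolts
    /sampling_rate      scalar (Hz)
    /stimulation_times  1-D, seconds (may be empty)
    /electrode_map      table: id, node, x, y
    /metadata           attrs: div, condition, network_id

Proprietary vendor formats are deliberately not parsed; convert upstream.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .types import ElectrodeMap, Electrode, FormatError, RawRecording, SpikeTable

_METADATA_KEYS = ("div", "condition", "network_id")


def save_recording(recording: RawRecording, path) -> None:
    emap = recording.electrode_map
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=recording.samples.astype(np.float32))
        f.create_dataset("sampling_rate", data=float(recording.sampling_rate))
        f.create_dataset("stimulation_times", data=np.asarray(recording.stimulation_times, float))
        ids = np.array(emap.electrode_ids, dtype=h5py.string_dtype())
        nodes = np.array([e.node_label for e in emap.electrodes], dtype=h5py.string_dtype())
        g = f.create_group("electrode_map")
        g.create_dataset("id", data=ids)
        g.create_dataset("node", data=nodes)
        g.create_dataset("x", data=np.array([e.x for e in emap.electrodes]))
        g.create_dataset("y", data=np.array([e.y for e in emap.electrodes]))
        m = f.create_group("metadata")
        for k in _METADATA_KEYS:
            if k in recording.metadata:
                m.attrs[k] = recording.metadata[k]


def load_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        for required in ("signals", "sampling_rate", "electrode_map"):
            if required not in f:
                raise FormatError(f"missing dataset/group {required!r} in {path}")
        signals = np.asarray(f["signals"])
        rate = float(np.asarray(f["sampling_rate"]))
        stim = (
            np.asarray(f["stimulation_times"], dtype=float)
            if "stimulation_times" in f
            else np.empty(0)
        )
        g = f["electrode_map"]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in g["id"][()]]
        nodes = [s.decode() if isinstance(s, bytes) else str(s) for s in g["node"][()]]
        xs = np.asarray(g["x"]) if "x" in g else np.full(len(ids), np.nan)
        ys = np.asarray(g["y"]) if "y" in g else np.full(len(ids), np.nan)
        emap = ElectrodeMap(
            Electrode(i, n, float(x), float(y)) for i, n, x, y in zip(ids, nodes, xs, ys)
        )
        metadata = {}
        if "metadata" in f:
            for k, v in f["metadata"].attrs.items():
                metadata[k] = v.item() if hasattr(v, "item") else v
    if signals.ndim != 2 or signals.shape[0] != len(emap):
        raise FormatError(
            f"signals shape {signals.shape} does not match electrode map "
            f"of {len(emap)} entries"
        )
    return RawRecording(signals, rate, emap, stim, metadata)


def save_spike_table(table: SpikeTable, path) -> None:
    df = table.frame.copy()
    if df["amplitude_uv"].isna().all():
        df = df.drop(columns=["amplitude_uv"])
    df.to_csv(path, index=False)


def load_spike_table(
    path, duration: float, electrode_map: ElectrodeMap, metadata: dict | None = None
) -> SpikeTable:
    df = pd.read_csv(path)
    if "electrode_id" not in df.columns or "spike_time_s" not in df.columns:
        raise FormatError(
            f"spike table {path} must have columns electrode_id, spike_time_s"
        )
    return SpikeTable(df, duration, electrode_map, metadata)


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_deterministic(obj))


def dumps_deterministic(obj) -> str:
    """Canonical JSON: sorted keys, fixed separators, repr-stable floats."""
    return json.dumps(_plain(obj), sort_keys=True, indent=2, allow_nan=True)


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_plain(v) for v in seq]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
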