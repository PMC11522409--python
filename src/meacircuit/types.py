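"""Core data model for multinodal MEA recordings.

The experimental platform is a four-chamber microfluidic device (one cortical
node ``C`` feeding three hippocampal nodes ``H1``, ``H2``, ``H3`` through
unidirectional microtunnels) mounted on a microelectrode array.  Electrodes sit
either inside a chamber or inside a tunnel; the node order C < H1 < H2 < H3
defines the feedforward direction used throughout the propagation analysis.

Time is seconds (double precision) everywhere; sample indices are 0-based and
all bins are half-open ``[t, t + dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Chamber labels in feedforward order, followed by the tunnel pseudo-label.
NODE_ORDER: tuple[str, ...] = ("C", "H1", "H2", "H3")
TUNNEL = "TUNNEL"
VALID_LABELS = frozenset(NODE_ORDER) | {TUNNEL}


class FormatError(ValueError):
    """Raised when a file or in-memory structure violates the data contract."""


class ConfigError(ValueError):
    """Raised when a parameter combination is invalid."""


@dataclass(frozen=True)
class Electrode:
    electrode_id: str
    node_label: str
    x: float = float("nan")
    y: float = float("nan")
    is_reference: bool = False


class ElectrodeMap:
    """Assignment of electrode ids to device nodes (or the tunnels).

    Parameters
    ----------
    electrodes
        Iterable of :class:`Electrode` (or ``(id, label)`` pairs).
    """

    def __init__(self, electrodes: Iterable[Electrode | tuple[str, str]]):
        elecs: list[Electrode] = []
        for e in electrodes:
            if not isinstance(e, Electrode):
                e = Electrode(str(e[0]), str(e[1]))
            if e.node_label not in VALID_LABELS:
                raise FormatError(
                    f"unknown node label {e.node_label!r} for electrode "
                    f"{e.electrode_id!r}; expected one of {sorted(VALID_LABELS)}"
                )
            elecs.append(e)
        ids = [e.electrode_id for e in elecs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate electrode ids: {dupes}")
        self._electrodes = tuple(elecs)
        self._label = {e.electrode_id: e.node_label for e in elecs}

    @property
    def electrodes(self) -> tuple[Electrode, ...]:
        return self._electrodes

    @property
    def electrode_ids(self) -> list[str]:
        return [e.electrode_id for e in self._electrodes]

    def node_of(self, electrode_id: str) -> str:
        return self._label[electrode_id]

    def electrodes_in(self, node_label: str) -> list[str]:
        return [e.electrode_id for e in self._electrodes if e.node_label == node_label]

    def node_labels_present(self) -> list[str]:
        present = {e.node_label for e in self._electrodes}
        return [n for n in (*NODE_ORDER, TUNNEL) if n in present]

    def __len__(self) -> int:
        return len(self._electrodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ElectrodeMap):
            return NotImplemented

        def key(e: Electrode):
            return (
                e.electrode_id,
                e.node_label,
                None if np.isnan(e.x) else e.x,
                None if np.isnan(e.y) else e.y,
                e.is_reference,
            )

        return list(map(key, self._electrodes)) == list(map(key, other._electrodes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "electrode_id": [e.electrode_id for e in self._electrodes],
                "node": [e.node_label for e in self._electrodes],
                "x": [e.x for e in self._electrodes],
                "y": [e.y for e in self._electrodes],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ElectrodeMap":
        xs = df["x"] if "x" in df else [float("nan")] * len(df)
        ys = df["y"] if "y" in df else [float("nan")] * len(df)
        return cls(
            Electrode(str(i), str(n), float(x), float(y))
            for i, n, x, y in zip(df["electrode_id"], df["node"], xs, ys)
        )


def default_electrode_map(
    n_per_node: Sequence[int] = (13, 13, 12, 12), n_tunnel: int = 9
) -> ElectrodeMap:
    """The 59-electrode layout: 50 electrodes across the four nodes plus 9
    tunnel electrodes.  The per-node split is a layout convention of this
    package; electrode ids are ``C01..``, ``H1_01..``, ``T01..``."""
    elecs: list[Electrode] = []
    for node, n in zip(NODE_ORDER, n_per_node):
        prefix = node if node == "C" else node + "_"
        for i in range(n):
            elecs.append(Electrode(f"{prefix}{i + 1:02d}", node))
    for i in range(n_tunnel):
        elecs.append(Electrode(f"T{i + 1:02d}", TUNNEL))
    return ElectrodeMap(elecs)


def _validate_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    out = [(float(a), float(b)) for a, b in intervals]
    for a, b in out:
        if b < a:
            raise FormatError(f"masked interval ({a}, {b}) has negative length")
    return sorted(out)


@dataclass
class RawRecording:
    """Multichannel extracellular voltage recording.

    ``samples`` is channels x time in microvolts; rows follow
    ``electrode_map.electrode_ids``.
    """

    samples: np.ndarray
    sampling_rate: float
    electrode_map: ElectrodeMap
    stimulation_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    metadata: dict = field(default_factory=dict)
    masked_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D channels x time matrix")
        if self.sampling_rate <= 0:
            raise FormatError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.shape[0] != len(self.electrode_map):
            raise FormatError(
                f"channel count {self.samples.shape[0]} does not match "
                f"electrode map of {len(self.electrode_map)} electrodes"
            )
        self.stimulation_times = np.asarray(self.stimulation_times, dtype=float)
        if self.stimulation_times.size:
            if np.any(np.diff(self.stimulation_times) <= 0):
                raise FormatError("stimulation_times must be strictly increasing")
            if self.stimulation_times[0] < 0 or self.stimulation_times[-1] > self.duration:
                raise FormatError("stimulation_times must lie within [0, duration]")
        self.masked_intervals = _validate_intervals(self.masked_intervals)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, electrode_id: str) -> np.ndarray:
        return self.samples[self.electrode_map.electrode_ids.index(electrode_id)]


class SpikeTable:
    """Per-electrode spike times with optional peak-to-peak amplitudes.

    Backed by a tidy :class:`pandas.DataFrame` with columns
    ``electrode_id``, ``spike_time_s`` and optionally ``amplitude_uv``.
    Within each electrode, times are strictly increasing.
    """

    COLUMNS = ("electrode_id", "spike_time_s", "amplitude_uv")

    def __init__(
        self,
        frame: pd.DataFrame,
        duration: float,
        electrode_map: ElectrodeMap,
        metadata: dict | None = None,
        masked_intervals: Sequence[tuple[float, float]] = (),
    ):
        if duration <= 0:
            raise FormatError(f"duration must be > 0, got {duration}")
        frame = frame.copy()
        if "amplitude_uv" not in frame.columns:
            frame["amplitude_uv"] = np.nan
        frame = frame[list(self.COLUMNS)]
        frame["electrode_id"] = frame["electrode_id"].astype(str)
        frame["spike_time_s"] = frame["spike_time_s"].astype(float)
        known = set(electrode_map.electrode_ids)
        unknown = set(frame["electrode_id"]) - known
        if unknown:
            raise FormatError(f"spike rows reference unmapped electrodes: {sorted(unknown)}")
        t = frame["spike_time_s"].to_numpy()
        if t.size and (t.min() < 0 or t.max() > duration):
            raise FormatError("spike times must lie within [0, duration]")
        # stable sort keeps the on-disk row order within ties deterministic
        frame = frame.sort_values(["electrode_id", "spike_time_s"], kind="stable")
        for eid, g in frame.groupby("electrode_id", sort=False):
            dt = np.diff(g["spike_time_s"].to_numpy())
            if dt.size and np.any(dt <= 0):
                raise FormatError(
                    f"spike times not strictly increasing on electrode {eid!r}"
                )
        self.frame = frame.reset_index(drop=True)
        self.duration = float(duration)
        self.electrode_map = electrode_map
        self.metadata = dict(metadata or {})
        self.masked_intervals = _validate_intervals(masked_intervals)

    def __len__(self) -> int:
        return len(self.frame)

    def times(self, electrode_id: str) -> np.ndarray:
        sel = self.frame["electrode_id"] == electrode_id
        return self.frame.loc[sel, "spike_time_s"].to_numpy()

    def by_electrode(self) -> dict[str, np.ndarray]:
        out = {eid: np.empty(0) for eid in self.electrode_map.electrode_ids}
        for eid, g in self.frame.groupby("electrode_id", sort=False):
            out[eid] = g["spike_time_s"].to_numpy()
        return out

    @property
    def masked_duration(self) -> float:
        return sum(min(b, self.duration) - max(a, 0.0) for a, b in self.masked_intervals)

    @property
    def unmasked_duration(self) -> float:
        return self.duration - self.masked_duration

    @classmethod
    def from_arrays(
        cls,
        spikes: Mapping[str, np.ndarray],
        duration: float,
        electrode_map: ElectrodeMap,
        amplitudes: Mapping[str, np.ndarray] | None = None,
        metadata: dict | None = None,
        masked_intervals: Sequence[tuple[float, float]] = (),
    ) -> "SpikeTable":
        rows = []
        for eid, t in spikes.items():
            t = np.asarray(t, dtype=float)
            amp = None if amplitudes is None else amplitudes.get(eid)
            for i, ti in enumerate(t):
                rows.append(
                    (eid, ti, np.nan if amp is None else float(amp[i]))
                )
        frame = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(frame, duration, electrode_map, metadata, masked_intervals)


@dataclass(frozen=True)
class Burst:
    """A single-electrode burst: >= min_spikes consecutive spikes whose ISIs
    all fall at or below that electrode's ISI threshold."""

    electrode_id: str
    start: float
    end: float
    n_spikes: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("burst end must exceed start")
        if self.n_spikes < 2:
            raise ValueError("burst needs at least 2 spikes")


@dataclass
class NetworkBurst:
    """An epoch where at least the required fraction of active electrodes burst
    near-simultaneously; carries the feedforward propagation classification."""

    start: float
    end: float
    participating_electrodes: frozenset[str]
    node_onsets: dict[str, float]
    initiation_node: str | None = None
    span: int = 0
    feedforward: bool = False
    onset_tie_flag: bool = False

    def to_record(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "n_electrodes": len(self.participating_electrodes),
            "electrodes": sorted(self.participating_electrodes),
            "node_onsets": {k: self.node_onsets[k] for k in sorted(self.node_onsets)},
            "initiation_node": self.initiation_node,
            "span": self.span,
            "feedforward": self.feedforward,
        }
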