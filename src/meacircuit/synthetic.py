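"""Synthetic multinodal recordings with known ground truth.

Emulates the statistical structure the analysis assumes: network-burst events
arise as a Poisson process in an initiating node and hop down the feedforward
chain C -> H1 -> H2 -> H3, each hop succeeding with probability ``p_tx`` and
adding a (truncated-Gaussian, >= 1 ms) conduction delay; within a reached node
each electrode joins the event with ``participation_prob`` and fires a burst of
>= 4 spikes with exponential intra-burst ISIs; independent tonic Poisson
background spiking is superposed.  The amyloid-beta perturbation mode applies
the two effects reported for perturbed networks — a raised initiating-node
burst rate and a lowered hop transmission probability — and nothing else, so
any synchrony change downstream is emergent.

Raw-voltage rendering places a biphasic spike template (negative-first, 0.6 ms
trough-to-peak by default) at each spike time on top of white Gaussian noise at
25 kHz, optionally adding slow exponential stimulation artifacts.  Particle
phantoms render bright disks of known equivalent diameter for the
quantification stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .types import (
    ConfigError,
    ElectrodeMap,
    Electrode,
    NODE_ORDER,
    SpikeTable,
    RawRecording,
)

MIN_HOP_DELAY = 0.001  # s; keeps node onset order well-defined at small jitter
_MIN_SEP = 1e-6        # s; strict per-electrode ordering after superposition


@dataclass
class NetworkSimConfig:
    """Generator parameters.  ``nb_rate`` is network-burst initiations per
    minute per initiating node (scalar, or a mapping node -> rate)."""

    n_electrodes_per_node: int = 10
    nb_rate: float | Mapping[str, float] = 15.0
    p_tx: float = 0.8
    hop_delay: float = 0.02
    hop_delay_jitter_sd: float = 0.005
    participation_prob: float = 0.8
    electrode_onset_jitter_sd: float = 0.002
    intra_burst_isi_mean: float = 0.01
    spikes_per_burst_mean: float = 10.0
    tonic_rate: float = 0.5
    perturbation: str = "none"          # "none" | "abeta"
    abeta_rate_factor: float = 1.5      # multiplies initiating-node (C) rate
    abeta_tx_factor: float = 0.7        # multiplies p_tx
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_tx <= 1:
            raise ConfigError("p_tx must be in [0, 1]")
        if not 0 <= self.participation_prob <= 1:
            raise ConfigError("participation_prob must be in [0, 1]")
        rates = self.nb_rate.values() if isinstance(self.nb_rate, Mapping) else [self.nb_rate]
        if any(r < 0 for r in rates) or self.tonic_rate < 0:
            raise ConfigError("rates must be >= 0")
        if self.perturbation not in ("none", "abeta"):
            raise ConfigError(f"unknown perturbation {self.perturbation!r}")
        if self.abeta_rate_factor < 1 or not 0 <= self.abeta_tx_factor <= 1:
            raise ConfigError("abeta factors: rate >= 1, tx in [0, 1]")

    def node_rate(self, node: str) -> float:
        if isinstance(self.nb_rate, Mapping):
            r = float(self.nb_rate.get(node, 0.0))
        else:
            r = float(self.nb_rate)
        if self.perturbation == "abeta" and node == "C":
            r *= self.abeta_rate_factor
        return r

    @property
    def effective_p_tx(self) -> float:
        return self.p_tx * (self.abeta_tx_factor if self.perturbation == "abeta" else 1.0)


@dataclass
class GroundTruth:
    """Everything the generator knows: spikes, bursts and network-burst events."""

    spikes: dict[str, np.ndarray]
    bursts: list[dict]                 # electrode_id, start, end, n_spikes, event
    events: list[dict]                 # initiation_node, node_onsets, nodes_reached, t0
    duration: float

    def events_initiated_in(self, node: str) -> list[dict]:
        return [e for e in self.events if e["initiation_node"] == node]

    def span_fraction(self, node: str = "C", span: int = 4) -> float:
        evs = self.events_initiated_in(node)
        if not evs:
            return float("nan")
        return sum(len(e["nodes_reached"]) >= span for e in evs) / len(evs)

    def to_dict(self) -> dict:
        return {
            "duration": self.duration,
            "events": self.events,
            "bursts": self.bursts,
            "spikes": {k: list(map(float, v)) for k, v in self.spikes.items()},
        }


def simulation_electrode_map(n_per_node: int) -> ElectrodeMap:
    elecs = []
    for node in NODE_ORDER:
        prefix = node if node == "C" else node + "_"
        elecs += [Electrode(f"{prefix}{i + 1:02d}", node) for i in range(n_per_node)]
    return ElectrodeMap(elecs)


def _strictly_increasing(t: np.ndarray) -> np.ndarray:
    t = np.sort(t)
    for i in range(1, t.size):
        if t[i] - t[i - 1] < _MIN_SEP:
            t[i] = t[i - 1] + _MIN_SEP
    return t


def simulate_spike_trains(
    config: NetworkSimConfig,
    duration: float,
    electrode_map: ElectrodeMap | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SpikeTable, GroundTruth]:
    """Draw one recording's worth of spiking with full ground truth."""
    if duration <= 0:
        raise ConfigError("duration must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    emap = electrode_map or simulation_electrode_map(config.n_electrodes_per_node)
    p_tx = config.effective_p_tx

    # network-burst initiation events, Poisson per initiating node
    raw_events: list[tuple[float, str]] = []
    for node in NODE_ORDER:
        rate_hz = config.node_rate(node) / 60.0
        if rate_hz <= 0:
            continue
        n = rng.poisson(rate_hz * duration)
        raw_events += [(t, node) for t in np.sort(rng.uniform(0, duration, n))]
    raw_events.sort()

    spikes: dict[str, list[np.ndarray]] = {eid: [] for eid in emap.electrode_ids}
    gt_bursts: list[dict] = []
    events: list[dict] = []

    for ev_idx, (t0, init_node) in enumerate(raw_events):
        onsets = {init_node: t0}
        i = NODE_ORDER.index(init_node)
        t_node = t0
        while i + 1 < len(NODE_ORDER):
            if rng.random() >= p_tx:
                break
            delay = max(MIN_HOP_DELAY, rng.normal(config.hop_delay, config.hop_delay_jitter_sd))
            t_node += delay
            i += 1
            onsets[NODE_ORDER[i]] = t_node
        for node, t_on in onsets.items():
            for eid in emap.electrodes_in(node):
                if rng.random() >= config.participation_prob:
                    continue
                start = t_on + abs(rng.normal(0.0, config.electrode_onset_jitter_sd))
                n_spk = 4 + rng.poisson(max(config.spikes_per_burst_mean - 4, 0.0))
                isis = rng.exponential(config.intra_burst_isi_mean, n_spk - 1)
                t = start + np.concatenate([[0.0], np.cumsum(isis)])
                t = t[t < duration]
                if t.size >= 2:
                    spikes[eid].append(t)
                    gt_bursts.append(
                        {
                            "electrode_id": eid,
                            "start": float(t[0]),
                            "end": float(t[-1]),
                            "n_spikes": int(t.size),
                            "event": ev_idx,
                        }
                    )
        events.append(
            {
                "t0": float(t0),
                "initiation_node": init_node,
                "node_onsets": {k: float(v) for k, v in onsets.items()},
                "nodes_reached": [n for n in NODE_ORDER if n in onsets],
            }
        )

    if config.tonic_rate > 0:
        for eid in emap.electrode_ids:
            n = rng.poisson(config.tonic_rate * duration)
            if n:
                spikes[eid].append(rng.uniform(0, duration, n))

    final: dict[str, np.ndarray] = {}
    for eid in emap.electrode_ids:
        t = np.concatenate(spikes[eid]) if spikes[eid] else np.empty(0)
        final[eid] = _strictly_increasing(t)

    table = SpikeTable.from_arrays(final, duration, emap)
    return table, GroundTruth(final, gt_bursts, events, duration)


def match_spike_trains(
    truth: SpikeTable, detected: SpikeTable, tol: float = 5e-4
) -> dict[str, float]:
    """Greedy one-to-one matching of detected to true spikes within ``tol``
    seconds, per electrode.  Returns recall, precision and counts."""
    tp = fn = 0
    det_by = detected.by_electrode()
    used = {eid: np.zeros(t.size, dtype=bool) for eid, t in det_by.items()}
    for eid, t_true in truth.by_electrode().items():
        dd = det_by.get(eid, np.empty(0))
        for s in t_true:
            i = int(np.searchsorted(dd, s))
            hit = None
            for j in (i - 1, i):
                if 0 <= j < dd.size and abs(dd[j] - s) <= tol and not used[eid][j]:
                    hit = j
                    break
            if hit is None:
                fn += 1
            else:
                used[eid][hit] = True
                tp += 1
    fp = int(sum((~u).sum() for u in used.values()))
    return {
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "n_true": tp + fn,
        "n_detected": tp + fp,
    }


def enforce_min_separation(table: SpikeTable, min_sep: float) -> SpikeTable:
    """Thin each electrode's train so consecutive spikes are at least
    ``min_sep`` apart (the later spike of a close pair is dropped).  Use this
    when building detection-recovery fixtures: a detector with a refractory
    period can only ever recover trains that respect it."""
    spikes = {}
    for eid, t in table.by_electrode().items():
        kept: list[float] = []
        for ti in t:
            if not kept or ti - kept[-1] >= min_sep:
                kept.append(ti)
        spikes[eid] = np.asarray(kept)
    return SpikeTable.from_arrays(spikes, table.duration, table.electrode_map)


def jitter_spike_times(
    table: SpikeTable, jitter_sd: float, rng: np.random.Generator
) -> SpikeTable:
    """Add zero-mean Gaussian jitter to every spike, keeping the total count
    fixed (times reflected back into [0, duration]).  Used to degrade
    synchrony in a controlled way."""
    spikes = {}
    for eid, t in table.by_electrode().items():
        tj = t + rng.normal(0.0, jitter_sd, t.size)
        tj = np.abs(tj)                                  # reflect at 0
        over = tj > table.duration
        tj[over] = 2 * table.duration - tj[over]         # reflect at end
        tj = np.clip(tj, 0.0, np.nextafter(table.duration, 0.0))
        spikes[eid] = _strictly_increasing(tj)
    return SpikeTable.from_arrays(spikes, table.duration, table.electrode_map)


# ---------------------------------------------------------------------------
# raw-voltage rendering
# ---------------------------------------------------------------------------

@dataclass
class SpikeTemplateSpec:
    """Biphasic extracellular spike waveform: a dominant negative lobe
    followed by a smaller repolarization lobe (half-sine each), with the
    trough-to-peak time fixed at half the total duration (0.6 ms by
    default).  The negative lobe dominates, as perisomatic extracellular
    spikes do, so the trough defines the spike time."""

    duration_s: float = 0.0012
    negative_first: bool = True
    second_lobe_ratio: float = 0.45

    def waveform(self, sampling_rate: float) -> np.ndarray:
        half = max(int(round(self.duration_s * sampling_rate / 2)), 3)
        lobe = np.sin(np.pi * np.arange(half) / half)
        w = np.concatenate([-lobe, self.second_lobe_ratio * lobe])
        if not self.negative_first:
            w = -w
        return w / np.ptp(w)  # unit peak-to-peak


@dataclass
class StimArtifactSpec:
    times: Sequence[float]
    amplitude_uv: float = 500.0
    decay_tau_s: float = 0.002


def render_raw_signal(
    table: SpikeTable,
    noise_sd: float,
    amplitude_uv: float = 60.0,
    template: SpikeTemplateSpec | None = None,
    stim_spec: StimArtifactSpec | None = None,
    sampling_rate: float = 25000.0,
    rng: np.random.Generator | None = None,
) -> RawRecording:
    """Render a spike table into a noisy voltage recording.

    Each spike becomes the template scaled to ``amplitude_uv`` peak-to-peak
    (or the spike's own ``amplitude_uv`` column when present), aligned so the
    dominant extremum (the trough) falls at the spike time.
    """
    if noise_sd <= 0:
        raise ConfigError("noise_sd must be > 0")
    template = template or SpikeTemplateSpec()
    if template.duration_s > 0.002:
        raise ConfigError("template duration must be <= 2 ms")
    if rng is None:
        rng = np.random.default_rng(0)
    emap = table.electrode_map
    n_samples = int(round(table.duration * sampling_rate))
    w = template.waveform(sampling_rate)
    peak_off = int(np.argmax(np.abs(w)))
    signals = rng.normal(0.0, noise_sd, (len(emap), n_samples))

    amp_col = table.frame["amplitude_uv"].to_numpy()
    eids = table.frame["electrode_id"].to_numpy()
    times = table.frame["spike_time_s"].to_numpy()
    row_of = {eid: i for i, eid in enumerate(emap.electrode_ids)}
    truncated = 0
    for eid, t, a in zip(eids, times, amp_col):
        amp = float(a) if np.isfinite(a) else amplitude_uv
        start = int(round(t * sampling_rate)) - peak_off
        seg = w * amp
        s0, s1 = max(start, 0), min(start + w.size, n_samples)
        if s1 - s0 < w.size:
            truncated += 1
        if s1 > s0:
            signals[row_of[eid], s0:s1] += seg[s0 - start : s1 - start]
    if truncated:
        warnings.warn(f"{truncated} spike template(s) truncated at recording edge")

    stim_times = np.empty(0)
    if stim_spec is not None:
        stim_times = np.asarray(sorted(stim_spec.times), dtype=float)
        n_art = int(round(10 * stim_spec.decay_tau_s * sampling_rate))
        t_art = np.arange(n_art) / sampling_rate
        art = stim_spec.amplitude_uv * np.exp(-t_art / stim_spec.decay_tau_s)
        for ts in stim_times:
            s0 = int(round(ts * sampling_rate))
            s1 = min(s0 + n_art, n_samples)
            if s1 > s0:
                signals[:, s0:s1] += art[: s1 - s0]

    return RawRecording(
        signals.astype(np.float32),
        sampling_rate,
        emap,
        stim_times,
        dict(table.metadata),
    )


# ---------------------------------------------------------------------------
# particle-image phantoms
# ---------------------------------------------------------------------------

def make_particle_phantom(
    shape: tuple[int, int],
    disks: Sequence[tuple[tuple[float, float], float]],
    um_per_px: float = 2803.0 / 2046.0,
    foreground: int = 200,
    background: int = 20,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Render bright disks on a dark background.

    ``disks`` is a list of ``((row, col), diameter_um)``.  Returns an 8-bit
    image and the ground-truth record (one entry per disk, with its equivalent
    circular diameter in µm from the rendered pixel area).
    """
    img = np.full(shape, float(background))
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    truth = []
    for (r0, c0), diam_um in disks:
        if diam_um <= 0:
            raise ConfigError("disk diameters must be > 0")
        radius_px = (diam_um / um_per_px) / 2.0
        if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
            raise ConfigError(f"disk centre {(r0, c0)} outside image {shape}")
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
        img[mask] = foreground
        area_px = int(mask.sum())
        truth.append(
            {
                "center": (float(r0), float(c0)),
                "diameter_um": float(diam_um),
                "area_px": area_px,
                "equivalent_diameter_um": 2.0
                * np.sqrt(area_px * um_per_px**2 / np.pi),
            }
        )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, noise_sd, shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), truth


def sim_config_from_mapping(d: Mapping) -> NetworkSimConfig:
    d = dict(d)
    if "simulation" in d and isinstance(d["simulation"], Mapping):
        d = dict(d["simulation"])
    return NetworkSimConfig(**d)
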