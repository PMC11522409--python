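"""Burst and network-burst detection, and feedforward propagation analysis.

Single-electrode bursts use the logISI approach: the histogram of log10(ISI)
is typically bimodal, with an intra-burst peak below 100 ms and a slower
inter-burst mode; the ISI threshold is the minimum between the two modes,
accepted only when the "void" between the peaks is deep enough
(void >= 0.7), and always capped at the 100 ms hard maximum.  Runs of at
least four consecutive spikes whose ISIs stay at or below the threshold are
bursts.

Network bursts reuse the same histogram machinery on the pooled sequence of
burst onsets across all electrodes (logIBEI): onset groups separated by gaps
above the derived inter-burst-event threshold are candidates, and a candidate
qualifies when at least 10% of the active electrodes (ceil, inclusive) burst
within it.  Each network burst is then classified by its propagation through
the feedforward chain C -> H1 -> H2 -> H3: the initiation node is the node
with the earliest burst onset, and the span counts consecutive downstream
nodes reached with strictly increasing onsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .types import (
    Burst,
    ConfigError,
    ElectrodeMap,
    NetworkBurst,
    NODE_ORDER,
    SpikeTable,
    TUNNEL,
)


@dataclass
class BurstParams:
    min_spikes: int = 4
    max_isi: float = 0.100
    bins_per_decade: int = 10
    smoothing_window: int = 3
    void_threshold: float = 0.7
    active_rate_min: float = 0.1
    nb_fraction: float = 0.10

    def __post_init__(self):
        if self.min_spikes < 2:
            raise ConfigError("min_spikes must be >= 2")
        if self.max_isi <= 0:
            raise ConfigError("max_isi must be > 0")
        if not 0 < self.void_threshold < 1:
            raise ConfigError("void_threshold must be in (0, 1)")
        if not 0 < self.nb_fraction <= 1:
            raise ConfigError("nb_fraction must be in (0, 1]")


def isi_threshold_logisi(
    spike_times: np.ndarray,
    params: BurstParams | None = None,
    void_choice: str = "first",
) -> float | None:
    """ISI threshold (s) from the log-ISI histogram; ``None`` if < 2 spikes.

    ``void_choice`` picks which qualifying void sets the threshold when the
    histogram has more than two modes: ``"first"`` (the void right after the
    intra-burst peak — the published single-electrode behavior) or ``"last"``
    (the void bordering the slowest mode — used for network-wide
    inter-burst-event intervals, where intermediate modes reflect conduction
    delays between nodes rather than event boundaries).  Falls back to
    ``max_isi`` when no valid peak/void structure exists, and is always capped
    at ``max_isi``.
    """
    params = params or BurstParams()
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        return None
    isi = np.diff(t)
    isi = isi[isi > 0]
    if isi.size == 0:
        return None
    logisi = np.log10(isi)
    lo = math.floor(logisi.min() * params.bins_per_decade) / params.bins_per_decade
    hi = math.ceil(logisi.max() * params.bins_per_decade) / params.bins_per_decade
    n_bins = max(int(round((hi - lo) * params.bins_per_decade)), 1)
    counts, edges = np.histogram(logisi, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = max(int(params.smoothing_window), 1)
    smooth = np.convolve(counts.astype(float), np.ones(w) / w, mode="same")

    peaks, _ = find_peaks(smooth)
    # peaks at the histogram edges are real modes too
    if smooth.size >= 2 and smooth[0] > smooth[1]:
        peaks = np.concatenate([[0], peaks])
    if smooth.size >= 2 and smooth[-1] > smooth[-2]:
        peaks = np.concatenate([peaks, [smooth.size - 1]])
    peaks = np.sort(peaks.astype(int))

    log_cap = np.log10(params.max_isi)
    intra = [p for p in peaks if centers[p] < log_cap]
    if not intra:
        return params.max_isi
    if void_choice not in ("first", "last"):
        raise ConfigError(f"void_choice must be 'first' or 'last', got {void_choice!r}")
    p1 = max(intra, key=lambda p: smooth[p])
    later = [p for p in peaks if p > p1]
    best = None
    for p2 in later:
        seg = smooth[p1 : p2 + 1]
        m = p1 + int(np.argmin(seg))
        denom = math.sqrt(smooth[p1] * smooth[p2])
        void = 1.0 - (smooth[m] / denom if denom > 0 else 1.0)
        if void >= params.void_threshold:
            best = m
            if void_choice == "first":
                break
    if best is None:
        return params.max_isi
    return float(min(10.0 ** centers[best], params.max_isi))


def detect_bursts(
    spike_times: np.ndarray,
    threshold: float,
    electrode_id: str = "",
    params: BurstParams | None = None,
) -> list[Burst]:
    """Maximal runs of consecutive spikes with ISI <= threshold; runs with at
    least ``min_spikes`` spikes become bursts."""
    params = params or BurstParams()
    if threshold <= 0:
        raise ConfigError("threshold must be > 0")
    t = np.asarray(spike_times, dtype=float)
    if t.size < params.min_spikes:
        return []
    gaps = np.diff(t) > threshold
    boundaries = np.flatnonzero(gaps) + 1
    bursts = []
    for run in np.split(np.arange(t.size), boundaries):
        if run.size >= params.min_spikes:
            bursts.append(
                Burst(electrode_id, float(t[run[0]]), float(t[run[-1]]), int(run.size))
            )
    return bursts


def detect_bursts_table(
    table: SpikeTable, params: BurstParams | None = None
) -> tuple[list[Burst], dict[str, float]]:
    """logISI threshold + burst detection per electrode.  Returns all bursts
    and the per-electrode thresholds actually applied."""
    params = params or BurstParams()
    bursts: list[Burst] = []
    thresholds: dict[str, float] = {}
    for eid, t in table.by_electrode().items():
        thr = isi_threshold_logisi(t, params)
        if thr is None:
            continue
        thresholds[eid] = thr
        bursts += detect_bursts(t, thr, eid, params)
    bursts.sort(key=lambda b: (b.start, b.electrode_id))
    return bursts, thresholds


def active_electrodes(table: SpikeTable, params: BurstParams | None = None) -> set[str]:
    """Electrodes firing at >= ``active_rate_min`` Hz over unmasked time."""
    params = params or BurstParams()
    denom = table.unmasked_duration
    if denom <= 0:
        raise ConfigError("no unmasked recording time")
    return {
        eid
        for eid, t in table.by_electrode().items()
        if t.size / denom >= params.active_rate_min
    }


def detect_network_bursts(
    bursts: list[Burst],
    active: set[str],
    params: BurstParams | None = None,
    electrode_map: ElectrodeMap | None = None,
    onset_outlier_gap: float = 0.010,
) -> list[NetworkBurst]:
    """Group burst onsets network-wide (logIBEI) and keep groups where at
    least ceil(fraction x |active|) distinct electrodes burst."""
    params = params or BurstParams()
    if not active:
        raise ConfigError("active electrode set is empty")
    if not bursts:
        return []
    order = sorted(bursts, key=lambda b: b.start)
    onsets = np.array([b.start for b in order])
    thr = isi_threshold_logisi(onsets, params, void_choice="last")
    if thr is None:
        thr = params.max_isi
    min_electrodes = math.ceil(params.nb_fraction * len(active))

    boundaries = np.flatnonzero(np.diff(onsets) > thr) + 1
    out: list[NetworkBurst] = []
    for run in np.split(np.arange(onsets.size), boundaries):
        group = [order[i] for i in run]
        electrodes = frozenset(b.electrode_id for b in group)
        if len(electrodes) < min_electrodes:
            continue
        nb = NetworkBurst(
            start=min(b.start for b in group),
            end=max(b.end for b in group),
            participating_electrodes=electrodes,
            node_onsets={},
        )
        if electrode_map is not None:
            starts_by_node: dict[str, list[float]] = {}
            for b in group:
                node = electrode_map.node_of(b.electrode_id)
                if node != TUNNEL:
                    starts_by_node.setdefault(node, []).append(b.start)
            nb.node_onsets = {
                node: _node_onset(starts, onset_outlier_gap)
                for node, starts in starts_by_node.items()
            }
            classify_propagation(nb)
        out.append(nb)
    return out


def _node_onset(starts: list[float], outlier_gap: float) -> float:
    """Earliest burst start in the node, after dropping isolated early
    outliers (a leading start more than ``outlier_gap`` ahead of the next
    one, which typically means a tonic spike got appended to the front of a
    burst by the ISI-run rule)."""
    s = sorted(starts)
    while len(s) >= 2 and s[1] - s[0] > outlier_gap:
        s = s[1:]
    return s[0]


def classify_propagation(nb: NetworkBurst, tie_tol: float = 0.0) -> NetworkBurst:
    """Fill in initiation node, span and the feedforward flag from per-node
    onsets.  Onset ties within ``tie_tol`` resolve toward the upstream node
    and set ``onset_tie_flag``."""
    onsets = nb.node_onsets
    if not onsets:
        raise ConfigError("network burst has no node onsets")
    nodes = [n for n in NODE_ORDER if n in onsets]
    t_min = min(onsets[n] for n in nodes)
    tied = [n for n in nodes if onsets[n] - t_min <= tie_tol]
    nb.onset_tie_flag = len(tied) > 1
    init = tied[0]  # NODE_ORDER is upstream-first
    span = 1
    i = NODE_ORDER.index(init)
    t_prev = onsets[init]
    while i + 1 < len(NODE_ORDER):
        nxt = NODE_ORDER[i + 1]
        if nxt not in onsets or onsets[nxt] <= t_prev:
            break
        span += 1
        i += 1
        t_prev = onsets[nxt]
    nb.initiation_node = init
    nb.span = span
    nb.feedforward = init == "C" and span == len(NODE_ORDER)
    return nb


def propagation_summary(
    network_bursts: list[NetworkBurst],
    bursts: list[Burst] | None = None,
    table: SpikeTable | None = None,
) -> dict:
    """Counts and percentages of network bursts by initiation node and span,
    plus (when bursts and the table are given) the per-node burst rate:
    the median across that node's electrodes of bursts per minute."""
    if not network_bursts:
        raise ConfigError("no network bursts to summarize")
    rows = [(nb.initiation_node, nb.span) for nb in network_bursts]
    df = pd.DataFrame(rows, columns=["initiation_node", "span"])
    total = len(df)
    counts = (
        df.groupby(["initiation_node", "span"]).size().reset_index(name="count")
    )
    counts["percent"] = 100.0 * counts["count"] / total
    summary: dict = {
        "n_network_bursts": total,
        "by_initiation_and_span": [
            {
                "initiation_node": r.initiation_node,
                "span": int(r.span),
                "count": int(r.count),
                "percent": float(r.percent),
            }
            for r in counts.itertuples()
        ],
        "percent_feedforward": 100.0
        * sum(nb.feedforward for nb in network_bursts)
        / total,
    }
    if bursts is not None and table is not None:
        minutes = table.unmasked_duration / 60.0
        per_elec: dict[str, int] = {eid: 0 for eid in table.electrode_map.electrode_ids}
        for b in bursts:
            per_elec[b.electrode_id] += 1
        node_rates = {}
        for node in NODE_ORDER:
            eids = table.electrode_map.electrodes_in(node)
            if eids:
                node_rates[node] = float(
                    np.median([per_elec[e] / minutes for e in eids])
                )
        summary["median_burst_rate_per_min_by_node"] = node_rates
    return summary
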