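"""Firing-rate series, the coherence index, and peristimulus time histograms.

The coherence index (CI) summarizes network synchrony as the ratio of the
standard deviation to the mean of the binned population firing rate: a
perfectly steady population gives CI = 0, while activity concentrated in
sparse network bursts gives a large CI.  The sample (n-1) SD convention is
used; on the toy case of a single occupied bin among M this yields exactly
CI = sqrt(M).

PSTHs follow the stimulation protocol: spike counts pooled per node in
20 ms bins over the 300 ms following each stimulus (the first 15 ms having
been blanked upstream), with mean and SD taken across the stimulus trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import ConfigError, ElectrodeMap, NODE_ORDER, SpikeTable


@dataclass
class RateSeries:
    bin_width: float
    rates_hz: np.ndarray            # per bin (scope already pooled)
    scope: str = "network"

    @property
    def n_bins(self) -> int:
        return int(self.rates_hz.size)


def instantaneous_firing_rate(
    table: SpikeTable,
    bin_width: float = 0.050,
    scope: str = "network",
    node: str | None = None,
    electrode_id: str | None = None,
) -> RateSeries:
    """Spike counts per half-open bin divided by the bin width (Hz).

    ``scope`` selects pooling: one electrode, one node's electrodes summed, or
    the whole network summed.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    n_bins = math.ceil(table.duration / bin_width)
    if scope == "electrode":
        t = table.times(electrode_id)
    elif scope == "node":
        eids = set(table.electrode_map.electrodes_in(node))
        sel = table.frame["electrode_id"].isin(eids)
        t = table.frame.loc[sel, "spike_time_s"].to_numpy()
    elif scope == "network":
        t = table.frame["spike_time_s"].to_numpy()
    else:
        raise ConfigError(f"unknown scope {scope!r}")
    counts, _ = np.histogram(t, bins=n_bins, range=(0.0, n_bins * bin_width))
    return RateSeries(bin_width, counts / bin_width, scope)


def coherence_index(rates: RateSeries | np.ndarray) -> float:
    """SD/mean of the binned population rate (sample SD, ddof=1).

    Scale-invariant; returns NaN (flagged undefined) for zero activity.
    """
    x = rates.rates_hz if isinstance(rates, RateSeries) else np.asarray(rates, float)
    if x.size < 2:
        raise ConfigError("coherence index needs >= 2 bins")
    m = float(np.mean(x))
    if m == 0.0:
        return float("nan")
    return float(np.std(x, ddof=1) / m)


def median_firing_rate(table: SpikeTable, electrode_ids=None) -> float:
    """Median across electrodes of spikes per unmasked second (Hz)."""
    denom = table.unmasked_duration
    if denom <= 0:
        raise ConfigError("no unmasked recording time")
    by = table.by_electrode()
    eids = list(electrode_ids) if electrode_ids is not None else list(by)
    if not eids:
        raise ConfigError("no electrodes to summarize")
    return float(np.median([by[e].size / denom for e in eids]))


@dataclass
class PSTHResult:
    bin_edges_s: np.ndarray                   # (0, window], half-open bins
    node_mean: dict[str, np.ndarray]          # mean count per bin across trials
    node_sd: dict[str, np.ndarray]            # SD across trials (ddof=1)
    n_trials: int

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 1000.0 * 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "bin_centers_ms": self.bin_centers_ms.tolist(),
            "mean": {k: v.tolist() for k, v in self.node_mean.items()},
            "sd": {k: v.tolist() for k, v in self.node_sd.items()},
        }


def compute_psth(
    table: SpikeTable,
    stim_times,
    window: float = 0.300,
    bin_width: float = 0.020,
    electrode_map: ElectrodeMap | None = None,
) -> PSTHResult:
    """Per-node PSTH: counts pooled over each node's electrodes in half-open
    ``bin_width`` bins covering ``[0, window)`` after every stimulus, then
    mean and SD across trials.

    Expects the table to be blanked for the post-stimulus dead time already.
    """
    stim = np.asarray(stim_times, dtype=float)
    if stim.size == 0:
        raise ConfigError("need at least one stimulus")
    if stim.size > 1 and np.any(np.diff(stim) < window):
        raise ConfigError("PSTH window overlaps the next stimulus")
    emap = electrode_map or table.electrode_map
    n_bins = int(round(window / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    node_mean: dict[str, np.ndarray] = {}
    node_sd: dict[str, np.ndarray] = {}
    for node in NODE_ORDER:
        eids = set(emap.electrodes_in(node))
        if not eids:
            continue
        sel = table.frame["electrode_id"].isin(eids)
        t = table.frame.loc[sel, "spike_time_s"].to_numpy()
        per_trial = np.empty((stim.size, n_bins))
        for i, ts in enumerate(stim):
            rel = t - ts
            per_trial[i], _ = np.histogram(rel, bins=edges)
        node_mean[node] = per_trial.mean(axis=0)
        node_sd[node] = (
            per_trial.std(axis=0, ddof=1) if stim.size > 1
            else np.zeros(n_bins)
        )
    return PSTHResult(edges, node_mean, node_sd, int(stim.size))
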