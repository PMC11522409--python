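"""End-to-end pipeline: raw recording (or spike table) in, metrics bundle out.

Stages, in order: band-pass/notch filtering, SALPA + blanking when the
recording contains stimuli, PTSD spike detection, logISI bursts, logIBEI
network bursts with propagation classification, rate/synchrony metrics,
binned cross-correlation connectivity, graph metrics (Louvain communities,
modularity, pagerank), and PSTHs for stimulation recordings.  Spike-table
inputs skip the signal stages.

The bundle embeds provenance (config hash, seed, stage list) so longitudinal
runs are comparable; given a fixed config and seed the serialized bundle is
byte-identical across invocations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .config import AnalysisConfig
from .types import RawRecording, SpikeTable
from .preprocess import FilterSpec, SalpaSpec, bandpass_notch_filter, salpa_subtract, blank_after_stimulus
from .spikes import SpikeDetectionParams, detect_spikes
from .bursts import (
    BurstParams,
    active_electrodes,
    detect_bursts_table,
    detect_network_bursts,
    propagation_summary,
)
from .dynamics import coherence_index, compute_psth, instantaneous_firing_rate, median_firing_rate
from .connectivity import (
    bin_trains,
    build_graph,
    correlation_matrices,
    louvain_modularity,
    pagerank,
)
from .io import dumps_deterministic


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input id."""


@dataclass
class ResultsBundle:
    provenance: dict
    results: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return dumps_deterministic({"provenance": self.provenance, "results": self.results})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def _filter_spec(cfg: AnalysisConfig) -> FilterSpec:
    return FilterSpec(
        cfg.filter_order, cfg.low_cut_hz, cfg.high_cut_hz,
        cfg.notch_freq_hz, cfg.notch_quality, cfg.zero_phase,
    )


def _detection_params(cfg: AnalysisConfig) -> SpikeDetectionParams:
    return SpikeDetectionParams(
        cfg.threshold_multiplier, cfg.peak_lifetime_s, cfg.refractory_s,
        cfg.noise_sd_method,
    )


def _burst_params(cfg: AnalysisConfig) -> BurstParams:
    return BurstParams(
        cfg.min_spikes_per_burst, cfg.max_isi_s, cfg.isi_bins_per_decade,
        cfg.isi_smoothing_window, cfg.void_threshold, cfg.active_rate_min_hz,
        cfg.network_burst_fraction,
    )


def run_pipeline(
    data: RawRecording | SpikeTable,
    config: AnalysisConfig | None = None,
    input_id: str = "recording",
    stim_times=None,
) -> ResultsBundle:
    """Run every applicable stage on one recording or spike table.

    ``stim_times`` supplies stimulation timestamps for spike-table inputs
    (raw recordings carry their own).
    """
    cfg = config or AnalysisConfig()
    bundle = ResultsBundle(
        provenance={
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "package_version": _pkg_version,
            "input_id": input_id,
            "stages": [],
        }
    )

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise StageError(f"stage {name!r} failed on input {input_id!r}: {exc}") from exc
        bundle.provenance["stages"].append(name)
        return out

    stim_times = np.asarray(stim_times if stim_times is not None else [], dtype=float)
    if isinstance(data, RawRecording):
        if stim_times.size == 0:
            stim_times = np.asarray(data.stimulation_times, dtype=float)
        rec = stage("filter", bandpass_notch_filter, data, _filter_spec(cfg))
        if stim_times.size:
            salpa = SalpaSpec(
                poly_order=cfg.salpa_poly_order,
                fit_halfwidth=cfg.salpa_fit_halfwidth,
                epoch=cfg.salpa_epoch_s,
                blank_after=cfg.blank_after_s,
            )
            rec = stage("salpa", salpa_subtract, rec, stim_times, salpa)
            rec = stage("blank", blank_after_stimulus, rec, stim_times, cfg.blank_after_s)
        table = stage("ptsd", detect_spikes, rec, _detection_params(cfg))
    elif isinstance(data, SpikeTable):
        table = data
        if stim_times.size:
            table = stage("blank", blank_after_stimulus, table, stim_times, cfg.blank_after_s)
    else:
        raise TypeError(f"unsupported input type {type(data).__name__}")

    bp = _burst_params(cfg)
    emap = table.electrode_map
    by = table.by_electrode()
    denom = table.unmasked_duration
    firing_rates = {eid: t.size / denom for eid, t in by.items()}
    bundle.results["firing"] = {
        "n_spikes": int(len(table)),
        "rate_by_electrode_hz": firing_rates,
        "median_rate_hz": median_firing_rate(table),
    }

    active = stage("active", active_electrodes, table, bp)
    bursts, thresholds = stage("bursts", detect_bursts_table, table, bp)
    bundle.results["bursts"] = {
        "n_bursts": len(bursts),
        "isi_threshold_s_by_electrode": thresholds,
        "n_active_electrodes": len(active),
        "active_electrodes": sorted(active),
    }

    nbs = []
    if bursts and active:
        nbs = stage("network_bursts", detect_network_bursts, bursts, active, bp, emap)
    bundle.results["network_bursts"] = {
        "n_network_bursts": len(nbs),
        "bursts": [nb.to_record() for nb in nbs],
    }
    if nbs:
        bundle.results["propagation"] = stage(
            "propagation", propagation_summary, nbs, bursts, table
        )

    rates = stage("rates", instantaneous_firing_rate, table, cfg.rate_bin_s, "network")
    ci = coherence_index(rates)
    bundle.results["dynamics"] = {
        "coherence_index": None if np.isnan(ci) else float(ci),
        "rate_bin_s": cfg.rate_bin_s,
    }

    binned = stage("bin", bin_trains, table, cfg.correlation_bin_s)
    summary = stage("xcorr", correlation_matrices, binned, emap, cfg.max_lag_bins)
    graph = stage("graph", build_graph, summary, cfg.edge_threshold, firing_rates, emap)
    # metrics may run on the thresholded graph (matching the plotted ones) or
    # on the full weighted graph
    metric_graph = graph if cfg.graph_on_thresholded else build_graph(
        summary, 0.0, firing_rates, emap
    )
    comm, q = stage(
        "louvain", louvain_modularity, metric_graph, cfg.louvain_gamma,
        cfg.louvain_restarts, cfg.seed,
    )
    pr = stage("pagerank", pagerank, metric_graph) if metric_graph.number_of_nodes() else {}

    def _mat(m):
        return [[None if not np.isfinite(v) else float(v) for v in row] for row in m]

    bundle.results["connectivity"] = {
        "electrode_ids": summary.electrode_ids,
        "electrode_matrix": _mat(summary.electrode_matrix),
        "node_order": list(summary.node_order),
        "node_matrix": _mat(summary.node_matrix),
    }
    bundle.results["graph"] = {
        "n_edges": graph.number_of_edges(),
        "modularity": None if np.isnan(q) else float(q),
        "n_communities": len(set(comm.values())),
        "communities": comm,
        "pagerank": pr,
    }

    if stim_times.size:
        psth = stage(
            "psth", compute_psth, table, stim_times,
            cfg.psth_window_s, cfg.psth_bin_s, emap,
        )
        bundle.results["psth"] = psth.to_dict()

    return bundle
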