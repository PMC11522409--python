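"""Analysis configuration: every tunable of the pipeline in one flat record.

Defaults are the values used for the embryonic cortical–hippocampal
recordings analysed by this pipeline: 4th-order 300–3000 Hz Butterworth
band-pass with 50 Hz mains notch (zero-phase), PTSD threshold 9 noise SDs
(7.5 for the lower-SNR adult cultures), 1 ms peak lifetime, 1.6 ms
refractory, logISI bursts of >= 4 spikes with ISI threshold capped at
100 ms, network bursts requiring >= 10% of active electrodes,
50 ms correlation bins with a 10-bin (500 ms) maximum lag, 0.1 edge
threshold, SALPA + 15 ms post-stimulus blanking, 20 ms PSTH bins over
300 ms, and the 5 µm particle-diameter cut at 2803/2046 µm per pixel.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import asdict, dataclass, field, fields

import yaml

from .types import ConfigError


@dataclass
class AnalysisConfig:
    # --- filtering ---
    filter_order: int = 4
    low_cut_hz: float = 300.0
    high_cut_hz: float = 3000.0
    notch_freq_hz: float = 50.0
    notch_quality: float = 30.0
    zero_phase: bool = True
    # --- spike detection (PTSD) ---
    threshold_multiplier: float = 9.0       # 7.5 for adult cultures
    peak_lifetime_s: float = 0.001
    refractory_s: float = 0.0016
    noise_sd_method: str = "mad"            # "mad" | "global_sd"
    # --- burst / network-burst detection ---
    min_spikes_per_burst: int = 4
    max_isi_s: float = 0.100
    isi_bins_per_decade: int = 10
    isi_smoothing_window: int = 3
    void_threshold: float = 0.7
    active_rate_min_hz: float = 0.1
    network_burst_fraction: float = 0.10
    # --- dynamics ---
    rate_bin_s: float = 0.050
    # --- connectivity / graph ---
    correlation_bin_s: float = 0.050
    max_lag_bins: int = 10
    edge_threshold: float = 0.1
    louvain_restarts: int = 100
    louvain_gamma: float = 1.0
    graph_on_thresholded: bool = True
    # --- stimulation ---
    salpa_poly_order: int = 3
    salpa_fit_halfwidth: int = 75           # samples (3 ms at 25 kHz)
    salpa_epoch_s: float = 0.050
    blank_after_s: float = 0.015
    psth_bin_s: float = 0.020
    psth_window_s: float = 0.300
    # --- particle quantification ---
    particle_min_diameter_um: float = 5.0
    um_per_px: float = 2803.0 / 2046.0
    # --- misc ---
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        positive = (
            "low_cut_hz", "high_cut_hz", "notch_freq_hz", "notch_quality",
            "threshold_multiplier", "peak_lifetime_s", "refractory_s",
            "max_isi_s", "rate_bin_s", "correlation_bin_s", "blank_after_s",
            "psth_bin_s", "psth_window_s", "particle_min_diameter_um",
            "um_per_px", "salpa_epoch_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.low_cut_hz >= self.high_cut_hz:
            raise ConfigError("low_cut_hz must be below high_cut_hz")
        if not 0 < self.network_burst_fraction <= 1:
            raise ConfigError("network_burst_fraction must be in (0, 1]")
        if not 0 < self.void_threshold < 1:
            raise ConfigError("void_threshold must be in (0, 1)")
        if self.min_spikes_per_burst < 2:
            raise ConfigError("min_spikes_per_burst must be >= 2")
        if self.refractory_s < self.peak_lifetime_s:
            raise ConfigError("refractory_s must be >= peak_lifetime_s")
        if self.noise_sd_method not in ("mad", "global_sd"):
            raise ConfigError(f"unknown noise_sd_method {self.noise_sd_method!r}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AnalysisConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(io.StringIO(str(source)))
        if d is None:
            d = {}
        if "analysis" in d and isinstance(d["analysis"], dict):
            d = d["analysis"]
        return cls.from_dict(d)

    def content_hash(self) -> str:
        """Stable hash of the full parameter set, for output provenance."""
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
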