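"""Signal conditioning: zero-phase band-pass + mains notch, SALPA artifact
suppression and post-stimulus blanking.

Band edges (300–3000 Hz, 4th-order Butterworth) are the single-pass −3 dB
design points; forward–backward application squares the magnitude response and
cancels the group delay.  The notch is a second-order IIR at 50 Hz with
quality factor 30 (narrow enough to leave the pass band untouched).

SALPA follows the local-polynomial-approximation idea: within the
post-stimulus epoch a sliding cubic estimate of the slow artifact is formed
(Savitzky–Golay, window 2*fit_halfwidth+1) and subtracted; subtraction stops
once the estimated artifact stays inside the noise band for a full fit window
("fit-and-test").  Samples pegged at the amplifier rails are interpolated
before fitting and masked afterwards.  The paper-style usage is SALPA followed
by hard blanking of the first 15 ms after each stimulus.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .types import ConfigError, RawRecording, SpikeTable
from dataclasses import dataclass, field


@dataclass
class FilterSpec:
    order: int = 4
    low_cut: float = 300.0
    high_cut: float = 3000.0
    notch_freq: float = 50.0
    notch_quality: float = 30.0
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not 0 < self.low_cut < self.high_cut:
            raise ConfigError("need 0 < low_cut < high_cut")
        if self.high_cut >= nyq:
            raise ConfigError(
                f"high_cut {self.high_cut} Hz must be below Nyquist {nyq} Hz"
            )


@dataclass
class SalpaSpec:
    poly_order: int = 3
    fit_halfwidth: int = 75        # samples; 3 ms at 25 kHz
    epoch: float = 0.050           # s of post-stimulus data eligible for subtraction
    blank_after: float = 0.015     # s; hard blank applied separately
    noise_band: float | None = None  # µV; None = subtract over the whole epoch
    rail: float | None = None        # µV; |x| >= rail flags pegged samples

    def validate(self) -> None:
        if 2 * self.fit_halfwidth + 1 < self.poly_order + 2:
            raise ConfigError("SALPA fit window must span >= poly_order + 2 samples")
        if self.epoch <= 0 or self.blank_after <= 0:
            raise ConfigError("epoch and blank_after must be > 0")


def bandpass_notch_filter(recording: RawRecording, spec: FilterSpec | None = None) -> RawRecording:
    """Zero-phase 4th-order Butterworth band-pass then 50 Hz notch, per channel."""
    spec = spec or FilterSpec()
    spec.validate(recording.sampling_rate)
    fs = recording.sampling_rate
    sos = sps.butter(
        spec.order, [spec.low_cut, spec.high_cut], btype="bandpass", fs=fs, output="sos"
    )
    b_n, a_n = sps.iirnotch(spec.notch_freq, spec.notch_quality, fs=fs)
    out = np.empty_like(recording.samples, dtype=np.float64)
    for i in range(recording.n_channels):
        x = recording.samples[i].astype(np.float64)
        x = sps.sosfiltfilt(sos, x)
        x = sps.filtfilt(b_n, a_n, x)
        out[i] = x
    return RawRecording(
        out.astype(recording.samples.dtype),
        fs,
        recording.electrode_map,
        recording.stimulation_times,
        dict(recording.metadata),
        list(recording.masked_intervals),
    )


def salpa_subtract(
    recording: RawRecording,
    stim_times=None,
    spec: SalpaSpec | None = None,
) -> RawRecording:
    """Subtract the local cubic artifact estimate after each stimulus.

    Only samples inside ``[t_stim, t_stim + epoch)`` are ever modified; with a
    ``noise_band``, subtraction additionally stops at the first point where the
    artifact estimate stays inside the band for a full fit window.
    """
    spec = spec or SalpaSpec()
    spec.validate()
    if stim_times is None:
        stim_times = recording.stimulation_times
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        return recording
    if stim_times.min() < 0 or stim_times.max() > recording.duration:
        raise ConfigError("stim_times must lie within the recording")

    fs = recording.sampling_rate
    win = 2 * spec.fit_halfwidth + 1
    n_epoch = int(round(spec.epoch * fs))
    out = recording.samples.astype(np.float64).copy()
    masked = list(recording.masked_intervals)

    for ch in range(recording.n_channels):
        for ts in stim_times:
            s0 = int(round(ts * fs))
            s1 = min(s0 + n_epoch, recording.n_samples)
            if s1 - s0 < win:
                s1 = min(s0 + win, recording.n_samples)
            seg = out[ch, s0:s1].copy()
            if seg.size < win:
                continue
            pegged = (
                np.abs(seg) >= spec.rail if spec.rail is not None
                else np.zeros(seg.size, dtype=bool)
            )
            if pegged.any() and not pegged.all():
                good = np.flatnonzero(~pegged)
                seg[pegged] = np.interp(np.flatnonzero(pegged), good, seg[good])
            est = sps.savgol_filter(seg, win, spec.poly_order, mode="interp")
            if spec.noise_band is not None:
                inside = np.abs(est) <= spec.noise_band
                # first index from which the estimate stays in-band a full window
                run = 0
                stop = seg.size
                for j, ok in enumerate(inside):
                    run = run + 1 if ok else 0
                    if run >= win:
                        stop = j - win + 1
                        break
                est[stop:] = 0.0
            out[ch, s0:s1] -= est
            if pegged.any():
                out[ch, s0:s1][pegged] = 0.0
                for j0, j1 in _runs(pegged):
                    masked.append(((s0 + j0) / fs, (s0 + j1) / fs))

    return RawRecording(
        out.astype(recording.samples.dtype),
        fs,
        recording.electrode_map,
        recording.stimulation_times,
        dict(recording.metadata),
        masked,
    )


def _runs(flags: np.ndarray):
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[splits + 1]])
    ends = np.concatenate([idx[splits], [idx[-1]]]) + 1
    yield from zip(starts, ends)


def blank_after_stimulus(data, stim_times=None, blank: float = 0.015):
    """Remove the first ``blank`` seconds after each stimulus.

    For a :class:`RawRecording` the samples in ``[t, t + blank)`` are zeroed;
    for a :class:`SpikeTable` the spikes are dropped.  In both cases the
    interval is recorded in ``masked_intervals`` so downstream rate
    denominators exclude it.
    """
    if blank <= 0:
        raise ConfigError("blank must be > 0")
    if stim_times is None and isinstance(data, RawRecording):
        stim_times = data.stimulation_times
    stim_times = np.asarray(stim_times if stim_times is not None else [], dtype=float)
    if stim_times.size == 0:
        return data
    intervals = [(float(t), float(t) + blank) for t in stim_times]

    if isinstance(data, RawRecording):
        out = data.samples.copy()
        fs = data.sampling_rate
        for t0, t1 in intervals:
            s0 = int(np.ceil(t0 * fs - 1e-9))
            s1 = min(int(np.ceil(t1 * fs - 1e-9)), data.n_samples)
            out[:, s0:s1] = 0.0
        return RawRecording(
            out, fs, data.electrode_map, data.stimulation_times,
            dict(data.metadata), list(data.masked_intervals) + intervals,
        )
    if isinstance(data, SpikeTable):
        t = data.frame["spike_time_s"].to_numpy()
        keep = np.ones(t.size, dtype=bool)
        for t0, t1 in intervals:
            keep &= ~((t >= t0) & (t < t1))
        return SpikeTable(
            data.frame[keep],
            data.duration,
            data.electrode_map,
            dict(data.metadata),
            list(data.masked_intervals) + intervals,
        )
    raise TypeError(f"cannot blank object of type {type(data).__name__}")
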