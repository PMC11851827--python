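"""Preprocessing: segmentation, band-pass/notch filtering, demeaning,
peak-to-peak trial rejection and occipitotemporal cluster averaging.

Conventions: t = 0 at stimulus onset, times in ms, amplitudes in μV,
0-based sample indices, windows closed on both ends.  All filters are
zero-phase (forward–backward), so symmetric deflections keep their
latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal as sig

from .containers import ContinuousRecording, EpochSet, RejectionLog

#: Default occipitotemporal cluster averaged into the virtual analysis channel.
DEFAULT_CLUSTER = ("P7", "P8", "PO7", "PO8", "O1", "O2", "P5", "P6")


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass plus notch filtering parameters.

    The band-pass is a zero-phase 4th-order Butterworth (applied forward
    and backward).  Notches are zero-phase narrow IIR band-stops
    (``notch_bandwidth`` Hz wide) by default; ``notch_method='dft'``
    instead subtracts the least-squares sinusoid fit at each notch
    frequency over the whole epoch, which removes a stationary line
    component exactly.
    """

    band: tuple[float, float] = (3.0, 45.0)
    notches: tuple[float, ...] = (60.0, 120.0)
    order: int = 4
    zero_phase: bool = True
    notch_method: str = "iir"  # 'iir' | 'dft'
    notch_bandwidth: float = 2.0

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not (0 < low < high < fs / 2):
            raise ValueError(f"band {self.band} must satisfy 0 < low < high < fs/2 = {fs / 2:g}")
        for f0 in self.notches:
            if not (0 < f0 < fs / 2):
                raise ValueError(f"notch {f0:g} Hz outside (0, {fs / 2:g}) Hz")
        if self.notch_method not in ("iir", "dft"):
            raise ValueError(f"unknown notch method {self.notch_method!r}")


def _bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    return sig.butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")


def _apply_dft_notch(x: np.ndarray, f0: float, fs: float) -> np.ndarray:
    """Subtract the least-squares sine+cosine fit at f0 along the last axis."""
    n = x.shape[-1]
    t = np.arange(n) / fs
    c = np.cos(2 * np.pi * f0 * t)
    s = np.sin(2 * np.pi * f0 * t)
    # project each row on the (c, s) pair
    cc, ss = c @ c, s @ s
    a = (x @ c) / cc
    b = (x @ s) / ss
    return x - a[..., None] * c - b[..., None] * s


def apply_filters(epochs: EpochSet, spec: FilterSpec = FilterSpec()) -> EpochSet:
    """Band-pass (3–45 Hz default) + 60/120 Hz notches, per trial/channel."""
    spec.validate(epochs.fs)
    x = np.asarray(epochs.voltages, dtype=float)
    sos = _bandpass_sos(spec, epochs.fs)
    if spec.zero_phase:
        y = sig.sosfiltfilt(sos, x, axis=-1)
    else:
        y = sig.sosfilt(sos, x, axis=-1)
    for f0 in spec.notches:
        if spec.notch_method == "dft":
            y = _apply_dft_notch(y, f0, epochs.fs)
        else:
            b, a = sig.iirnotch(f0, f0 / spec.notch_bandwidth, fs=epochs.fs)
            y = sig.filtfilt(b, a, y, axis=-1) if spec.zero_phase else sig.lfilter(b, a, y, axis=-1)
    out = epochs.copy()
    out.voltages = y
    return out


def filter_attenuation_db(spec: FilterSpec, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Magnitude response (dB) of the composite filter chain at ``freqs``.

    Zero-phase application squares each stage's magnitude; the DFT notch
    has no transfer function and is excluded (it nulls its line exactly).
    """
    freqs = np.asarray(freqs, dtype=float)
    _, h = sig.sosfreqz(_bandpass_sos(spec, fs), worN=2 * np.pi * freqs / fs)
    mag = np.abs(h)
    if spec.notch_method == "iir":
        for f0 in spec.notches:
            b, a = sig.iirnotch(f0, f0 / spec.notch_bandwidth, fs=fs)
            _, hn = sig.freqz(b, a, worN=2 * np.pi * freqs / fs)
            mag = mag * np.abs(hn)
    if spec.zero_phase:
        mag = mag**2
    with np.errstate(divide="ignore"):
        return 20 * np.log10(mag)


def segment_continuous(recording: ContinuousRecording, window: tuple[float, float]) -> EpochSet:
    """Cut stimulus-locked epochs from a continuous recording.

    ``window`` is in seconds relative to each event onset (e.g. (−0.5,
    1.5)); each epoch gets ``span × fs`` samples with t = 0 at the onset.
    """
    fs = recording.fs
    start_off = int(round(window[0] * fs))
    n_samp = int(round((window[1] - window[0]) * fs))
    n_total = recording.data.shape[1]
    bad = [
        int(ev)
        for ev in recording.event_samples
        if ev + start_off < 0 or ev + start_off + n_samp > n_total
    ]
    if bad:
        raise ValueError(
            f"events too close to the recording edge for window {window}: onsets {bad}"
        )
    trials = np.stack(
        [
            recording.data[:, ev + start_off : ev + start_off + n_samp]
            for ev in recording.event_samples
        ]
    )
    times = window[0] * 1000.0 + np.arange(n_samp) * 1000.0 / fs
    if recording.event_meta is not None:
        meta = recording.event_meta.copy()
    else:
        import pandas as pd

        meta = pd.DataFrame(
            {
                "participant_id": "unknown",
                "trial_index": np.arange(len(recording.event_samples)),
                "emotion": "unknown",
                "mouth": "unknown",
                "onset_sample": recording.event_samples,
            }
        )
    return EpochSet(trials, times, list(recording.channels), fs, meta)


def demean(epochs: EpochSet) -> EpochSet:
    """Remove each trial's per-channel mean over the full epoch."""
    if epochs.n_samples == 0:
        raise ValueError("cannot demean zero-length epochs")
    out = epochs.copy()
    out.voltages = out.voltages - out.voltages.mean(axis=-1, keepdims=True)
    return out


def baseline_correct(epochs: EpochSet, window_ms: tuple[float, float]) -> EpochSet:
    """Subtract the mean over a baseline window (ms) instead of the full epoch."""
    mask = (epochs.times >= window_ms[0]) & (epochs.times <= window_ms[1])
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} ms covers no samples")
    out = epochs.copy()
    out.voltages = out.voltages - out.voltages[..., mask].mean(axis=-1, keepdims=True)
    return out


def reject_trials(
    epochs: EpochSet, peak_to_peak_threshold: float = 150.0
) -> tuple[EpochSet, RejectionLog]:
    """Drop trials whose peak-to-peak range on any channel exceeds the
    threshold (μV).  Surviving trials keep their order; the log records
    the dropped ``trial_index`` values and is emitted even when empty.
    """
    if peak_to_peak_threshold <= 0:
        raise ValueError("threshold must be positive")
    ptp = epochs.voltages.max(axis=-1) - epochs.voltages.min(axis=-1)
    bad = (ptp > peak_to_peak_threshold).any(axis=1)
    if bad.all():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed the {peak_to_peak_threshold:g} μV "
            "peak-to-peak threshold; review the threshold"
        )
    keep = np.flatnonzero(~bad)
    log = RejectionLog(
        participant_id=str(epochs.metadata["participant_id"].iloc[0]),
        rejected_trial_indices=[int(i) for i in epochs.metadata["trial_index"].iloc[np.flatnonzero(bad)]],
        criterion="max peak-to-peak over channels",
        threshold=float(peak_to_peak_threshold),
    )
    return epochs.select_trials(keep), log


def cluster_average(epochs: EpochSet, channel_subset: tuple[str, ...] | list[str] | None = None) -> EpochSet:
    """Average a channel subset into one virtual channel ('cluster').

    Defaults to the intersection-checked occipitotemporal cluster; raises
    for any label not present in the data.
    """
    subset = list(channel_subset) if channel_subset is not None else list(DEFAULT_CLUSTER)
    if not subset:
        raise ValueError("channel subset must be non-empty")
    missing = [ch for ch in subset if ch not in epochs.channels]
    if missing:
        raise KeyError(f"unknown channel label(s): {missing}")
    idx = [epochs.channels.index(ch) for ch in subset]
    mean = epochs.voltages[:, idx, :].mean(axis=1, keepdims=True)
    out = epochs.copy()
    out.voltages = mean
    out.channels = ["cluster"]
    return out


@dataclass
class PreprocessSettings:
    """Bundle of preprocessing choices used by the pipeline stage."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    ptp_threshold: float = 150.0
    cluster: tuple[str, ...] = DEFAULT_CLUSTER
    demean_mode: str = "epoch"  # 'epoch' | 'baseline' | 'none'
    baseline_ms: tuple[float, float] = (-200.0, 0.0)


def preprocess_participant(
    epochs: EpochSet, settings: PreprocessSettings = PreprocessSettings()
) -> tuple[EpochSet, RejectionLog]:
    """Filter → demean → reject → cluster-average one participant."""
    out = apply_filters(epochs, settings.filter_spec)
    if settings.demean_mode == "epoch":
        out = demean(out)
    elif settings.demean_mode == "baseline":
        out = baseline_correct(out, settings.baseline_ms)
    out, log = reject_trials(out, settings.ptp_threshold)
    # fall back to all recorded channels when none of the named cluster exists
    cluster = [ch for ch in settings.cluster if ch in out.channels] or list(out.channels)
    out = cluster_average(out, cluster)
    return out, log
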