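"""Core in-memory containers exchanged between pipeline stages.

All voltages are in microvolts (μV), all times in milliseconds relative to
stimulus onset, and sampling rates in Hz.  The unit of exchange between
stages is :class:`EpochSet`: a ``trials × channels × samples`` voltage
array together with its time vector, channel labels and a per-trial
metadata table (participant, emotion, mouth display, onset sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Metadata columns every EpochSet carries, in canonical order.
META_COLUMNS = ("participant_id", "trial_index", "emotion", "mouth", "onset_sample")

EMOTIONS = ("fearful", "happy", "neutral")
MOUTHS = ("open", "closed")


@dataclass
class EpochSet:
    """Epoched multichannel EEG: ``voltages[trial, channel, sample]`` in μV.

    Parameters
    ----------
    voltages
        Array of shape ``(n_trials, n_channels, n_samples)``.
    times
        Time vector in ms relative to stimulus onset, length ``n_samples``.
    channels
        Channel labels, length ``n_channels``.
    fs
        Sampling rate in Hz.
    metadata
        One row per trial, columns :data:`META_COLUMNS`; row order matches
        the first axis of ``voltages``.
    """

    voltages: np.ndarray
    times: np.ndarray
    channels: list[str]
    fs: float
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages)
        self.times = np.asarray(self.times, dtype=float)
        if self.voltages.ndim != 3:
            raise ValueError("voltages must be trials × channels × samples")
        n_trials, n_channels, n_samples = self.voltages.shape
        if len(self.times) != n_samples:
            raise ValueError("time vector length does not match sample axis")
        if len(self.channels) != n_channels:
            raise ValueError("channel labels do not match channel axis")
        if len(self.metadata) != n_trials:
            raise ValueError("metadata rows do not match trial axis")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[1]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[2]

    @property
    def participant_id(self) -> str:
        ids = self.metadata["participant_id"].unique()
        if len(ids) != 1:
            raise ValueError("EpochSet holds more than one participant")
        return str(ids[0])

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.voltages.copy(),
            self.times.copy(),
            list(self.channels),
            self.fs,
            self.metadata.copy(),
        )

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        """Subset trials by positional index, preserving order."""
        index = np.asarray(index)
        return replace(
            self,
            voltages=self.voltages[index],
            metadata=self.metadata.iloc[index].reset_index(drop=True),
        )

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG plus stimulus event onsets.

    ``data`` is ``channels × samples`` in μV; ``event_samples`` holds the
    onset sample of each stimulus; ``event_meta`` (optional) carries one
    metadata row per event in the same order.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    event_samples: np.ndarray
    event_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.event_samples = np.asarray(self.event_samples, dtype=int)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if self.event_meta is not None and len(self.event_meta) != len(self.event_samples):
            raise ValueError("event metadata rows do not match events")


@dataclass
class ConditionERP:
    """Per-participant averaged waveform for one condition level."""

    participant_id: str
    condition: tuple[str, ...] | str
    waveform: np.ndarray
    times: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.waveform.shape != self.times.shape:
            raise ValueError("waveform and time vector differ in length")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


@dataclass
class GrandERP:
    """Across-participant (unweighted) average of condition ERPs."""

    condition: tuple[str, ...] | str
    waveform: np.ndarray
    times: np.ndarray
    n_participants: int


@dataclass
class RejectionLog:
    """Record of automatically rejected trials for one participant."""

    participant_id: str
    rejected_trial_indices: list[int]
    criterion: str
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "trial_index": list(self.rejected_trial_indices),
                "criterion": self.criterion,
                "threshold_uv": self.threshold,
            },
            index=range(len(self.rejected_trial_indices)),
        )


@dataclass
class PeakMeasure:
    """Windowed extremum of a waveform: amplitude (μV) and latency (ms)."""

    component: str
    amplitude: float
    latency: float
    window: tuple[float, float] = field(default=(np.nan, np.nan))
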