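"""Synthetic factorial ERP datasets with known ground truth.

The generator emulates a face-viewing study with a 3 (emotion: fearful,
happy, neutral) × 2 (mouth display: open with exposed teeth, closed)
within-participant design: 42 participants, 48 trials per cell (288
trials), 2-s stimulus-locked epochs from −0.5 s to +1.5 s sampled at
500 Hz over an occipitotemporal channel cluster.

Each trial is a deterministic condition template — a sum of
Gaussian-windowed deflections for the P100 (positive, ~100 ms) and N170
(negative, ~170 ms) components — plus white noise, 1/f ("pink") noise and
a per-participant amplitude offset.  Condition effects are injected as

* an extra (more negative) N170 amplitude for open-mouth trials,
* a signed latency shift of every component for fearful trials, and
* an optional P100 amplitude bump for fearful × open-mouth trials.

Because the templates are closed-form, every downstream estimate has an
exact ground truth at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EMOTIONS, META_COLUMNS, MOUTHS, EpochSet

#: Default occipitotemporal cluster (10–20 labels).
DEFAULT_CLUSTER = ("P7", "P8", "PO7", "PO8", "O1", "O2", "P5", "P6")


@dataclass(frozen=True)
class ComponentSpec:
    """One Gaussian-windowed ERP deflection.

    ``amplitude`` is a positive magnitude; the signed peak is
    ``polarity * amplitude`` at ``peak_latency`` (ms).  ``width`` is the
    Gaussian standard deviation in ms.
    """

    name: str
    polarity: int
    peak_latency: float
    amplitude: float
    width: float

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be a non-negative magnitude")
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth condition effects injected into the templates.

    n170_open_mouth_amp_delta
        Extra N170 amplitude magnitude (μV, i.e. a more negative peak) on
        open-mouth trials.
    fearful_latency_shift
        Signed shift (ms) of every component's latency on fearful trials;
        negative = earlier.  Keep it an integer multiple of the sample
        period for exact-recovery checks.
    p100_interaction_delta
        Extra P100 amplitude (μV) on fearful × open-mouth trials only
        (a simple interaction pattern; it also induces small main effects).
    """

    n170_open_mouth_amp_delta: float = 0.4
    fearful_latency_shift: float = -2.0
    p100_interaction_delta: float = 0.25


def default_components() -> list[ComponentSpec]:
    """P100–N170–P2 sequence typical of posterior visual ERPs.

    The P2 matters for the latency permutation test: it pulls the
    waveform up through the −3…+1 μV refinement band before the 200-ms
    segment end, so both edges of the refined segment move with the
    waveform and a pure latency shift is recovered exactly.
    """
    return [
        ComponentSpec("P100", +1, 100.0, 4.0, 12.0),
        ComponentSpec("N170", -1, 170.0, 6.0, 15.0),
        ComponentSpec("P2", +1, 230.0, 4.0, 25.0),
    ]


@dataclass
class SimConfig:
    """Study-design constants and noise levels for one simulated dataset."""

    n_participants: int = 42
    trials_per_cell: int = 48
    fs: float = 500.0
    epoch_window: tuple[float, float] = (-0.5, 1.5)
    n_channels: int = len(DEFAULT_CLUSTER)
    components: list[ComponentSpec] = field(default_factory=default_components)
    effects: EffectSpec = field(default_factory=EffectSpec)
    noise_sd: float = 10.0
    pink_noise_scale: float = 5.0
    between_participant_sd: float = 2.0
    latency_jitter_sd: float = 0.0
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.trials_per_cell * len(EMOTIONS) * len(MOUTHS)

    @property
    def n_samples(self) -> int:
        span = self.epoch_window[1] - self.epoch_window[0]
        n = span * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch window span must be an integer number of samples")
        return int(round(n))

    @property
    def times(self) -> np.ndarray:
        """Epoch time vector in ms; t = 0 at stimulus onset."""
        return self.epoch_window[0] * 1000.0 + np.arange(self.n_samples) * 1000.0 / self.fs

    @property
    def onset_index(self) -> int:
        return int(round(-self.epoch_window[0] * self.fs))

    def channel_names(self) -> list[str]:
        if self.n_channels <= len(DEFAULT_CLUSTER):
            return list(DEFAULT_CLUSTER[: self.n_channels])
        extra = [f"CH{i}" for i in range(len(DEFAULT_CLUSTER), self.n_channels)]
        return list(DEFAULT_CLUSTER) + extra


def make_template(
    components: list[ComponentSpec],
    effects: EffectSpec,
    emotion: str,
    mouth: str,
    times: np.ndarray,
    amplitude_offset: float = 0.0,
    latency_jitter: float = 0.0,
) -> np.ndarray:
    """Noise-free condition template (μV) on the given time grid (ms).

    The template is the sum over components of
    ``polarity · amplitude · exp(−(t − latency)² / (2 width²))`` with the
    configured condition effects applied: all latencies shift by
    ``fearful_latency_shift`` when ``emotion == 'fearful'``; the N170
    amplitude grows by ``n170_open_mouth_amp_delta`` when
    ``mouth == 'open'``; the P100 amplitude grows by
    ``p100_interaction_delta`` for fearful open-mouth trials.

    ``amplitude_offset`` is added to every component magnitude (clipped at
    zero) and models between-participant amplitude differences;
    ``latency_jitter`` (ms) shifts all latencies and models trial-to-trial
    timing variability.
    """
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}")
    if mouth not in MOUTHS:
        raise ValueError(f"unknown mouth condition {mouth!r}")
    times = np.asarray(times, dtype=float)
    wave = np.zeros_like(times)
    shift = effects.fearful_latency_shift if emotion == "fearful" else 0.0
    for comp in components:
        amp = comp.amplitude + amplitude_offset
        if comp.name.upper() == "N170" and mouth == "open":
            amp += effects.n170_open_mouth_amp_delta
        if comp.name.upper() == "P100" and emotion == "fearful" and mouth == "open":
            amp += effects.p100_interaction_delta
        amp = max(amp, 0.0)
        latency = comp.peak_latency + shift + latency_jitter
        if not (times[0] <= latency <= times[-1]):
            raise ValueError(
                f"component {comp.name!r} peak latency {latency:g} ms lies outside "
                f"the time vector [{times[0]:g}, {times[-1]:g}] ms"
            )
        wave += comp.polarity * amp * np.exp(-0.5 * ((times - latency) / comp.width) ** 2)
    return wave


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """1/f-amplitude noise with unit per-sample variance (last axis = time).

    White noise is shaped in the frequency domain by ``1/sqrt(f)`` (DC
    removed) and the profile is normalised so each output sample has unit
    variance in expectation.
    """
    n = shape[-1]
    freqs = np.fft.fftfreq(n)
    profile = np.zeros(n)
    nonzero = freqs != 0
    profile[nonzero] = 1.0 / np.sqrt(np.abs(freqs[nonzero]))
    # E[sample variance] = mean(profile²) for unit-variance white input.
    profile /= np.sqrt(np.mean(profile**2))
    white = rng.standard_normal(shape)
    shaped = np.fft.ifft(np.fft.fft(white, axis=-1) * profile, axis=-1).real
    return shaped


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-participant stream derived from the master seed."""
    return np.random.default_rng([int(seed), int(index)])


def _balanced_metadata(participant_id: str, trials_per_cell: int, onset_index: int) -> pd.DataFrame:
    rows = []
    trial = 0
    for rep in range(trials_per_cell):
        for emotion in EMOTIONS:
            for mouth in MOUTHS:
                rows.append((participant_id, trial, emotion, mouth, onset_index))
                trial += 1
    return pd.DataFrame(rows, columns=list(META_COLUMNS))


def simulate_participant(config: SimConfig, index: int) -> EpochSet:
    """Simulate one participant's balanced epoch set (trial order shuffled)."""
    rng = _participant_rng(config.seed, index)
    pid = f"sub-{index + 1:02d}"
    times = config.times
    meta = _balanced_metadata(pid, config.trials_per_cell, config.onset_index)
    # Shuffle presentation order, then renumber trial_index sequentially.
    order = rng.permutation(len(meta))
    meta = meta.iloc[order].reset_index(drop=True)
    meta["trial_index"] = np.arange(len(meta))

    offset = rng.normal(0.0, config.between_participant_sd) if config.between_participant_sd else 0.0
    n_trials, n_ch, n_samp = len(meta), config.n_channels, config.n_samples
    volts = np.empty((n_trials, n_ch, n_samp))
    for i, row in meta.iterrows():
        jitter = (
            rng.normal(0.0, config.latency_jitter_sd) if config.latency_jitter_sd else 0.0
        )
        template = make_template(
            config.components, config.effects, row["emotion"], row["mouth"], times,
            amplitude_offset=offset, latency_jitter=jitter,
        )
        volts[i] = template  # same template on every cluster channel
    if config.noise_sd:
        volts += config.noise_sd * rng.standard_normal(volts.shape)
    if config.pink_noise_scale:
        volts += config.pink_noise_scale * _pink_noise(rng, volts.shape)
    # Pass through float32 so on-disk round trips are bit-exact.
    volts = volts.astype(np.float32).astype(np.float64)
    return EpochSet(volts, times, config.channel_names(), config.fs, meta)


def simulate_dataset(config: SimConfig) -> list[EpochSet]:
    """Simulate all participants; identical config+seed ⇒ identical output."""
    if config.n_participants <= 0:
        raise ValueError("n_participants must be positive")
    if config.trials_per_cell <= 0:
        raise ValueError("trials_per_cell must be positive")
    return [simulate_participant(config, i) for i in range(config.n_participants)]


def condition_template(config: SimConfig, emotion: str, mouth: str) -> np.ndarray:
    """Noise-free template for one cell under the config's effects."""
    return make_template(config.components, config.effects, emotion, mouth, config.times)
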