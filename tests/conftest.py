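"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from erpface import preprocess as pp
from erpface.containers import EpochSet
from erpface.synth import EffectSpec, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """4 participants × 24 trials × 2 channels with modest noise."""
    return SimConfig(
        n_participants=4,
        trials_per_cell=4,
        n_channels=2,
        noise_sd=3.0,
        pink_noise_scale=1.0,
        between_participant_sd=1.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_clustered(small_dataset):
    return [pp.preprocess_participant(d)[0] for d in small_dataset]


@pytest.fixture(scope="session")
def noiseless_config() -> SimConfig:
    """Deterministic dataset: trials equal their condition template."""
    return SimConfig(
        n_participants=3,
        trials_per_cell=2,
        n_channels=2,
        noise_sd=0.0,
        pink_noise_scale=0.0,
        between_participant_sd=0.0,
        effects=EffectSpec(
            n170_open_mouth_amp_delta=1.0,
            fearful_latency_shift=-2.0,
            p100_interaction_delta=0.0,
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return simulate_dataset(noiseless_config)


def single_trial_epochs(wave: np.ndarray, fs: float = 500.0, t0_ms: float = -500.0) -> EpochSet:
    """Wrap one waveform as a single-trial, single-channel EpochSet."""
    wave = np.asarray(wave, dtype=float)
    times = t0_ms + np.arange(wave.size) * 1000.0 / fs
    meta = pd.DataFrame(
        {
            "participant_id": ["s01"],
            "trial_index": [0],
            "emotion": ["neutral"],
            "mouth": ["closed"],
            "onset_sample": [int(round(-t0_ms * fs / 1000.0))],
        }
    )
    return EpochSet(wave[None, None, :], times, ["cluster"], fs, meta)
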