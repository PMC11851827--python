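"""Segmentation, filtering, demeaning, rejection and cluster averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from conftest import single_trial_epochs
from erpface.containers import ContinuousRecording, EpochSet
from erpface.preprocess import (
    FilterSpec,
    apply_filters,
    cluster_average,
    demean,
    filter_attenuation_db,
    reject_trials,
    segment_continuous,
)

FS = 500.0


def _recording(n_events=12, gap=1200, n_samples=20_000):
    rng = np.random.default_rng(0)
    data = rng.normal(size=(2, n_samples))
    events = 400 + gap * np.arange(n_events)
    return ContinuousRecording(data, FS, ["P7", "P8"], events)


class TestSegmentation:
    def test_one_epoch_per_event_with_expected_samples(self):
        rec = _recording()
        epochs = segment_continuous(rec, (-0.5, 1.5))
        assert epochs.n_trials == 12
        assert epochs.n_samples == 1000  # 2 s × 500 Hz
        assert epochs.times[0] == -500.0
        assert 0.0 in epochs.times

    def test_epoch_content_matches_recording(self):
        rec = _recording()
        epochs = segment_continuous(rec, (-0.1, 0.1))
        ev = rec.event_samples[3]
        np.testing.assert_array_equal(
            epochs.voltages[3, 0], rec.data[0, ev - 50 : ev + 50]
        )

    def test_event_too_close_to_edge_errors(self):
        rec = ContinuousRecording(np.zeros((1, 5000)), FS, ["P7"], [10, 2000])
        with pytest.raises(ValueError, match="10"):
            segment_continuous(rec, (-0.5, 1.5))


class TestFilters:
    def test_magnitude_response_contracts(self):
        """≥40 dB at the 60 Hz notch, ~unity at 10 Hz, for the zero-phase chain."""
        db = filter_attenuation_db(FilterSpec(), FS, np.array([10.0, 60.0, 120.0]))
        assert db[1] <= -40.0 and db[2] <= -40.0
        assert 20 * np.log10(0.9) <= db[0] <= 20 * np.log10(1.1)

    @pytest.mark.parametrize("method", ["iir", "dft"])
    def test_60hz_sinusoid_attenuated(self, method):
        t = np.arange(1000) / FS
        epochs = single_trial_epochs(np.sin(2 * np.pi * 60.0 * t))
        out = apply_filters(epochs, FilterSpec(notch_method=method)).voltages[0, 0]
        mid = slice(250, 750)  # steady-state portion
        ratio = np.sqrt(np.mean(out[mid] ** 2)) / np.sqrt(0.5)
        assert ratio < 10 ** (-40 / 20)

    def test_10hz_passband_gain_near_unity(self):
        t = np.arange(1000) / FS
        epochs = single_trial_epochs(np.sin(2 * np.pi * 10.0 * t))
        out = apply_filters(epochs).voltages[0, 0]
        mid = slice(250, 750)
        ratio = np.sqrt(np.mean(out[mid] ** 2)) / np.sqrt(0.5)
        assert 0.9 <= ratio <= 1.1

    def test_dc_rejected(self):
        epochs = single_trial_epochs(np.full(1000, 7.0))
        out = apply_filters(epochs).voltages
        assert np.abs(out).max() < 1e-3 * 7.0

    def test_zero_phase_keeps_symmetric_peak_latency(self):
        times = -500.0 + 2.0 * np.arange(1000)
        wave = -6.0 * np.exp(-0.5 * ((times - 170.0) / 15.0) ** 2)
        out = apply_filters(single_trial_epochs(wave)).voltages[0, 0]
        assert np.argmin(out) == np.argmin(wave)

    def test_band_outside_nyquist_errors(self):
        epochs = single_trial_epochs(np.zeros(1000))
        with pytest.raises(ValueError):
            apply_filters(epochs, FilterSpec(band=(3.0, 300.0)))

    def test_filtering_commutes_with_trial_subsetting(self, small_dataset):
        epochs = small_dataset[0]
        sub = np.array([1, 3, 5])
        a = apply_filters(demean(epochs)).select_trials(sub)
        b = apply_filters(demean(epochs.select_trials(sub)))
        np.testing.assert_allclose(a.voltages, b.voltages, atol=1e-10)
        assert a.metadata.equals(b.metadata)


class TestDemean:
    def test_removes_offset_and_preserves_shape(self):
        epochs = single_trial_epochs(np.full(1000, 7.0))
        out = demean(epochs)
        assert out.voltages.shape == epochs.voltages.shape
        assert np.abs(out.voltages.mean(axis=-1)).max() < 1e-9

    def test_idempotent(self, small_dataset):
        once = demean(small_dataset[0])
        twice = demean(once)
        np.testing.assert_allclose(once.voltages, twice.voltages, atol=1e-12)

    def test_zero_length_epoch_errors(self):
        meta = pd.DataFrame(
            {"participant_id": ["s"], "trial_index": [0], "emotion": ["neutral"],
             "mouth": ["closed"], "onset_sample": [0]}
        )
        empty = EpochSet(np.empty((1, 1, 0)), np.empty(0), ["c"], FS, meta)
        with pytest.raises(ValueError):
            demean(empty)


class TestRejection:
    def test_clean_data_passes_untouched(self, small_dataset):
        epochs = small_dataset[0]
        kept, log = reject_trials(epochs, 150.0)
        assert kept.n_trials == epochs.n_trials
        assert log.rejected_trial_indices == []

    def test_injected_artifact_trial_is_the_one_rejected(self, small_dataset):
        epochs = small_dataset[0].copy()
        epochs.voltages[5, 0, 500:] += 500.0
        kept, log = reject_trials(epochs, 150.0)
        assert log.rejected_trial_indices == [int(epochs.metadata["trial_index"].iloc[5])]
        assert kept.n_trials == epochs.n_trials - 1
        # survivors keep their order
        expected = epochs.metadata.drop(index=5)["trial_index"].tolist()
        assert kept.metadata["trial_index"].tolist() == expected

    def test_all_rejected_raises_threshold_advice(self, small_dataset):
        with pytest.raises(ValueError, match="threshold"):
            reject_trials(small_dataset[0], 0.001)


class TestClusterAverage:
    def test_single_channel_identity(self, small_dataset):
        epochs = small_dataset[0]
        out = cluster_average(epochs, [epochs.channels[0]])
        np.testing.assert_array_equal(out.voltages[:, 0], epochs.voltages[:, 0])

    def test_opposite_channels_cancel(self):
        times = np.arange(100) * 2.0
        v = np.random.default_rng(1).normal(size=(1, 1, 100))
        meta = pd.DataFrame(
            {"participant_id": ["s"], "trial_index": [0], "emotion": ["neutral"],
             "mouth": ["closed"], "onset_sample": [0]}
        )
        epochs = EpochSet(np.concatenate([v, -v], axis=1), times, ["a", "b"], FS, meta)
        out = cluster_average(epochs, ["a", "b"])
        np.testing.assert_allclose(out.voltages, 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=20)
    @given(k=hst.integers(min_value=1, max_value=5))
    def test_identical_channels_unchanged(self, k):
        rng = np.random.default_rng(k)
        wave = rng.normal(size=100)
        v = np.tile(wave, (1, k, 1))
        meta = pd.DataFrame(
            {"participant_id": ["s"], "trial_index": [0], "emotion": ["neutral"],
             "mouth": ["closed"], "onset_sample": [0]}
        )
        epochs = EpochSet(v, np.arange(100) * 2.0, [f"c{i}" for i in range(k)], FS, meta)
        out = cluster_average(epochs, list(epochs.channels))
        np.testing.assert_allclose(out.voltages[0, 0], wave, atol=1e-12)

    def test_unknown_label_named_in_error(self, small_dataset):
        with pytest.raises(KeyError, match="Cz"):
            cluster_average(small_dataset[0], ["Cz"])
        with pytest.raises(ValueError):
            cluster_average(small_dataset[0], [])
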