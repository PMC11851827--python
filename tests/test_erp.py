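"""Condition/grand averaging, smoothing and windowed peak measures."""

import numpy as np
import pytest

from erpface.containers import ConditionERP
from erpface.erp import (
    condition_average,
    grand_average,
    measure_peak,
    peak_table,
    smooth_moving_average,
)
from erpface.preprocess import cluster_average
from erpface.synth import SimConfig, simulate_dataset

TIMES = -500.0 + 2.0 * np.arange(1000)


@pytest.fixture(scope="module")
def one_participant_288():
    cfg = SimConfig(n_participants=1, trials_per_cell=48, n_channels=1,
                    noise_sd=0.0, pink_noise_scale=0.0, seed=2)
    return cluster_average(simulate_dataset(cfg)[0], ["P7"])


class TestConditionAverage:
    def test_trial_counts_96_per_emotion_144_per_mouth(self, one_participant_288):
        by_emotion = condition_average(one_participant_288, "emotion")
        assert [e.n_trials for e in by_emotion] == [96, 96, 96]
        by_mouth = condition_average(one_participant_288, "mouth")
        assert [e.n_trials for e in by_mouth] == [144, 144]
        by_cell = condition_average(one_participant_288, "cell")
        assert [e.n_trials for e in by_cell] == [48] * 6

    def test_identical_trials_average_to_themselves(self, noiseless_dataset):
        epochs = cluster_average(noiseless_dataset[0], ["P7"])
        neutral_closed = epochs.select_trials(
            np.flatnonzero(
                (epochs.metadata["emotion"] == "neutral").to_numpy()
                & (epochs.metadata["mouth"] == "closed").to_numpy()
            )
        )
        erp = [
            e for e in condition_average(epochs, "cell") if e.condition == ("neutral", "closed")
        ][0]
        np.testing.assert_allclose(erp.waveform, neutral_closed.voltages[0, 0], atol=1e-5)

    def test_missing_level_named(self, one_participant_288):
        happy_only = one_participant_288.select_trials(
            np.flatnonzero((one_participant_288.metadata["emotion"] == "happy").to_numpy())
        )
        with pytest.raises(ValueError, match="fearful"):
            condition_average(happy_only, "emotion")


class TestGrandAverage:
    @staticmethod
    def _erp(pid, wave, cond=("neutral",)):
        return ConditionERP(pid, cond, wave, TIMES, 10)

    def test_single_participant_identity(self):
        wave = np.sin(TIMES / 50.0)
        g = grand_average([self._erp("s1", wave)])
        np.testing.assert_array_equal(g.waveform, wave)
        assert g.n_participants == 1

    def test_opposite_waveforms_cancel(self):
        wave = np.sin(TIMES / 50.0)
        g = grand_average([self._erp("s1", wave), self._erp("s2", -wave)])
        np.testing.assert_allclose(g.waveform, 0.0, atol=1e-12)

    def test_pooling_groups_counts_participants(self):
        erps = [self._erp(f"s{i}", np.zeros_like(TIMES)) for i in range(19 + 23)]
        assert grand_average(erps).n_participants == 42

    def test_mixed_conditions_or_grids_error(self):
        a = self._erp("s1", np.zeros_like(TIMES))
        b = ConditionERP("s2", ("happy",), np.zeros_like(TIMES), TIMES, 10)
        with pytest.raises(ValueError, match="condition"):
            grand_average([a, b])
        c = ConditionERP("s2", ("neutral",), np.zeros(500), TIMES[:500], 10)
        with pytest.raises(ValueError, match="time"):
            grand_average([a, c])

    def test_balanced_linearity_matches_pooled_trial_mean(self, small_clustered):
        """With balanced cells, grand(condition means) = mean over all trials."""
        erps = []
        for epochs in small_clustered:
            level = [e for e in condition_average(epochs, "emotion") if e.condition == ("happy",)]
            erps.append(level[0])
        g = grand_average(erps)
        pooled = np.mean(
            [
                epochs.voltages[
                    np.flatnonzero((epochs.metadata["emotion"] == "happy").to_numpy()), 0, :
                ].mean(axis=0)
                for epochs in small_clustered
            ],
            axis=0,
        )
        np.testing.assert_allclose(g.waveform, pooled, atol=1e-12)


class TestSmoothing:
    def test_constant_preserved(self):
        np.testing.assert_allclose(smooth_moving_average(np.full(50, 3.3)), np.full(50, 3.3), rtol=1e-14)

    def test_interior_impulse_spreads_to_fifths(self):
        x = np.zeros(21)
        x[10] = 1.0
        out = smooth_moving_average(x)
        np.testing.assert_allclose(out[8:13], 0.2)
        assert out[:8].max() == 0.0 and out[13:].max() == 0.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_moving_average(np.zeros(10), n_points=4)

    def test_white_noise_variance_reduced_fivefold(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20_000)
        out = smooth_moving_average(x)
        assert out[2:-2].var() == pytest.approx(1.0 / 5.0, rel=0.10)

    def test_gaussian_peak_shrinks_but_latency_holds(self):
        wave = -6.0 * np.exp(-0.5 * ((TIMES - 170.0) / 15.0) ** 2)
        out = smooth_moving_average(wave)
        assert out.min() >= wave.min()  # smoothing cannot deepen the trough
        assert TIMES[np.argmin(out)] == TIMES[np.argmin(wave)]


class TestMeasurePeak:
    def test_n170_template_recovered_exactly(self):
        wave = -3.0 * np.exp(-0.5 * ((TIMES - 170.0) / 15.0) ** 2)
        pk = measure_peak(wave, TIMES, "N170")
        assert pk.amplitude == pytest.approx(-3.0, abs=1e-12)
        assert pk.latency == 170.0

    def test_monotone_waveform_peaks_at_window_edge(self):
        wave = TIMES / 100.0  # strictly increasing
        pk = measure_peak(wave, TIMES, "P100")
        assert pk.latency == 120.0

    def test_tie_broken_by_earliest_time(self):
        wave = np.zeros_like(TIMES)
        wave[np.where(TIMES == 160.0)[0][0]] = -2.0
        wave[np.where(TIMES == 180.0)[0][0]] = -2.0
        assert measure_peak(wave, TIMES, "N170").latency == 160.0

    def test_window_outside_time_vector_errors(self):
        with pytest.raises(ValueError):
            measure_peak(np.zeros(50), np.arange(50) * 2.0, "N170", window=(100.0, 600.0))

    def test_peak_table_layout(self, small_clustered):
        tab = peak_table(small_clustered, "N170")
        assert len(tab) == 6 * len(small_clustered)
        assert set(tab.columns) == {"participant", "emotion", "mouth", "amplitude_uv", "latency_ms"}
        assert (tab["amplitude_uv"] < 0).all()  # N170 minima are negative here
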