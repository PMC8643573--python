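"""Small Laplacian, Morlet decomposition, ERD/ERS maps, band summaries."""

import numpy as np
import pytest

from mrcplab.model import EEG_CHANNELS, Montage, epoch_times
from mrcplab.oscillations import (
    DEFAULT_BANDS,
    FIG_CAPTION_BANDS,
    BandDefinition,
    ERDMap,
    band_summary,
    erd_ers,
    erd_long_table,
    morlet_tfr,
    morlet_trials,
    small_laplacian,
)

FS = 250.0
CH = list(EEG_CHANNELS)


class TestSmallLaplacian:
    def test_common_mode_rejection(self):
        eeg = np.ones((17, 100)) * 3.3
        assert np.allclose(small_laplacian(eeg, CH, "Cz"), 0.0)

    def test_constant_arithmetic(self):
        m = Montage()
        eeg = np.zeros((17, 10))
        eeg[m.index("Cz")] = 5.0
        for val, n in zip((1.0, 2.0, 3.0, 4.0), m.laplacian_neighbors["Cz"]):
            eeg[m.index(n)] = val
        assert np.allclose(small_laplacian(eeg, CH, "Cz"), 5.0 - 2.5)

    def test_recovers_local_signal_under_shared_background(self):
        rng = np.random.default_rng(0)
        m = Montage()
        common = rng.standard_normal(500)
        local = rng.standard_normal(500)
        eeg = np.tile(common, (17, 1))
        eeg[m.index("Cz")] = common + local
        assert np.allclose(small_laplacian(eeg, CH, "Cz"), local, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 17, 200))
        lhs = small_laplacian(2 * a + 3 * b, CH, "FC1")
        rhs = 2 * small_laplacian(a, CH, "FC1") + 3 * small_laplacian(b, CH, "FC1")
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_unknown_center_rejected(self):
        with pytest.raises(ValueError):
            small_laplacian(np.zeros((17, 10)), CH, "Pz")


class TestMorlet:
    def test_zero_signal_zero_power(self):
        m = morlet_tfr(np.zeros(2000), FS)
        assert np.allclose(m.power, 0.0)
        assert m.power.shape == (50, 2000)

    def test_pure_tone_ridge_at_tone_frequency(self):
        t = np.arange(2000) / FS
        m = morlet_tfr(np.sin(2 * np.pi * 20.0 * t), FS)
        interior = m.power[:, 400:1600].mean(axis=1)
        assert abs(m.freqs[np.argmax(interior)] - 20.0) <= 1.0

    def test_two_tone_separation(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 6.0 * t) + np.sin(2 * np.pi * 30.0 * t)
        m = morlet_tfr(x, FS)
        interior = m.power[:, 400:1600].mean(axis=1)
        low = m.freqs[np.argmax(np.where(m.freqs <= 15, interior, 0.0))]
        high = m.freqs[np.argmax(np.where(m.freqs > 15, interior, 0.0))]
        assert abs(low - 6.0) <= 1.0 and abs(high - 30.0) <= 1.0

    def test_resolution_tradeoff_between_10_and_40_hz(self):
        """Fixed cycle count: temporal smearing of a click is wider at 10 Hz
        than at 40 Hz, spectral width of a tone narrower at 10 Hz."""
        t = np.arange(4000) / FS
        click = np.zeros(t.size)
        click[2000] = 1.0
        m_click = morlet_tfr(click, FS, freqs=np.array([10.0, 40.0]))

        def half_width(row):
            peak = row.max()
            return np.sum(row > peak / 2.0)

        assert half_width(m_click.power[0]) > half_width(m_click.power[1])
        tone10 = morlet_tfr(np.sin(2 * np.pi * 10 * t), FS).power[:, 1000:3000]
        tone40 = morlet_tfr(np.sin(2 * np.pi * 40 * t), FS).power[:, 1000:3000]
        assert half_width(tone10.mean(axis=1)) < half_width(tone40.mean(axis=1))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            morlet_tfr(np.zeros(500), FS)  # < 5 cycles at 1 Hz

    def test_edge_valid_margins_scale_with_frequency(self):
        m = morlet_tfr(np.zeros(2000), FS, times=epoch_times())
        assert m.edge_valid is not None
        # 2.5 cycles: 2.5 s at 1 Hz vs 0.05 s at 50 Hz
        assert m.edge_valid[0].sum() < m.edge_valid[-1].sum()

    def test_crop_pad_removes_context(self):
        trials = np.random.default_rng(2).standard_normal((3, 2500))
        full = morlet_trials(trials, FS)
        cropped = morlet_trials(trials, FS, crop_pad=250)
        assert cropped.shape == (3, 50, 2000)
        assert np.allclose(cropped, full[:, :, 250:-250])


def _synthetic_power(rng, n_trials=50, n_freqs=8, n_times=200):
    """iid exponential 'power' trials on a [-4, 4) s grid."""
    times = np.linspace(-4.0, 4.0, n_times, endpoint=False)
    power = rng.exponential(1.0, (n_trials, n_freqs, n_times))
    freqs = np.arange(10.0, 10.0 + n_freqs)
    return power, times, freqs


class TestERD:
    def test_stationary_trials_give_near_zero_map(self):
        power, times, freqs = _synthetic_power(np.random.default_rng(3),
                                               n_trials=400)
        erd = erd_ers(power, times=times, freqs=freqs)
        assert abs(erd.erd_pct.mean()) < 2.0

    def test_baseline_rows_average_to_zero_by_construction(self):
        power, times, freqs = _synthetic_power(np.random.default_rng(4))
        erd = erd_ers(power, times=times, freqs=freqs)
        sel = (times >= -4.0) & (times < -2.0)
        assert np.abs(erd.erd_pct[:, sel].mean(axis=1)).max() < 1e-6

    def test_scale_invariance_is_exact(self):
        power, times, freqs = _synthetic_power(np.random.default_rng(5))
        a = erd_ers(power, times=times, freqs=freqs)
        b = erd_ers(4.0 * power, times=times, freqs=freqs)
        assert np.array_equal(a.erd_pct, b.erd_pct)

    def test_zero_baseline_error_names_frequency(self):
        power, times, freqs = _synthetic_power(np.random.default_rng(6))
        power[:, 2, :] = 0.0
        with pytest.raises(ValueError, match="12"):
            erd_ers(power, times=times, freqs=freqs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            erd_ers([], times=None, freqs=None)


class TestBandSummary:
    def _uniform_map(self, value, freqs, times):
        return ERDMap("Cz", freqs, times, np.full((freqs.size, times.size),
                                                  value))

    def test_uniform_map(self):
        freqs = np.arange(1.0, 51.0)
        times = epoch_times()
        erd = self._uniform_map(-30.0, freqs, times)
        assert band_summary(erd, DEFAULT_BANDS["low_beta"], (-1, 1)) == -30.0

    def test_partition_of_bands(self):
        freqs = np.arange(1.0, 51.0)
        times = epoch_times()
        erd = self._uniform_map(0.0, freqs, times)
        lb = DEFAULT_BANDS["low_beta"]
        erd.erd_pct[lb.rows(freqs), :] = -40.0
        assert band_summary(erd, lb, (-1, 1)) == -40.0
        assert band_summary(erd, DEFAULT_BANDS["high_beta"], (-1, 1)) == 0.0

    def test_band_independence_to_machine_precision(self):
        rng = np.random.default_rng(7)
        freqs = np.arange(1.0, 51.0)
        times = epoch_times()
        erd = ERDMap("Cz", freqs, times,
                     rng.standard_normal((freqs.size, times.size)))
        before = band_summary(erd, DEFAULT_BANDS["low_beta"], (0, 2))
        erd.erd_pct[DEFAULT_BANDS["high_beta"].rows(freqs), :] += 55.0
        after = band_summary(erd, DEFAULT_BANDS["low_beta"], (0, 2))
        assert after == before

    def test_window_outside_grid_rejected(self):
        freqs = np.arange(1.0, 51.0)
        erd = self._uniform_map(0.0, freqs, epoch_times())
        with pytest.raises(ValueError):
            band_summary(erd, BandDefinition("x", 60.0, 70.0), (0, 1))

    def test_presets_differ_only_in_low_beta(self):
        assert FIG_CAPTION_BANDS["low_beta"].low_hz == 12.0
        assert FIG_CAPTION_BANDS["low_beta"].high_hz == 21.0
        assert FIG_CAPTION_BANDS["high_beta"] == DEFAULT_BANDS["high_beta"]


def test_erd_long_table_round_trip():
    power, times, freqs = _synthetic_power(np.random.default_rng(8),
                                           n_trials=12, n_freqs=3, n_times=20)
    erd = erd_ers(power, times=times, freqs=freqs, channel="FC1")
    table = erd_long_table(erd)
    assert len(table) == 3 * 20
    assert set(table.channel) == {"FC1"}
    back = table.erd_pct.to_numpy().reshape(3, 20)
    assert np.allclose(back, erd.erd_pct)
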