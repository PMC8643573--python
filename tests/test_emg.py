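"""EMG conditioning, TKEO identities, onset detection, EMG features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcplab.emg import (
    OnsetDetection,
    auto_threshold,
    bandpass_emg,
    detect_onset,
    detect_session_onsets,
    downsample_emg,
    emg_features,
    envelope,
    session_envelopes,
    smooth_energy,
    tkeo,
)
from mrcplab.model import TrialEpoch, epoch_times
from mrcplab.preprocess import extract_epochs
from mrcplab.synth import generate_session, null_profile

FS = 1000.0


def _sine(freq, fs=FS, dur=4.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t), t


def _tone_amplitude(y, freq, fs=FS):
    """Amplitude of the ``freq`` component over the interior half (projection
    onto the complex exponential, immune to filtfilt edge transients)."""
    n = y.size
    sl = slice(n // 4, 3 * n // 4)
    t = np.arange(n) / fs
    return 2.0 * np.abs(np.mean(y[sl] * np.exp(-2j * np.pi * freq * t[sl])))


class TestBandpass:
    def test_zero_in_zero_out(self):
        assert np.all(bandpass_emg(np.zeros(1000), FS) == 0.0)

    @pytest.mark.parametrize("freq,low,high", [
        (60.0, 0.99, 1.01),    # passband center: amplitude within 1%
        (2.0, 0.0, 0.05),      # stopband
    ])
    def test_frequency_response(self, freq, low, high):
        x, _ = _sine(freq, dur=8.0)
        amp = _tone_amplitude(bandpass_emg(x, FS), freq)
        assert low <= amp <= high

    def test_rate_too_low_for_upper_corner(self):
        with pytest.raises(ValueError):
            bandpass_emg(np.zeros(1000), 200.0)

    def test_zero_phase_time_reversal_symmetry(self):
        """Away from the boundary transients, filtering commutes with time
        reversal (the response has zero phase)."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(6000)
        fwd = bandpass_emg(x, FS)
        rev = bandpass_emg(x[::-1], FS)[::-1]
        sl = slice(1000, 5000)
        assert np.allclose(fwd[sl], rev[sl], atol=1e-6)


class TestDownsample:
    def test_constant_preserved(self):
        out = downsample_emg(np.full(4000, 3.7))
        assert out.size == 1000
        assert np.allclose(out, 3.7)

    def test_in_band_sinusoid_amplitude_preserved(self):
        x, _ = _sine(10.0, dur=8.0)
        out = downsample_emg(x)
        assert _tone_amplitude(out, 10.0, 250.0) == pytest.approx(1.0, rel=0.02)

    def test_aliasing_component_removed(self):
        x, _ = _sine(400.0, dur=8.0)
        out = downsample_emg(x)
        # 400 Hz would alias to 100 Hz at 250 Hz; it must not survive
        assert np.abs(out[200:-200]).max() < 0.01

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            downsample_emg(np.zeros(100), 1000.0, 300.0)


class TestTKEO:
    def test_constant_maps_to_zero_exactly(self):
        assert np.all(tkeo(np.full(100, 5.0)) == 0.0)

    def test_matches_defining_formula(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        psi = tkeo(x)
        for n in range(1, 49):
            assert psi[n] == x[n] ** 2 - x[n - 1] * x[n + 1]
        assert psi[0] == 0.0 and psi[-1] == 0.0

    def test_unit_impulse(self):
        x = np.zeros(11)
        x[5] = 1.0
        psi = tkeo(x)
        expected = np.zeros(11)
        expected[4:7] = [0.0, 1.0, 0.0]
        assert np.array_equal(psi, expected)

    @settings(derandomize=True, max_examples=25)
    @given(a=st.sampled_from([-2.0, 0.5, 3.0]), seed=st.integers(0, 1000))
    def test_homogeneity_of_degree_two(self, a, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        assert np.allclose(tkeo(a * x), a * a * tkeo(x), rtol=1e-12, atol=1e-12)

    def test_sinusoid_closed_form(self):
        """psi(A sin(w n)) = A^2 sin^2(w) for interior samples."""
        A, w = 2.0, 0.1
        n = np.arange(500)
        psi = tkeo(A * np.sin(w * n))
        assert np.allclose(psi[1:-1], A ** 2 * np.sin(w) ** 2, atol=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            tkeo(np.zeros(2))


class TestAutoThreshold:
    def test_zero_baseline_gives_zero(self):
        assert auto_threshold(np.zeros(600)) == 0.0

    def test_affine_equivariance(self):
        e = np.random.default_rng(2).standard_normal(1000) ** 2
        assert auto_threshold(4.0 * e) == pytest.approx(4.0 * auto_threshold(e))

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            auto_threshold(np.array([]))


class TestDetectOnset:
    def test_zero_energy_undetected(self):
        det = detect_onset(np.zeros(8000), 1.0, FS, threshold=0.0)
        assert not det.detected and det.onset_time_s is None

    def test_ideal_step_detected_at_exact_sample(self):
        e = np.zeros(8000)
        t_star = 3000
        e[t_star:] = 10.0
        det = detect_onset(e, 1.0, FS, threshold=1.0, min_hold_s=0.05)
        assert det.detected
        assert det.onset_time_s == pytest.approx(t_star / FS, abs=1.0 / FS)

    def test_isolated_spike_rejected_by_hold(self):
        e = np.zeros(8000)
        e[3000:3005] = 100.0  # 5 ms spike, hold requires 50 ms
        det = detect_onset(e, 1.0, FS, threshold=1.0, min_hold_s=0.05)
        assert not det.detected

    def test_false_crossing_rate_on_pure_noise_below_5pct(self):
        """k=8 auto-threshold on burst-free EMG: < 5% of trials trigger."""
        sess, _, _ = generate_session(null_profile(emg_peak_uv=0.0), "s",
                                      n_trials=60,
                                      rng=np.random.default_rng(3),
                                      trial_spacing_s=10.0)
        dets, _ = detect_session_onsets(sess)
        assert np.mean([d.detected for d in dets]) < 0.05

    def test_variance_decreases_with_snr(self):
        """Detection error variance shrinks monotonically over 0/6/12 dB."""
        variances = []
        for i, snr in enumerate((0.0, 6.0, 12.0)):
            sess, truth, _ = generate_session(
                null_profile(emg_snr_db=snr), "s", n_trials=50,
                rng=np.random.default_rng(20 + i), trial_spacing_s=10.0)
            dets, _ = detect_session_onsets(sess)
            errs = [d.onset_time_s - o for d, o in zip(dets, truth.onset_s)
                    if d.detected]
            # at 0 dB most bursts are (correctly) left undetected
            assert len(errs) >= 5
            variances.append(np.var(errs))
        assert variances[0] > variances[1] > variances[2]


class TestEMGFeatures:
    def _epoch_with_envelopes(self, ta, sol=None):
        times = epoch_times()
        return TrialEpoch("s", 0, 0.0, np.zeros((17, times.size)), times,
                          emg_ta_envelope=ta, emg_sol_envelope=sol)

    def test_triangular_peak_read_exactly(self):
        times = epoch_times()
        ta = np.interp(times, [0.2, 0.4, 0.6], [0.0, 500.0, 0.0],
                       left=0.0, right=0.0)
        feats = emg_features(self._epoch_with_envelopes(ta))
        assert feats.peak_amplitude_uv == pytest.approx(500.0)
        assert feats.peak_time_ms == pytest.approx(400.0, abs=4.0)

    def test_flat_envelope_gives_missing_features(self):
        feats = emg_features(self._epoch_with_envelopes(np.zeros(2000)))
        assert feats.peak_amplitude_uv is None and feats.peak_time_ms is None

    def test_zero_sol_channel_gives_missing_lag_only(self):
        times = epoch_times()
        ta = np.interp(times, [0.2, 0.4, 0.6], [0.0, 500.0, 0.0],
                       left=0.0, right=0.0)
        feats = emg_features(self._epoch_with_envelopes(ta, np.zeros(2000)))
        assert feats.onset_lag_ta_sol_ms is None
        assert feats.peak_amplitude_uv == pytest.approx(500.0)

    def test_ta_sol_lag_recovery(self):
        """SOL bursts injected 120 ms after TA: mean recovered lag within
        +-20 ms over 40 trials."""
        prof = null_profile(ta_sol_lag_s=(0.12, 0.0))
        sess, truth, _ = generate_session(prof, "s", n_trials=40,
                                          rng=np.random.default_rng(4),
                                          trial_spacing_s=10.0)
        envs = session_envelopes(sess)
        dets = [OnsetDetection(i, float(t), 0.0, 0.0, True)
                for i, t in enumerate(truth.onset_s)]
        epochs, _ = extract_epochs(sess.eeg, dets, 250.0,
                                   ta_envelope=envs["TA_right"],
                                   sol_envelope=envs["SOL_right"])
        lags = [emg_features(ep).onset_lag_ta_sol_ms for ep in epochs]
        lags = [v for v in lags if v is not None]
        assert len(lags) >= 30
        assert np.mean(lags) == pytest.approx(120.0, abs=20.0)


def test_envelope_is_nonnegative_and_smooth():
    rng = np.random.default_rng(5)
    x = bandpass_emg(rng.standard_normal(4000), FS)
    env = envelope(x, FS)
    # rectified + 6 Hz low-pass: tracks |x| on average, much smoother
    assert np.var(np.diff(env)) < np.var(np.diff(np.abs(x)))
    assert env.mean() == pytest.approx(np.abs(x).mean(), rel=0.15)


def test_smooth_energy_preserves_mean():
    e = np.random.default_rng(6).standard_normal(5000) ** 2
    assert smooth_energy(e, FS).mean() == pytest.approx(e.mean(), rel=0.01)
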