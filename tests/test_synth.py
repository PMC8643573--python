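"""Generator contracts: determinism, injected structure, blink statistics."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import poisson

from mrcplab.emg import OnsetDetection
from mrcplab.model import Group, epoch_times
from mrcplab.preprocess import extract_epochs
from mrcplab.synth import (
    BandModulation,
    GroupProfile,
    default_profiles,
    generate_cohort,
    generate_session,
    inject_blinks,
    mrcp_template,
    null_profile,
    pink_noise,
)


class TestDeterminism:
    def test_same_seed_bit_identical_cohort(self):
        profiles = [null_profile(peak_negativity_uv=-10.0)]
        a, truth_a = generate_cohort(profiles, 2, n_trials=3, seed=9,
                                     trial_spacing_s=10.0)
        b, truth_b = generate_cohort(profiles, 2, n_trials=3, seed=9,
                                     trial_spacing_s=10.0)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.eeg, sb.eeg)
            assert np.array_equal(sa.emg, sb.emg)
            assert sa.cues == sb.cues
        assert truth_a.trials.equals(truth_b.trials)

    def test_different_seed_differs(self):
        profiles = [null_profile()]
        a, _ = generate_cohort(profiles, 1, n_trials=2, seed=1,
                               trial_spacing_s=10.0)
        b, _ = generate_cohort(profiles, 1, n_trials=2, seed=2,
                               trial_spacing_s=10.0)
        assert not np.array_equal(a[0].eeg, b[0].eeg)


class TestSchedule:
    def test_cue_structure(self):
        sess, truth, _ = generate_session(
            null_profile(), "s", n_trials=15, rng=np.random.default_rng(0))
        assert len(sess.cues) == 15
        for ready, go in sess.cues:
            assert go - ready == pytest.approx(2.0)
        spacings = np.diff([r for r, _ in sess.cues])
        assert np.all(spacings >= 10.0)
        assert np.all(truth.onset_s > truth.go_s)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_session(null_profile(), "s", n_trials=0)
        with pytest.raises(ValueError):
            generate_cohort([null_profile()], 0)
        with pytest.raises(ValueError):
            BandModulation("gamma", ("Cz",), (0.0, 1.0), -10.0)
        with pytest.raises(ValueError):
            GroupProfile(name=Group.HC, peak_jitter_sd_s=-1.0)


class TestTemplate:
    def test_analytic_readouts_are_exact(self):
        t = epoch_times()
        w = mrcp_template(t, 0.3, -3.0, -12.0, -16.0, 3.0)
        at = lambda s: w[int(round((s - t[0]) * 250.0))]
        assert at(0.3) == pytest.approx(-16.0, abs=1e-12)
        assert (at(-0.1) - at(-1.1)) / 1.0 == pytest.approx(-3.0, abs=1e-12)
        assert (at(0.3) - at(-0.1)) / 0.4 == pytest.approx(-12.0, abs=1e-12)
        assert (at(1.8) - at(0.3)) / 1.5 == pytest.approx(3.0, abs=1e-12)

    def test_grand_average_trough_recovery(self):
        """100 noisy trials: the averaged Cz trough is within +-1 uV of the
        injected -16 uV (SE = 2/sqrt(100) uV)."""
        prof = null_profile(peak_negativity_uv=-16.0, ns1_slope_uv_per_s=-3.0,
                            ns2_slope_uv_per_s=-12.0, rebound_rate_uv_per_s=3.0,
                            pink_rms_uv=2.0, white_rms_uv=0.0)
        sess, truth, _ = generate_session(prof, "s", n_trials=100,
                                          rng=np.random.default_rng(10),
                                          trial_spacing_s=10.0)
        dets = [OnsetDetection(i, float(t), 0.0, 0.0, True)
                for i, t in enumerate(truth.onset_s)]
        epochs, _ = extract_epochs(sess.eeg, dets, 250.0)
        mean_cz = np.mean([ep.channel("Cz") for ep in epochs], axis=0)
        assert mean_cz.min() == pytest.approx(-16.0, abs=1.0)


class TestPinkNoise:
    def test_unit_rms_and_spectral_slope(self):
        x = pink_noise(2 ** 16, np.random.default_rng(0))
        assert np.sqrt(np.mean(x ** 2)) == pytest.approx(1.0, rel=1e-6)
        f, p = sps.welch(x, fs=250.0, nperseg=4096)
        sel = (f > 1) & (f < 50)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert -1.3 < slope < -0.7


class TestERDByConstruction:
    def test_welch_band_power_change_matches_requested_pct(self):
        """A pure -40% low-beta schedule in [-1, 0] s produces a measured
        Welch band-power drop of 40 +- 5 points vs baseline at 200 trials."""
        prof = null_profile(modulations=(
            BandModulation("low_beta", ("Cz",), (-1.0, 0.0), -40.0),))
        sess, truth, _ = generate_session(prof, "s", n_trials=200,
                                          rng=np.random.default_rng(11),
                                          trial_spacing_s=10.0)
        cz = sess.channel("Cz")
        fs = 250.0

        def band_power(t0, t1, onset):
            seg = cz[int((onset + t0) * fs): int((onset + t1) * fs)]
            f, p = sps.welch(seg, fs=fs, nperseg=min(250, seg.size))
            m = (f >= 13) & (f <= 20)
            return np.trapezoid(p[m], f[m])

        mod = np.mean([band_power(-1.0, 0.0, o) for o in truth.onset_s])
        base = np.mean([band_power(-4.0, -2.0, o) for o in truth.onset_s])
        assert 100.0 * (mod - base) / base == pytest.approx(-40.0, abs=5.0)


class TestBlinks:
    def test_rate_zero_and_amplitude_zero_are_identity(self):
        sess, _, _ = generate_session(null_profile(), "s", n_trials=2,
                                      rng=np.random.default_rng(1),
                                      trial_spacing_s=10.0)
        for rate, amp in ((0.0, 150.0), (10.0, 0.0)):
            out, times = inject_blinks(sess, rate, amp, 0)
            assert np.array_equal(out.eeg, sess.eeg)
            assert times == []

    def test_negative_rate_rejected(self):
        sess, _, _ = generate_session(null_profile(), "s", n_trials=2,
                                      rng=np.random.default_rng(1),
                                      trial_spacing_s=10.0)
        with pytest.raises(ValueError):
            inject_blinks(sess, -1.0, 100.0, 0)

    def test_blink_count_is_poisson(self):
        """Total blink count over 50 seeds stays inside the Poisson 99%
        interval for the requested rate."""
        sess, _, _ = generate_session(null_profile(), "s", n_trials=2,
                                      rng=np.random.default_rng(2),
                                      trial_spacing_s=10.0)
        lam_per_run = 10.0 / 60.0 * sess.duration_s
        total = sum(len(inject_blinks(sess, 10.0, 150.0, seed)[1])
                    for seed in range(50))
        lam = 50 * lam_per_run
        assert poisson.ppf(0.005, lam) <= total <= poisson.ppf(0.995, lam)

    def test_blinks_are_frontally_dominant(self):
        sess, _, _ = generate_session(null_profile(pink_rms_uv=0.5,
                                                   white_rms_uv=0.1),
                                      "s", n_trials=2,
                                      rng=np.random.default_rng(3),
                                      trial_spacing_s=10.0)
        out, times = inject_blinks(sess, 20.0, 150.0, 7)
        assert len(times) > 0
        var = out.eeg.var(axis=1)
        assert var[out.montage.index("FP1")] > 5 * var[out.montage.index("Pz")]


def test_default_profiles_cover_all_groups():
    profiles = default_profiles()
    assert set(profiles) == set(Group)
    hc, severe = profiles[Group.HC], profiles[Group.PD_SEVEREFOG]
    # the clinical contrasts the cohort emulates
    assert hc.ns1_slope_uv_per_s < severe.ns1_slope_uv_per_s
    assert hc.emg_peak_uv > severe.emg_peak_uv
    hc_lowbeta = [m for m in hc.modulations if m.band == "low_beta"]
    sev_lowbeta = [m for m in severe.modulations if m.band == "low_beta"]
    assert hc_lowbeta and hc_lowbeta[0].pct < 0      # strong ERD in controls
    assert not sev_lowbeta                           # absent in severe FOG
    assert any(m.band == "theta" and m.pct > 0 for m in severe.modulations)
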