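"""Synthetic multi-subject EEG+EMG sessions with known injected structure.

Every downstream stage (onset detection, MRCP features, ERD/ERS maps, group
statistics) is exercised against cohorts produced here, with a ground-truth
table of the injected parameters, so recovery can be measured without any
recorded data.

What is emulated
----------------
* 'ready'/'go' auditory cues 2 s apart, 15 trials per session by default.
* EEG background: 1/f (pink) noise plus white sensor noise, per channel.
* A piecewise-linear movement-related cortical potential (MRCP) template —
  an early shallow negative slope (NS1) over [peak−1.4, peak−0.4] s, a steep
  late slope (NS2) over the final 0.4 s, and a linear post-peak rebound —
  spatially weighted over the motor-cortex channels (Cz maximal).
* Band-limited oscillatory carriers whose envelopes are rescaled inside
  scheduled windows relative to the true movement onset, realizing requested
  event-related desynchronization/synchronization (ERD/ERS) percentages of
  *measured* band power (the gain compensates for broadband background power
  in the band, so the injected percentage is the recoverable one).
* EMG: 20–120 Hz bursts on the dominant-leg tibialis anterior (TA) starting
  at the true onset, and on the soleus (SOL) a configurable lag later, with
  band-limited baseline noise at a configurable burst-to-baseline SNR.
* Optional stereotyped eye-blink transients, frontally dominant.

Sessions are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .model import (
    EEG_CHANNELS,
    EMG_CHANNELS,
    Group,
    Montage,
    RawSession,
)

#: Frequency bands (Hz).  The low/high beta split follows the 13–20 / 21–35
#: convention; a 12–21 split is available in :mod:`mrcplab.oscillations`.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "low_beta": (13.0, 20.0),
    "high_beta": (21.0, 35.0),
    "beta": (12.0, 35.0),
}

#: Spatial weighting of the MRCP template (Cz maximal, motor midline focus).
MRCP_WEIGHTS: dict[str, float] = {
    "Cz": 1.0, "FC1": 0.8, "FC2": 0.8, "C3": 0.55, "C4": 0.55, "Fz": 0.5,
    "CP1": 0.45, "CP2": 0.45, "Pz": 0.35, "F3": 0.25, "F4": 0.25,
    "P3": 0.2, "P4": 0.2, "AF3": 0.1, "AF4": 0.1, "FP1": 0.05, "FP2": 0.05,
}

#: Frontal-dominant spatial pattern of eye blinks.
BLINK_WEIGHTS: dict[str, float] = {
    "FP1": 1.0, "FP2": 1.0, "AF3": 0.6, "AF4": 0.6, "F3": 0.3, "Fz": 0.3,
    "F4": 0.3, "FC1": 0.15, "FC2": 0.15, "C3": 0.08, "Cz": 0.08, "C4": 0.08,
    "CP1": 0.04, "CP2": 0.04, "P3": 0.02, "Pz": 0.02, "P4": 0.02,
}


@dataclass(frozen=True)
class BandModulation:
    """One scheduled band-power change: ``pct`` percent (negative = ERD)
    applied on ``channels`` inside ``window_s`` relative to movement onset."""

    band: str
    channels: tuple[str, ...]
    window_s: tuple[float, float]
    pct: float

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}; known: {sorted(BANDS)}")
        if self.window_s[1] <= self.window_s[0]:
            raise ValueError("modulation window must have positive length")


@dataclass(frozen=True)
class GroupProfile:
    """Injected per-group structure.

    Slopes are µV/s (negative = growing pre-movement negativity), amplitudes
    µV.  ``emg_onset_delay_s`` and ``ta_sol_lag_s`` are (mean, SD) in
    seconds.  Noise amplitudes are session RMS values per channel.
    """

    name: Group
    ns1_slope_uv_per_s: float = -3.0
    ns2_slope_uv_per_s: float = -12.0
    peak_negativity_uv: float = -16.0
    rebound_rate_uv_per_s: float = 3.0
    peak_offset_s: float = 0.3           # template trough relative to onset
    peak_jitter_sd_s: float = 0.0
    amplitude_jitter_sd: float = 0.0     # fractional trial-to-trial MRCP scale
    modulations: tuple[BandModulation, ...] = ()
    emg_peak_uv: float = 900.0
    emg_onset_delay_s: tuple[float, float] = (0.5, 0.1)
    ta_sol_lag_s: tuple[float, float] = (0.12, 0.02)
    emg_snr_db: float = 12.0
    pink_rms_uv: float = 4.0
    white_rms_uv: float = 1.0
    carrier_rms_uv: float = 3.0
    blink_rate_per_min: float = 0.0
    blink_amplitude_uv: float = 120.0

    def __post_init__(self) -> None:
        for sd in (self.peak_jitter_sd_s, self.amplitude_jitter_sd,
                   self.emg_onset_delay_s[1], self.ta_sol_lag_s[1]):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


def default_profiles() -> dict[Group, GroupProfile]:
    """Group profiles qualitatively mirroring the clinical contrasts: healthy
    controls with the strongest NS1 and beta ERD plus post-movement beta
    rebound; severe freezing-of-gait with near-absent NS1, suppressed
    low-beta ERD, pre-movement theta ERS and the weakest TA burst.

    These are test parameters for recovery and contrast detection, not
    claims about any cohort.
    """
    motor = ("Cz", "FC1", "FC2")
    return {
        Group.HC: GroupProfile(
            name=Group.HC,
            ns1_slope_uv_per_s=-3.0, ns2_slope_uv_per_s=-12.8,
            peak_negativity_uv=-16.0, rebound_rate_uv_per_s=3.4,
            peak_jitter_sd_s=0.05, amplitude_jitter_sd=0.15,
            emg_peak_uv=946.0,
            modulations=(
                BandModulation("low_beta", motor, (-1.0, 2.0), -40.0),
                BandModulation("high_beta", motor, (-2.0, 2.0), -30.0),
                BandModulation("beta", motor, (2.5, 4.0), 30.0),
            ),
        ),
        Group.PD_NOFOG: GroupProfile(
            name=Group.PD_NOFOG,
            ns1_slope_uv_per_s=-1.7, ns2_slope_uv_per_s=-10.5,
            peak_negativity_uv=-10.5, rebound_rate_uv_per_s=2.8,
            peak_jitter_sd_s=0.06, amplitude_jitter_sd=0.15,
            emg_peak_uv=737.0,
            modulations=(
                BandModulation("low_beta", motor, (-1.0, 2.0), -20.0),
                BandModulation("high_beta", motor, (-2.0, 2.0), -15.0),
            ),
        ),
        Group.PD_MILDFOG: GroupProfile(
            name=Group.PD_MILDFOG,
            ns1_slope_uv_per_s=-1.0, ns2_slope_uv_per_s=-13.2,
            peak_negativity_uv=-13.6, rebound_rate_uv_per_s=1.2,
            peak_jitter_sd_s=0.06, amplitude_jitter_sd=0.2,
            emg_peak_uv=825.0,
            modulations=(
                BandModulation("low_beta", motor, (-1.0, 2.0), -10.0),
                BandModulation("high_beta", motor, (-2.0, 0.0), -20.0),
                BandModulation("theta", motor, (-2.0, 0.0), 15.0),
            ),
        ),
        Group.PD_SEVEREFOG: GroupProfile(
            name=Group.PD_SEVEREFOG,
            ns1_slope_uv_per_s=-0.6, ns2_slope_uv_per_s=-18.6,
            peak_negativity_uv=-13.7, rebound_rate_uv_per_s=2.5,
            peak_jitter_sd_s=0.1, amplitude_jitter_sd=0.25,
            emg_peak_uv=512.0,
            ta_sol_lag_s=(0.25, 0.08),
            modulations=(
                BandModulation("theta", motor, (-2.0, 0.5), 25.0),
                BandModulation("high_beta", ("Cz",), (0.0, 2.0), -25.0),
            ),
        ),
    }


def null_profile(name: Group = Group.HC, **overrides) -> GroupProfile:
    """A profile with no injected MRCP, no band modulation and no blinks:
    the EEG is stationary colored noise."""
    base = dict(
        name=name, ns1_slope_uv_per_s=0.0, ns2_slope_uv_per_s=0.0,
        peak_negativity_uv=0.0, rebound_rate_uv_per_s=0.0,
        amplitude_jitter_sd=0.0, peak_jitter_sd_s=0.0,
        modulations=(), blink_rate_per_min=0.0,
    )
    base.update(overrides)
    return GroupProfile(**base)


@dataclass
class GroundTruth:
    """Injected parameters per generated trial plus blink times and seed."""

    trials: pd.DataFrame
    blinks: pd.DataFrame
    seed: int
    profiles: dict[str, GroupProfile] = field(default_factory=dict)


def pink_noise(n: int, rng: np.random.Generator, alpha: float = 1.0) -> np.ndarray:
    """Unit-RMS 1/f^alpha noise of length ``n`` (DC removed)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore"):
        scale = np.where(f > 0, f ** (-alpha / 2.0), 0.0)
    x = np.fft.irfft(spec * scale, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float,
              order: int = 4) -> np.ndarray:
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def mrcp_template(t: np.ndarray, peak_time_s: float, ns1: float, ns2: float,
                  peak_uv: float, rebound: float,
                  knee_s: float = 0.24) -> np.ndarray:
    """Piecewise-linear MRCP waveform evaluated at session times ``t``.

    Knots (relative to the trough at ``peak_time_s``): an approach from 0 at
    −2.4 s to the pre-NS1 level at −1.4 s, the NS1 segment to −0.4 s, the
    NS2 segment to the trough, then a two-segment recovery — a brief steep
    motor-potential rebound (slope −ns2 for ``knee_s``) followed by a slower
    return that passes *exactly* through ``peak_uv + 1.5·rebound`` at
    +1.5 s — and a final linear decay to 0 at +4 s.  The pre-NS1 level is
    chosen so the trough equals ``peak_uv`` while the NS1/NS2 slopes and the
    +1.5 s rebound read-out are analytically exact.  The steep initial
    recovery keeps the trough sharply localized on both flanks, as in
    recorded motor potentials.
    """
    b = peak_uv - ns1 * 1.0 - ns2 * 0.4          # value at peak-1.4 s
    knots_t = peak_time_s + np.array([-2.4, -1.4, -0.4, 0.0, knee_s, 1.5, 4.0])
    knots_v = np.array([0.0, b, b + ns1, peak_uv, peak_uv - ns2 * knee_s,
                        peak_uv + 1.5 * rebound, 0.0])
    return np.interp(t, knots_t, knots_v, left=0.0, right=0.0)


def _smooth_gain(n: int, fs: float, windows: list[tuple[float, float, float]],
                 ramp_s: float = 0.1) -> np.ndarray:
    """Amplitude-gain time series: ``g`` throughout each scheduled window,
    1 elsewhere, with raised-cosine ramps of ``ramp_s`` placed just *outside*
    the window edges so the whole window sits at plateau gain."""
    t = np.arange(n) / fs
    gain = np.ones(n)
    for t0, t1, g in windows:
        ramp = ramp_s
        up = np.clip((t - (t0 - ramp)) / ramp, 0.0, 1.0)
        down = np.clip((t1 + ramp - t) / ramp, 0.0, 1.0)
        frac = np.minimum(up, down)                  # 0 outside, 1 in plateau
        frac = 0.5 - 0.5 * np.cos(np.pi * frac)      # raised cosine
        gain *= 1.0 + (g - 1.0) * frac
    return gain


def _burst_envelope(t: np.ndarray, onset_s: float, rise_s: float = 0.02,
                    plateau_s: float = 0.9, fall_s: float = 0.4) -> np.ndarray:
    """Trapezoidal burst envelope; the 20 ms rise models a ballistic
    dorsiflexion burst with a sharp recruitment front."""
    knots_t = onset_s + np.array([0.0, rise_s, rise_s + plateau_s,
                                  rise_s + plateau_s + fall_s])
    return np.interp(t, knots_t, [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)


def generate_session(
    profile: GroupProfile,
    subject_id: str,
    n_trials: int = 15,
    rng: np.random.Generator | None = None,
    trial_spacing_s: float = 15.0,
    lead_in_s: float = 12.0,
    dominant_foot: str = "right",
    montage: Montage | None = None,
) -> tuple[RawSession, pd.DataFrame, pd.DataFrame]:
    """Generate one session; returns (session, trial truth table, blink table)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if trial_spacing_s < 10.0:
        raise ValueError("inter-trial spacing must be >= 10 s")
    rng = rng or np.random.default_rng(0)
    montage = montage or Montage()
    fs_eeg, fs_emg = 250.0, 1000.0
    duration = float(int(np.ceil(lead_in_s + (n_trials - 1) * trial_spacing_s + 10.0)))
    n_eeg, n_emg = int(duration * fs_eeg), int(duration * fs_emg)
    t_eeg = np.arange(n_eeg) / fs_eeg
    t_emg = np.arange(n_emg) / fs_emg

    # --- cue and event schedule -------------------------------------------
    readies = lead_in_s + trial_spacing_s * np.arange(n_trials)
    gos = readies + 2.0
    delays = np.clip(rng.normal(*profile.emg_onset_delay_s, n_trials), 0.15, 1.5)
    onsets = gos + delays
    peak_jit = rng.normal(0.0, profile.peak_jitter_sd_s or 0.0, n_trials) \
        if profile.peak_jitter_sd_s > 0 else np.zeros(n_trials)
    peak_times = onsets + profile.peak_offset_s + peak_jit
    amp_scale = np.ones(n_trials)
    if profile.amplitude_jitter_sd > 0:
        amp_scale = np.clip(
            1.0 + rng.normal(0.0, profile.amplitude_jitter_sd, n_trials), 0.2, 2.0)
    lags = np.clip(rng.normal(*profile.ta_sol_lag_s, n_trials), 0.0, 1.0)

    # --- EEG: background noise --------------------------------------------
    eeg = np.empty((len(montage.channel_names), n_eeg))
    for ci in range(eeg.shape[0]):
        ch = np.zeros(n_eeg)
        if profile.pink_rms_uv > 0:
            ch += profile.pink_rms_uv * pink_noise(n_eeg, rng)
        if profile.white_rms_uv > 0:
            ch += profile.white_rms_uv * rng.standard_normal(n_eeg)
        eeg[ci] = ch

    # --- EEG: MRCP template -----------------------------------------------
    if profile.peak_negativity_uv != 0 or profile.ns1_slope_uv_per_s != 0 \
            or profile.ns2_slope_uv_per_s != 0:
        mrcp = np.zeros(n_eeg)
        for k in range(n_trials):
            mrcp += amp_scale[k] * mrcp_template(
                t_eeg, peak_times[k], profile.ns1_slope_uv_per_s,
                profile.ns2_slope_uv_per_s, profile.peak_negativity_uv,
                profile.rebound_rate_uv_per_s)
        for name, w in MRCP_WEIGHTS.items():
            eeg[montage.index(name)] += w * mrcp

    # --- EEG: band-limited carriers with scheduled ERD/ERS ----------------
    by_band_channel: dict[tuple[str, str], list[BandModulation]] = {}
    for mod in profile.modulations:
        for ch_name in mod.channels:
            by_band_channel.setdefault((mod.band, ch_name), []).append(mod)
    for (band, ch_name), mods in by_band_channel.items():
        ci = montage.index(ch_name)
        lo, hi = BANDS[band]
        carrier = _bandpass(rng.standard_normal(n_eeg), (lo, hi), fs_eeg)
        carrier *= profile.carrier_rms_uv / np.sqrt(np.mean(carrier ** 2))
        v_carrier = float(np.mean(carrier ** 2))
        v_bg = float(np.var(_bandpass(eeg[ci], (lo, hi), fs_eeg)))
        windows = []
        for mod in mods:
            # amplitude gain chosen so *total* band power changes by pct,
            # compensating for broadband background power in the band
            g2 = 1.0 + (mod.pct / 100.0) * (1.0 + v_bg / v_carrier)
            g = np.sqrt(max(g2, 0.0))
            for k in range(n_trials):
                windows.append((onsets[k] + mod.window_s[0],
                                onsets[k] + mod.window_s[1], g))
        eeg[ci] += carrier * _smooth_gain(n_eeg, fs_eeg, windows)

    # --- EMG ---------------------------------------------------------------
    burst_amp = profile.emg_peak_uv * np.sqrt(np.pi / 2.0)  # rectified mean -> peak
    noise_rms = burst_amp / (10.0 ** (profile.emg_snr_db / 20.0)) \
        if profile.emg_peak_uv > 0 else 20.0
    emg = np.empty((len(EMG_CHANNELS), n_emg))
    side = dominant_foot
    for mi, name in enumerate(EMG_CHANNELS):
        noise = _bandpass(rng.standard_normal(n_emg), (20.0, 120.0), fs_emg)
        ch = noise_rms * noise / np.sqrt(np.mean(noise ** 2))
        is_dominant = name.endswith(side)
        if is_dominant and profile.emg_peak_uv > 0:
            env = np.zeros(n_emg)
            sol = name.startswith("SOL")
            scale = 0.8 if sol else 1.0
            for k in range(n_trials):
                start = onsets[k] + (lags[k] if sol else 0.0)
                env += _burst_envelope(t_emg, start)
            carrier = _bandpass(rng.standard_normal(n_emg), (20.0, 120.0), fs_emg)
            carrier /= np.sqrt(np.mean(carrier ** 2))
            ch = ch + scale * burst_amp * env * carrier
        emg[mi] = ch

    session = RawSession(
        subject_id=subject_id, group=profile.name, dominant_foot=dominant_foot,
        eeg=eeg, emg=emg, cues=list(zip(readies.tolist(), gos.tolist())),
        montage=montage)

    blink_rows: list[dict] = []
    if profile.blink_rate_per_min > 0 and profile.blink_amplitude_uv != 0:
        session, times = inject_blinks(
            session, profile.blink_rate_per_min, profile.blink_amplitude_uv, rng)
        blink_rows = [{"subject_id": subject_id, "time_s": t} for t in times]

    trials = pd.DataFrame({
        "subject_id": subject_id,
        "group": profile.name.value,
        "trial": np.arange(n_trials),
        "ready_s": readies,
        "go_s": gos,
        "onset_s": onsets,
        "peak_time_s": peak_times,
        "ns1_uv_per_s": amp_scale * profile.ns1_slope_uv_per_s,
        "ns2_uv_per_s": amp_scale * profile.ns2_slope_uv_per_s,
        "peak_uv": amp_scale * profile.peak_negativity_uv,
        "rebound_uv_per_s": amp_scale * profile.rebound_rate_uv_per_s,
        "emg_peak_uv": profile.emg_peak_uv,
        "ta_sol_lag_s": lags,
    })
    blinks = pd.DataFrame(blink_rows, columns=["subject_id", "time_s"])
    return session, trials, blinks


def inject_blinks(
    session: RawSession,
    rate_per_min: float,
    amplitude_uv: float,
    rng: np.random.Generator | int | None = None,
) -> tuple[RawSession, list[float]]:
    """Add stereotyped ~0.3 s frontal-dominant blink transients at Poisson
    times; returns a modified copy and the blink onset times (s)."""
    if rate_per_min < 0:
        raise ValueError("blink rate must be >= 0")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    eeg = session.eeg.copy()
    duration = session.duration_s
    n_blinks = rng.poisson(rate_per_min / 60.0 * duration)
    times: list[float] = []
    if rate_per_min > 0 and amplitude_uv != 0 and n_blinks > 0:
        fs = session.eeg_rate
        width = int(round(0.3 * fs))
        shape = np.hanning(width) ** 2
        starts = np.sort(rng.uniform(0.0, duration - 0.35, n_blinks))
        for t0 in starts:
            i0 = int(round(t0 * fs))
            seg = slice(i0, i0 + width)
            n_seg = eeg[0, seg].size
            for name, w in BLINK_WEIGHTS.items():
                eeg[session.montage.index(name), seg] += \
                    amplitude_uv * w * shape[:n_seg]
            times.append(float(t0))
    out = replace(session, eeg=eeg, emg=session.emg.copy(),
                  cues=list(session.cues))
    return out, times


def generate_cohort(
    profiles: Sequence[GroupProfile] | dict[Group, GroupProfile],
    n_subjects_per_group: int,
    n_trials: int = 15,
    seed: int = 0,
    trial_spacing_s: float = 15.0,
    left_dominant_fraction: float = 0.0,
) -> tuple[list[RawSession], GroundTruth]:
    """Generate a cohort: ``n_subjects_per_group`` sessions for each profile.

    Deterministic for a fixed seed (per-subject RNG streams are spawned from
    one root ``SeedSequence``, so cohorts are bit-reproducible).
    """
    if n_subjects_per_group < 1 or n_trials < 1:
        raise ValueError("subject and trial counts must be >= 1")
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(profiles) * n_subjects_per_group)
    sessions: list[RawSession] = []
    trial_tables, blink_tables = [], []
    si = 0
    for profile in profiles:
        for k in range(n_subjects_per_group):
            rng = np.random.default_rng(streams[si])
            subject_id = f"{profile.name.value}_{k:02d}"
            foot = "left" if rng.uniform() < left_dominant_fraction else "right"
            sess, trials, blinks = generate_session(
                profile, subject_id, n_trials=n_trials, rng=rng,
                trial_spacing_s=trial_spacing_s, dominant_foot=foot)
            sessions.append(sess)
            trial_tables.append(trials)
            blink_tables.append(blinks)
            si += 1
    truth = GroundTruth(
        trials=pd.concat(trial_tables, ignore_index=True),
        blinks=pd.concat(blink_tables, ignore_index=True)
        if blink_tables else pd.DataFrame(columns=["subject_id", "time_s"]),
        seed=seed,
        profiles={p.name.value: p for p in profiles},
    )
    return sessions, truth
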