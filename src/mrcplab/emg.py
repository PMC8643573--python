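"""EMG conditioning, Teager–Kaiser energy, movement-onset detection, features.

The detection chain follows the standard surface-EMG recipe for cued
movements: zero-phase 20–120 Hz band-pass, Teager–Kaiser energy operator
(TKEO) to sharpen burst onsets, then a threshold crossing after the 'go' cue.
The threshold is derived automatically from the pre-cue baseline
(median + k · robust SD), replacing per-subject visual selection so runs are
reproducible; ``k`` and the hold time are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .model import TrialEpoch

EMG_BAND_HZ = (20.0, 120.0)
DEFAULT_K = 8.0
DEFAULT_HOLD_S = 0.05
DEFAULT_SMOOTH_S = 0.05
_MAD_TO_SD = 1.4826  # consistency factor: MAD -> SD for a normal distribution


@dataclass
class OnsetDetection:
    trial_index: int
    onset_time_s: float | None
    threshold_used: float
    cue_go_time_s: float
    detected: bool


@dataclass
class EMGFeatures:
    """Scalar EMG features of one epoch.  ``peak_amplitude_uv`` / ``peak_time_ms``
    describe the rectified-envelope TA peak in [0, +4] s relative to onset;
    ``onset_lag_ta_sol_ms`` is SOL burst onset minus TA burst onset."""

    peak_amplitude_uv: float | None
    peak_time_ms: float | None
    onset_lag_ta_sol_ms: float | None


def bandpass_emg(x: np.ndarray, rate_hz: float) -> np.ndarray:
    """Zero-phase second-order Butterworth band-pass, 20–120 Hz corners."""
    if rate_hz <= 2 * EMG_BAND_HZ[1]:
        raise ValueError(
            f"sampling rate {rate_hz} Hz too low for a {EMG_BAND_HZ[1]} Hz corner")
    sos = sps.butter(2, EMG_BAND_HZ, btype="bandpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def downsample_emg(x: np.ndarray, from_hz: float = 1000.0,
                   to_hz: float = 250.0) -> np.ndarray:
    """Anti-aliased decimation (default 1000 -> 250 Hz, factor 4)."""
    ratio = from_hz / to_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"rate ratio {from_hz}/{to_hz} must be an integer")
    # zero-phase FIR anti-aliasing with mean-padding: unit DC gain and no
    # boundary droop, so constants survive exactly
    return sps.resample_poly(x, 1, int(round(ratio)), padtype="mean")


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager–Kaiser energy: psi[n] = x[n]^2 - x[n-1]*x[n+1]; endpoints 0.

    Homogeneous of degree 2 (psi(a*x) = a^2 psi(x)); for A*sin(w*n) the
    interior values equal A^2 sin^2(w) up to O(w^4).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("TKEO needs at least 3 samples")
    psi = np.zeros_like(x)
    psi[..., 1:-1] = x[..., 1:-1] ** 2 - x[..., :-2] * x[..., 2:]
    return psi


def smooth_energy(energy: np.ndarray, rate_hz: float,
                  window_s: float = DEFAULT_SMOOTH_S) -> np.ndarray:
    """Centered moving average of the energy series."""
    w = max(int(round(window_s * rate_hz)), 1)
    return uniform_filter1d(np.asarray(energy, dtype=float), size=w, mode="nearest")


def auto_threshold(energy_baseline: np.ndarray, k: float = DEFAULT_K) -> float:
    """Threshold = baseline median + k * (robust SD via MAD).

    ``energy_baseline`` should be the *smoothed* TKEO over a quiet pre-'ready'
    stretch (>= 0.5 s).  Affinely equivariant: scaling the energy by c scales
    the threshold by c.
    """
    e = np.asarray(energy_baseline, dtype=float)
    if e.size == 0:
        raise ValueError("empty baseline window")
    med = float(np.median(e))
    mad = float(np.median(np.abs(e - med)))
    return med + k * _MAD_TO_SD * mad


def detect_onset(
    energy: np.ndarray,
    go_time_s: float,
    rate_hz: float,
    threshold: float,
    min_hold_s: float = DEFAULT_HOLD_S,
    baseline_median: float = 0.0,
    backtrack_frac: float = 0.15,
    trial_index: int = 0,
    search_window_s: float = 4.0,
    smooth_s: float = DEFAULT_SMOOTH_S,
) -> OnsetDetection:
    """Double-threshold onset detection on the TKEO series after the 'go' cue.

    A burst is *confirmed* at the first sample after ``go_time_s`` where the
    50 ms-smoothed energy exceeds ``threshold`` and at least half of the raw
    energy samples in the following ``min_hold_s`` do too (the majority
    condition rejects isolated spikes, however large).  The confirmation
    point is then *backtracked* along the smoothed
    energy to where it last left a lower threshold
    ``baseline_median + backtrack_frac * (threshold - baseline_median)``, and
    the onset is the first raw-energy sample above that lower threshold from
    there on.  For an ideal step the detected onset is exactly the first
    supra-threshold sample.  No confirmation inside the search window is a
    QC outcome (``detected=False``), not an error.
    """
    e = np.asarray(energy, dtype=float)
    n = e.size
    hold = max(int(round(min_hold_s * rate_hz)), 1)
    start = int(np.ceil(go_time_s * rate_hz))
    stop = min(n, int(np.floor((go_time_s + search_window_s) * rate_hz)))
    if start >= n:
        return OnsetDetection(trial_index, None, threshold, go_time_s, False)
    sm = smooth_energy(e, rate_hz, smooth_s)
    frac_above = uniform_filter1d((e > threshold).astype(float), size=hold,
                                  mode="constant", origin=-(hold // 2))
    confirmed = np.flatnonzero((sm[start:stop] > threshold)
                               & (frac_above[start:stop] >= 0.5))
    if confirmed.size == 0:
        return OnsetDetection(trial_index, None, threshold, go_time_s, False)
    ic = start + int(confirmed[0])
    lower = baseline_median + backtrack_frac * (threshold - baseline_median)
    j = ic
    while j > start and sm[j - 1] > lower:
        j -= 1
    seg = np.flatnonzero(e[j:stop] > lower)
    i0 = j + int(seg[0]) if seg.size else ic
    return OnsetDetection(trial_index, float(i0 / rate_hz), threshold,
                          go_time_s, True)


def detect_session_onsets(
    session,
    k: float = DEFAULT_K,
    min_hold_s: float = DEFAULT_HOLD_S,
    threshold_override: float | None = None,
) -> tuple[list[OnsetDetection], float]:
    """Per-trial movement onsets from the dominant-leg TA channel.

    One subject-level threshold is derived from the concatenated quiet
    pre-'ready' stretches ([ready-3, ready-0.2] s of each trial) of the
    smoothed TKEO, as median + k·MAD-SD; pass ``threshold_override`` to mimic
    a manually chosen value.  Detection runs at the native 1000 Hz before any
    downsampling; onsets are reported in seconds on the session clock.
    """
    fs = session.emg_rate
    ta = session.emg_channel("TA_left" if session.dominant_foot == "left"
                             else "TA_right")
    e = tkeo(bandpass_emg(ta, fs))
    sm = smooth_energy(e, fs)
    base_chunks = []
    for ready, _go in session.cues:
        i0 = max(int((ready - 3.0) * fs), 0)
        i1 = max(int((ready - 0.2) * fs), 0)
        if i1 > i0:
            base_chunks.append(sm[i0:i1])
    if not base_chunks:
        raise ValueError("no pre-'ready' baseline available")
    baseline = np.concatenate(base_chunks)
    base_med = float(np.median(baseline))
    threshold = (threshold_override if threshold_override is not None
                 else auto_threshold(baseline, k=k))
    detections = []
    for ti, (_ready, go) in enumerate(session.cues):
        detections.append(detect_onset(
            e, go, fs, threshold, min_hold_s=min_hold_s,
            baseline_median=base_med, trial_index=ti))
    return detections, threshold


def session_envelopes(session) -> dict[str, np.ndarray]:
    """Rectified low-pass envelopes of all four EMG channels, decimated to
    the EEG rate so they align sample-for-sample with EEG epochs."""
    out = {}
    q = session.emg_rate / session.eeg_rate
    for name in ("TA_left", "TA_right", "SOL_left", "SOL_right"):
        env = envelope(bandpass_emg(session.emg_channel(name), session.emg_rate),
                       session.emg_rate)
        out[name] = downsample_emg(env, session.emg_rate, session.emg_rate / q) \
            if q > 1 else env
    return out


def envelope(x_bandpassed: np.ndarray, rate_hz: float,
             lowpass_hz: float = 6.0) -> np.ndarray:
    """Rectify then zero-phase low-pass: the amplitude envelope used for the
    EMG feature set and for plotting (normalization is display-only)."""
    sos = sps.butter(2, lowpass_hz, btype="lowpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, np.abs(x_bandpassed), axis=-1)


def _envelope_onset_s(env: np.ndarray, times: np.ndarray, frac: float = 0.5,
                      search_s: tuple[float, float] = (-0.5, 4.0),
                      baseline_s: tuple[float, float] = (-4.0, -2.0)) -> float | None:
    """Burst onset as the first half-rise crossing of the envelope.

    The threshold is referenced to the quiet-baseline level (median over
    ``baseline_s``) so the resting envelope of band-limited noise cannot
    trigger it: thr = base + frac·(peak − base), searched inside
    ``search_s``.  Using the same fractional rise for both muscles makes the
    TA–SOL lag insensitive to the smoothing-induced rise time.
    """
    sel = (times >= search_s[0]) & (times <= search_s[1])
    base_sel = (times >= baseline_s[0]) & (times < baseline_s[1])
    if not sel.any():
        return None
    base = float(np.median(env[base_sel])) if base_sel.any() else 0.0
    peak = float(np.max(env[sel]))
    if not np.isfinite(peak) or peak - base <= 0:
        return None
    thr = base + frac * (peak - base)
    idx = np.flatnonzero(env[sel] > thr)
    if idx.size == 0:
        return None
    return float(times[sel][idx[0]])


def emg_features(epoch: TrialEpoch) -> EMGFeatures:
    """TA envelope peak (amplitude, time) within [0, +4] s and TA–SOL onset lag.

    A flat or missing envelope yields missing features rather than an error;
    the SOL lag is missing whenever either muscle has no detectable burst.
    """
    if epoch.emg_ta_envelope is None:
        return EMGFeatures(None, None, None)
    times = epoch.times
    ta = np.asarray(epoch.emg_ta_envelope, dtype=float)
    win = (times >= 0.0) & (times <= 4.0)
    ta_win = ta[win]
    if ta_win.size == 0 or np.ptp(ta_win) <= 0:
        return EMGFeatures(None, None, None)
    i = int(np.argmax(ta_win))
    peak_uv = float(ta_win[i])
    peak_ms = float(times[win][i] * 1000.0)

    lag_ms: float | None = None
    if epoch.emg_sol_envelope is not None:
        sol = np.asarray(epoch.emg_sol_envelope, dtype=float)
        t_ta = _envelope_onset_s(ta, times)
        t_sol = _envelope_onset_s(sol, times) if np.ptp(sol) > 0 else None
        if t_ta is not None and t_sol is not None:
            lag_ms = (t_sol - t_ta) * 1000.0
    return EMGFeatures(peak_uv, peak_ms, lag_ms)
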