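"""Single-trial MRCP features, grand averages, variability, topography.

Five features are computed per trial on one channel (Cz by default, over the
leg area of M1): peak negativity and its time, the early (NS1) and late (NS2)
pre-movement slopes of the Bereitschaftspotential, and the post-peak rebound
rate.  Two EMG-linked features complete the set: the TA envelope peak and the
MRCP-peak-to-EMG-peak latency.  All amplitude reads use the nearest sample
(4 ms resolution, far below the feature time scales); no interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emg import EMGFeatures, emg_features
from .model import EEG_RATE_HZ, GO_WINDOW_S, Montage, TrialEpoch

#: Search window for the peak negativity, closed, seconds relative to onset.
PEAK_SEARCH_WINDOW_S = (-1.0, 1.5)
#: Trials whose peak time falls outside this closed window are outliers.
OUTLIER_WINDOW_MS = (-1500.0, 2000.0)
#: Floor on |mean| in the coefficient-of-variation ratio, µV.
COV_EPS_UV = 0.1


@dataclass
class MRCPFeatureSet:
    subject_id: str
    trial_index: int
    channel: str
    peak_negativity_uv: float
    peak_time_ms: float
    ns1_uv_per_s: float
    ns2_uv_per_s: float
    rebound_uv_per_s: float | None
    latency_mrcp_emg_ms: float | None
    emg_peak_uv: float | None
    emg_peak_time_ms: float | None
    ta_sol_lag_ms: float | None
    outlier: bool


def peak_negativity(epoch: TrialEpoch, channel: str = "Cz") -> tuple[float, float]:
    """Minimum value and its time (ms) in the closed window [-1, +1.5] s.

    Ties break to the earliest time.
    """
    lo = epoch.sample_index(PEAK_SEARCH_WINDOW_S[0])
    hi = epoch.sample_index(PEAK_SEARCH_WINDOW_S[1])
    x = epoch.channel(channel)[lo:hi + 1]
    i = int(np.argmin(x))  # argmin returns the first (earliest) minimum
    return float(x[i]), float(epoch.times[lo + i] * 1000.0)


def ns1(epoch: TrialEpoch, channel: str, peak_time_s: float) -> float:
    """Early slope: [x(peak-0.4 s) - x(peak-1.4 s)] / 1.0 s, µV/s.

    Negative when the potential grows more negative toward the peak.
    """
    return (epoch.value_at(channel, peak_time_s - 0.4)
            - epoch.value_at(channel, peak_time_s - 1.4)) / 1.0


def ns2(epoch: TrialEpoch, channel: str, peak_time_s: float,
        peak_amplitude_uv: float) -> float:
    """Late slope: [peak - x(peak-0.4 s)] / 0.4 s, µV/s."""
    return (peak_amplitude_uv - epoch.value_at(channel, peak_time_s - 0.4)) / 0.4


def rebound_rate(epoch: TrialEpoch, channel: str, peak_time_s: float,
                 peak_amplitude_uv: float) -> float | None:
    """Recovery slope: [x(peak+1.5 s) - peak] / 1.5 s; positive = recovery.

    Missing (None) when the epoch does not reach peak+1.5 s.
    """
    t = peak_time_s + 1.5
    if t >= epoch.times[-1] + 0.5 / 250.0:
        return None
    return (epoch.value_at(channel, t) - peak_amplitude_uv) / 1.5


def flag_outlier(peak_time_ms: float) -> bool:
    """True iff the peak time lies outside the closed window [-1.5, 2] s."""
    return peak_time_ms < OUTLIER_WINDOW_MS[0] or peak_time_ms > OUTLIER_WINDOW_MS[1]


def latency_mrcp_emg(peak_time_ms: float, emg_peak_time_ms: float) -> float:
    """MRCP peak time minus EMG-TA peak time (ms); negative when the cortical
    peak precedes the muscular one."""
    return peak_time_ms - emg_peak_time_ms


def compute_features(epoch: TrialEpoch, channel: str = "Cz") -> MRCPFeatureSet:
    """All MRCP and EMG features of one epoch."""
    amp, t_ms = peak_negativity(epoch, channel)
    t_s = t_ms / 1000.0
    emg: EMGFeatures = emg_features(epoch)
    latency = None
    if emg.peak_time_ms is not None:
        latency = latency_mrcp_emg(t_ms, emg.peak_time_ms)
    return MRCPFeatureSet(
        subject_id=epoch.subject_id,
        trial_index=epoch.trial_index,
        channel=channel,
        peak_negativity_uv=amp,
        peak_time_ms=t_ms,
        ns1_uv_per_s=ns1(epoch, channel, t_s),
        ns2_uv_per_s=ns2(epoch, channel, t_s, amp),
        rebound_uv_per_s=rebound_rate(epoch, channel, t_s, amp),
        latency_mrcp_emg_ms=latency,
        emg_peak_uv=emg.peak_amplitude_uv,
        emg_peak_time_ms=emg.peak_time_ms,
        ta_sol_lag_ms=emg.onset_lag_ta_sol_ms,
        outlier=flag_outlier(t_ms),
    )


def features_table(features: list[MRCPFeatureSet]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in features])


def grand_average(epochs: list[TrialEpoch],
                  channel: str = "Cz") -> tuple[np.ndarray, np.ndarray, int]:
    """Pointwise mean and SD across trials (population convention, so a
    single trial has SD exactly 0)."""
    if not epochs:
        raise ValueError("no epochs")
    data = np.stack([ep.channel(channel) for ep in epochs])
    return data.mean(axis=0), data.std(axis=0, ddof=0), data.shape[0]


def coefficient_of_variation(
    epochs: list[TrialEpoch],
    channel: str = "Cz",
    window_s: tuple[float, float] = GO_WINDOW_S,
    eps_uv: float = COV_EPS_UV,
    mode: str = "waveform",
) -> float:
    """Across-trial variability of the MRCP waveform.

    ``mode='waveform'`` (default): mean over time points t in the 'Go'
    window of SD(t) / max(|mean(t)|, eps) — the pointwise SD-over-mean ratio
    with a small floor so zero crossings of the mean cannot blow the ratio
    up.  Alternatives: ``'peak_amplitude'`` / ``'peak_time'`` give the plain
    CoV (SD/|mean|) of the per-trial scalar feature.
    """
    if len(epochs) < 2:
        raise ValueError("need at least 2 epochs")
    if mode in ("peak_amplitude", "peak_time"):
        vals = []
        for ep in epochs:
            amp, t_ms = peak_negativity(ep, channel)
            vals.append(amp if mode == "peak_amplitude" else t_ms)
        vals = np.asarray(vals)
        m = float(np.mean(vals))
        return float(np.std(vals, ddof=0) / max(abs(m), eps_uv))
    if mode != "waveform":
        raise ValueError(f"unknown CoV mode {mode!r}")
    data = np.stack([ep.channel(channel) for ep in epochs])
    times = epochs[0].times
    sel = (times >= window_s[0]) & (times < window_s[1])
    mean = data.mean(axis=0)[sel]
    sd = data.std(axis=0, ddof=0)[sel]
    return float(np.mean(sd / np.maximum(np.abs(mean), eps_uv)))


def topo_series(
    epochs: list[TrialEpoch],
    times_s: list[float] | None = None,
    montage: Montage | None = None,
) -> pd.DataFrame:
    """Grand-average amplitude per channel at requested times: the values
    behind a topographic-map time series (default 13 points, -2..+4 s every
    0.5 s).  Index: channel; columns: times (s)."""
    if not epochs:
        raise ValueError("no epochs")
    montage = montage or epochs[0].montage
    if times_s is None:
        times_s = [round(-2.0 + 0.5 * i, 3) for i in range(13)]
    data = np.stack([ep.eeg for ep in epochs]).mean(axis=0)
    times = epochs[0].times
    cols = {}
    for t in times_s:
        # +4.0 s is one sample past the half-open window; clamp to the edge
        idx = int(round((t - times[0]) * EEG_RATE_HZ))
        if idx < 0 or idx > times.size:
            raise IndexError(f"time {t} s outside epoch window")
        cols[t] = data[:, min(idx, times.size - 1)]
    return pd.DataFrame(cols, index=list(montage.channel_names))
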