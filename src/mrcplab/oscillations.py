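"""Spatial filtering, Morlet time-frequency power, ERD/ERS percent maps.

The oscillation path applies a surface small-Laplacian at the motor-cortex
channels (center minus the mean of its four surrounding electrodes, reducing
volume conduction), decomposes each epoch with 5-cycle complex Morlet
wavelets on a 1–50 Hz grid, and expresses trial-averaged power as percent
change relative to the pre-movement baseline [-4, -2] s
(ERD% = 100·(P - B)/B per frequency; negative = desynchronization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import EEG_RATE_HZ, Montage, TrialEpoch

BASELINE_WINDOW_S = (-4.0, -2.0)
DEFAULT_FREQS_HZ = np.arange(1.0, 51.0)
DEFAULT_N_CYCLES = 5.0


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def rows(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.low_hz) & (freqs <= self.high_hz)


#: Default band presets (low/high beta split at 20/21 Hz).
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "low_beta": BandDefinition("low_beta", 13.0, 20.0),
    "high_beta": BandDefinition("high_beta", 21.0, 35.0),
    "beta": BandDefinition("beta", 12.0, 35.0),
}

#: Alternative preset splitting low/high beta at 12–21 / 21–35 Hz.
FIG_CAPTION_BANDS: dict[str, BandDefinition] = {
    **DEFAULT_BANDS,
    "low_beta": BandDefinition("low_beta", 12.0, 21.0),
}


@dataclass
class TFRMap:
    """Time-frequency power of one channel: ``power[f, t]`` in µV²;
    ``edge_valid[f, t]`` is False within 2.5 wavelet cycles of the epoch
    edges, where the convolution is contaminated."""

    channel: str
    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray
    edge_valid: np.ndarray | None = None


@dataclass
class ERDMap:
    """Percent power change relative to the baseline window.  By
    construction the baseline-window mean of every frequency row is 0."""

    channel: str
    freqs: np.ndarray
    times: np.ndarray
    erd_pct: np.ndarray
    baseline_window: tuple[float, float] = BASELINE_WINDOW_S
    significance_mask: np.ndarray | None = None


def small_laplacian(
    eeg: np.ndarray,
    channels: list[str] | tuple[str, ...],
    center: str,
    montage: Montage | None = None,
) -> np.ndarray:
    """Center signal minus the mean of its four surrounding electrodes.

    Linear, and annihilates any signal common to the center and all
    neighbors (common-mode / volume-conduction rejection).
    """
    montage = montage or Montage()
    if center not in montage.laplacian_neighbors:
        raise ValueError(
            f"no Laplacian neighbor set for {center!r}; "
            f"available: {sorted(montage.laplacian_neighbors)}")
    names = list(channels)
    missing = [n for n in (center, *montage.laplacian_neighbors[center])
               if n not in names]
    if missing:
        raise ValueError(f"missing channels for small Laplacian: {missing}")
    eeg = np.asarray(eeg, dtype=float)
    out = eeg[names.index(center)].astype(float).copy()
    for n in montage.laplacian_neighbors[center]:
        out -= eeg[names.index(n)] / 4.0
    return out


def epoch_laplacian(epoch: TrialEpoch, center: str) -> np.ndarray:
    return small_laplacian(epoch.eeg, list(epoch.montage.channel_names),
                           center, epoch.montage)


def _edge_valid(freqs: np.ndarray, times: np.ndarray,
                n_cycles: float) -> np.ndarray:
    """Per-frequency validity mask: False within ``n_cycles/2`` periods of
    either epoch edge."""
    margin = (n_cycles / 2.0) / freqs[:, None]
    return (times[None, :] >= times[0] + margin) & \
           (times[None, :] <= times[-1] - margin)


def morlet_tfr(
    signal: np.ndarray,
    rate_hz: float = EEG_RATE_HZ,
    freqs: np.ndarray | None = None,
    n_cycles: float = DEFAULT_N_CYCLES,
    times: np.ndarray | None = None,
    channel: str = "",
) -> TFRMap:
    """Complex-Morlet power of one time series (``freqs`` × time, µV²).

    Wavelets are zero-mean and energy-normalized; a unit sinusoid at
    frequency f produces a power ridge whose frequency argmax is f on the
    default 1 Hz grid.  The signal must be long enough for ``n_cycles``
    of the lowest frequency; shorter edge regions are flagged in
    ``edge_valid`` rather than silently reported.
    """
    from mne.time_frequency import tfr_array_morlet

    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("morlet_tfr expects a single time series")
    freqs = DEFAULT_FREQS_HZ if freqs is None else np.asarray(freqs, dtype=float)
    if x.size < n_cycles * rate_hz / freqs.min():
        raise ValueError(
            f"signal too short for {n_cycles} cycles at {freqs.min()} Hz")
    power = tfr_array_morlet(
        x[None, None, :], sfreq=rate_hz, freqs=freqs, n_cycles=n_cycles,
        zero_mean=True, output="power", verbose="error")[0, 0]
    if times is None:
        times = np.arange(x.size) / rate_hz
    return TFRMap(channel=channel, freqs=freqs, times=np.asarray(times),
                  power=power, edge_valid=_edge_valid(freqs, times, n_cycles))


def morlet_trials(
    trials: np.ndarray,
    rate_hz: float = EEG_RATE_HZ,
    freqs: np.ndarray | None = None,
    n_cycles: float = DEFAULT_N_CYCLES,
    crop_pad: int = 0,
) -> np.ndarray:
    """Morlet power for a stack of single-channel trials
    (``(n_trials, n_times)`` -> ``(n_trials, n_freqs, n_times)``).

    When the trials carry ``crop_pad`` samples of decomposition context on
    each side (see ``preprocess.cut_padded_windows``), the pad is cropped
    from the returned power so all remaining columns are edge-clean.
    """
    from mne.time_frequency import tfr_array_morlet

    trials = np.asarray(trials, dtype=float)
    freqs = DEFAULT_FREQS_HZ if freqs is None else np.asarray(freqs, dtype=float)
    power = tfr_array_morlet(
        trials[:, None, :], sfreq=rate_hz, freqs=freqs, n_cycles=n_cycles,
        zero_mean=True, output="power", verbose="error")[:, 0]
    if crop_pad > 0:
        power = power[:, :, crop_pad:-crop_pad]
    return power


def erd_ers(
    trials_power: np.ndarray | list[TFRMap],
    times: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    baseline_window: tuple[float, float] = BASELINE_WINDOW_S,
    channel: str = "",
) -> ERDMap:
    """Percent-change map from single-trial power maps.

    Power is averaged across trials first, then each frequency row is
    normalized by its mean baseline power:
    ERD%(f, t) = 100 · (P(f, t) − B(f)) / B(f).  Scale-invariant; the
    baseline-window mean of every row is 0 by construction.
    """
    if isinstance(trials_power, list):
        if not trials_power:
            raise ValueError("need at least one trial")
        times = trials_power[0].times
        freqs = trials_power[0].freqs
        channel = channel or trials_power[0].channel
        stack = np.stack([m.power for m in trials_power])
    else:
        stack = np.asarray(trials_power, dtype=float)
        if times is None or freqs is None:
            raise ValueError("times and freqs required with an array input")
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("trials_power must be (n_trials, n_freqs, n_times)")
    mean_power = stack.mean(axis=0)
    sel = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not np.any(sel):
        raise ValueError("baseline window outside the epoch")
    baseline = mean_power[:, sel].mean(axis=1)
    bad = np.flatnonzero(baseline <= 0)
    if bad.size:
        raise ValueError(f"zero baseline power at {freqs[bad[0]]} Hz")
    erd = 100.0 * (mean_power - baseline[:, None]) / baseline[:, None]
    return ERDMap(channel=channel, freqs=np.asarray(freqs),
                  times=np.asarray(times), erd_pct=erd,
                  baseline_window=baseline_window)


def band_summary(erd: ERDMap, band: BandDefinition,
                 window_s: tuple[float, float]) -> float:
    """Mean ERD% over the band's frequency rows and the window's columns."""
    rows = band.rows(erd.freqs)
    cols = (erd.times >= window_s[0]) & (erd.times < window_s[1])
    if not rows.any() or not cols.any():
        raise ValueError("band or window outside the map grid")
    return float(erd.erd_pct[np.ix_(rows, cols)].mean())


def erd_long_table(erd: ERDMap) -> pd.DataFrame:
    """Long-format export: (channel, freq_hz, time_s, erd_pct, significant)."""
    f_grid, t_grid = np.meshgrid(erd.freqs, erd.times, indexing="ij")
    sig = erd.significance_mask if erd.significance_mask is not None \
        else np.zeros_like(erd.erd_pct, dtype=bool)
    return pd.DataFrame({
        "channel": erd.channel,
        "freq_hz": f_grid.ravel(),
        "time_s": t_grid.ravel(),
        "erd_pct": erd.erd_pct.ravel(),
        "significant": sig.ravel(),
    })
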