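"""Shared data model: montage, raw sessions, and onset-locked trial epochs.

The recording layout mirrors a cued ankle-dorsiflexion protocol: 17 scalp EEG
channels of the 10-20 system sampled at 250 Hz, four surface EMG channels
(tibialis anterior and soleus, both legs) at 1000 Hz, and per-trial
'ready'/'go' auditory cues 2 s apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

#: The 17 EEG channels, in canonical order.
EEG_CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "AF3", "AF4", "F3", "Fz", "F4", "FC1", "FC2",
    "C3", "Cz", "C4", "CP1", "CP2", "P3", "Pz", "P4",
)

#: EMG channels: tibialis anterior and soleus, left/right.
EMG_CHANNELS: tuple[str, ...] = ("TA_left", "TA_right", "SOL_left", "SOL_right")

#: (left, right) mirror pairs; midline channels (Fz, Cz, Pz) have no pair.
LATERAL_PAIRS: tuple[tuple[str, str], ...] = (
    ("FP1", "FP2"), ("AF3", "AF4"), ("F3", "F4"), ("FC1", "FC2"),
    ("C3", "C4"), ("CP1", "CP2"), ("P3", "P4"),
)

# Small-Laplacian neighbor sets for the three motor-cortex centers.  The true
# orthogonal neighbors (FCz, CPz, FC5/FC6, ...) are not part of the 17-channel
# montage, so the nearest available members stand in; override via Montage.
LAPLACIAN_NEIGHBORS: dict[str, tuple[str, str, str, str]] = {
    "Cz": ("C3", "C4", "Fz", "Pz"),
    "FC1": ("F3", "Fz", "C3", "Cz"),
    "FC2": ("F4", "Fz", "C4", "Cz"),
}

# Approximate 2-D scalp coordinates (x: left-negative, y: anterior-positive),
# used for topographic table ordering and plotting only.
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "FP1": (-0.31, 0.95), "FP2": (0.31, 0.95),
    "AF3": (-0.35, 0.75), "AF4": (0.35, 0.75),
    "F3": (-0.45, 0.55), "Fz": (0.0, 0.58), "F4": (0.45, 0.55),
    "FC1": (-0.22, 0.30), "FC2": (0.22, 0.30),
    "C3": (-0.55, 0.0), "Cz": (0.0, 0.0), "C4": (0.55, 0.0),
    "CP1": (-0.22, -0.30), "CP2": (0.22, -0.30),
    "P3": (-0.45, -0.55), "Pz": (0.0, -0.58), "P4": (0.45, -0.55),
}

EEG_RATE_HZ = 250.0
EMG_RATE_HZ = 1000.0

#: Onset-locked epoch window, half-open: [-4 s, +4 s) at 250 Hz = 2000 samples.
EPOCH_WINDOW_S = (-4.0, 4.0)
EPOCH_N_SAMPLES = 2000
#: The sub-window reported to users ('Go' window).
GO_WINDOW_S = (-2.0, 4.0)


class Group(str, Enum):
    """Participant group; FOG severity is carried in the label so three-group
    and severity analyses share one code path with different group maps."""

    HC = "HC"
    PD_NOFOG = "PD_noFOG"
    PD_MILDFOG = "PD_mildFOG"
    PD_SEVEREFOG = "PD_severeFOG"


class MontageError(ValueError):
    """Channel set does not match the 17-channel montage."""


@dataclass(frozen=True)
class Montage:
    """The 17-channel 10-20 montage with Laplacian neighbor sets."""

    channel_names: tuple[str, ...] = EEG_CHANNELS
    positions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CHANNEL_POSITIONS))
    laplacian_neighbors: dict[str, tuple[str, str, str, str]] = field(
        default_factory=lambda: dict(LAPLACIAN_NEIGHBORS))
    lateral_pairs: tuple[tuple[str, str], ...] = LATERAL_PAIRS

    def __post_init__(self) -> None:
        if set(self.channel_names) != set(EEG_CHANNELS):
            missing = set(EEG_CHANNELS) - set(self.channel_names)
            extra = set(self.channel_names) - set(EEG_CHANNELS)
            raise MontageError(
                f"montage mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for center, nbrs in self.laplacian_neighbors.items():
            if len(nbrs) != 4:
                raise MontageError(f"{center}: need exactly 4 Laplacian neighbors")
            for n in nbrs:
                if n not in self.channel_names:
                    raise MontageError(f"Laplacian neighbor {n} not in montage")
        for left, right in self.lateral_pairs:
            if left not in self.channel_names or right not in self.channel_names:
                raise MontageError(f"lateral pair ({left}, {right}) not in montage")

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise MontageError(f"montage mismatch: missing channel {name}") from None


DEFAULT_MONTAGE = Montage()


@dataclass
class RawSession:
    """A continuous multi-rate EEG+EMG recording with cue annotations.

    EEG is ``(17, n)`` in microvolt at ``eeg_rate``; EMG is ``(4, m)`` in
    microvolt at ``emg_rate`` ordered per :data:`EMG_CHANNELS`.  ``cues`` holds
    ``(ready_time_s, go_time_s)`` pairs on the shared session clock.
    """

    subject_id: str
    group: Group
    dominant_foot: str  # "left" | "right"
    eeg: np.ndarray
    emg: np.ndarray
    cues: list[tuple[float, float]]
    eeg_rate: float = EEG_RATE_HZ
    emg_rate: float = EMG_RATE_HZ
    montage: Montage = field(default_factory=lambda: DEFAULT_MONTAGE)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.ndim != 2 or self.eeg.shape[0] != len(self.montage.channel_names):
            raise MontageError(
                f"EEG must be ({len(self.montage.channel_names)}, n); got {self.eeg.shape}")
        if self.emg.ndim != 2 or self.emg.shape[0] != len(EMG_CHANNELS):
            raise ValueError(f"EMG must be (4, m); got {self.emg.shape}")
        if self.dominant_foot not in ("left", "right"):
            raise ValueError(f"dominant_foot must be 'left' or 'right', got {self.dominant_foot!r}")
        one_sample = 1.0 / self.eeg_rate
        for ready, go in self.cues:
            if abs((go - ready) - 2.0) > one_sample:
                raise ValueError(
                    f"cue pair ({ready}, {go}): 'go' must follow 'ready' by 2 s")

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate

    def channel(self, name: str) -> np.ndarray:
        return self.eeg[self.montage.index(name)]

    def emg_channel(self, name: str) -> np.ndarray:
        return self.emg[EMG_CHANNELS.index(name)]


def flip_lateral_channels(session: RawSession) -> RawSession:
    """Swap left/right EEG channels for left-foot-dominant participants.

    Analyses are expressed for a right-dominant foot; for left-dominant
    participants every lateral pair is swapped so that "contralateral" always
    means the same channel.  Midline channels are untouched; for
    right-dominant sessions this is the identity (a copy).  Involution: two
    applications restore the input.
    """
    eeg = session.eeg.copy()
    if session.dominant_foot == "left":
        for left, right in session.montage.lateral_pairs:
            li, ri = session.montage.index(left), session.montage.index(right)
            eeg[[li, ri]] = eeg[[ri, li]]
    return replace(session, eeg=eeg, emg=session.emg.copy(),
                   cues=list(session.cues))


@dataclass
class TrialEpoch:
    """Onset-locked EEG segment with aligned EMG envelopes.

    The time axis spans [-4, +4) s relative to the EMG-derived movement onset
    at 250 Hz (2000 samples); index 1000 is exactly t = 0.  Envelopes are the
    rectified low-passed EMG of the dominant leg, resampled to the same axis.
    """

    subject_id: str
    trial_index: int
    onset_time_s: float
    eeg: np.ndarray                      # (n_channels, 2000)
    times: np.ndarray                    # (2000,) seconds relative to onset
    emg_ta_envelope: np.ndarray | None = None
    emg_sol_envelope: np.ndarray | None = None
    emg_ta_contra_envelope: np.ndarray | None = None
    qc_flags: set[str] = field(default_factory=set)
    montage: Montage = field(default_factory=lambda: DEFAULT_MONTAGE)

    def channel(self, name: str) -> np.ndarray:
        return self.eeg[self.montage.index(name)]

    def sample_index(self, t_s: float) -> int:
        """Nearest-sample index for a time (s) relative to onset."""
        i = int(round((t_s - self.times[0]) * EEG_RATE_HZ))
        if i < 0 or i >= self.times.size:
            raise IndexError(f"time {t_s} s outside epoch window")
        return i

    def value_at(self, channel: str, t_s: float) -> float:
        return float(self.channel(channel)[self.sample_index(t_s)])


def epoch_times() -> np.ndarray:
    """The canonical epoch time axis: 2000 samples, [-4, +4) s at 250 Hz."""
    return np.arange(EPOCH_N_SAMPLES) / EEG_RATE_HZ + EPOCH_WINDOW_S[0]
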