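"""Minimal EDF reader/writer for raw EEG+EMG sessions.

Plain EDF (16-bit) with 1-second data records and per-channel sampling rates,
which is how mixed 250 Hz EEG / 1000 Hz EMG recordings are conventionally
stored.  Cue annotations live in a sidecar tab-separated table
(``<name>.annotations.tsv``, columns ``event``/``time_s``) and subject
metadata in a sidecar YAML (``<name>.meta.yaml``) holding subject id, group,
dominant foot and the unpadded sample counts.

Samples round-trip within the 16-bit quantization of each channel's physical
range; annotations and metadata round-trip exactly.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from .model import (
    EEG_CHANNELS,
    EMG_CHANNELS,
    Group,
    Montage,
    MontageError,
    RawSession,
)

_DIG_MAX = 32767


class EDFFormatError(IOError):
    """File is not a readable EDF of the expected layout."""


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _fmt_phys(value: float) -> str:
    """Format a physical bound into EDF's 8-char field (and keep it parseable)."""
    for fmt in ("%.6g", "%.4g", "%.2g"):
        s = fmt % value
        if len(s) <= 8:
            return s
    return "%.1e" % value


def annotations_path_for(path: str | Path) -> Path:
    return Path(path).with_suffix(".annotations.tsv")


def metadata_path_for(path: str | Path) -> Path:
    return Path(path).with_suffix(".meta.yaml")


def write_session(session: RawSession, path: str | Path,
                  annotations_path: str | Path | None = None) -> None:
    """Write a session as EDF plus sidecar annotation/metadata files."""
    path = Path(path)
    if annotations_path is None:
        annotations_path = annotations_path_for(path)

    eeg_spr = int(round(session.eeg_rate))     # samples per 1-s record
    emg_spr = int(round(session.emg_rate))
    n_eeg, n_emg = session.eeg.shape[1], session.emg.shape[1]
    n_records = max(math.ceil(n_eeg / eeg_spr), math.ceil(n_emg / emg_spr), 1)

    labels = list(EEG_CHANNELS) + list(EMG_CHANNELS)
    sprs = [eeg_spr] * len(EEG_CHANNELS) + [emg_spr] * len(EMG_CHANNELS)
    signals = [session.eeg[i] for i in range(len(EEG_CHANNELS))] + \
              [session.emg[i] for i in range(len(EMG_CHANNELS))]

    # Symmetric physical range per channel; use the value as re-parsed from
    # the 8-char header field so the reader's scaling matches the writer's.
    phys_max = []
    for x in signals:
        p = float(np.max(np.abs(x))) if x.size else 0.0
        p = max(p, 1.0)
        phys_max.append(float(_fmt_phys(p)))

    ns = len(labels)
    header = bytearray()
    header += _pad("0", 8)
    header += _pad(f"subject={session.subject_id}", 80)
    header += _pad("cued ankle dorsiflexion EEG+EMG", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)                      # record duration, seconds
    header += _pad(str(ns), 4)
    for lab in labels:
        header += _pad(lab, 16)
    for _ in labels:
        header += _pad("", 80)                  # transducer
    for _ in labels:
        header += _pad("uV", 8)
    for p in phys_max:
        header += _pad(_fmt_phys(-p), 8)
    for p in phys_max:
        header += _pad(_fmt_phys(p), 8)
    for _ in labels:
        header += _pad(str(-_DIG_MAX), 8)
    for _ in labels:
        header += _pad(str(_DIG_MAX), 8)
    for _ in labels:
        header += _pad("", 80)                  # prefiltering
    for spr in sprs:
        header += _pad(str(spr), 8)
    for _ in labels:
        header += _pad("", 32)

    # Digitize with zero-padded tails so every record is complete.
    dig = []
    for x, spr, p in zip(signals, sprs, phys_max):
        full = np.zeros(n_records * spr)
        full[: x.size] = x
        d = np.clip(np.round(full / p * _DIG_MAX), -_DIG_MAX, _DIG_MAX)
        dig.append(d.astype("<i2").reshape(n_records, spr))

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            for d in dig:
                fh.write(d[r].tobytes())

    with open(annotations_path, "w") as fh:
        fh.write("event\ttime_s\n")
        for ready, go in session.cues:
            fh.write(f"ready\t{ready:.6f}\n")
            fh.write(f"go\t{go:.6f}\n")

    meta = {
        "subject_id": session.subject_id,
        "group": session.group.value,
        "dominant_foot": session.dominant_foot,
        "n_samples_eeg": int(n_eeg),
        "n_samples_emg": int(n_emg),
    }
    with open(metadata_path_for(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_session(path: str | Path,
                 annotations_path: str | Path | None = None,
                 montage: Montage | None = None) -> RawSession:
    """Read an EDF session written by :func:`write_session`.

    Channels are returned in canonical montage order regardless of file
    order; a missing montage channel raises :class:`MontageError`.
    """
    path = Path(path)
    if annotations_path is None:
        annotations_path = annotations_path_for(path)
    montage = montage or Montage()

    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFFormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise EDFFormatError(f"{path}: unreadable EDF header: {exc}") from exc
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise EDFFormatError(f"{path}: truncated signal headers")

        def field(offset: int, width: int, i: int) -> str:
            start = offset * ns + i * width
            return sig[start: start + width].decode("ascii").strip()

        labels, pmins, pmaxs, dmins, dmaxs, sprs = [], [], [], [], [], []
        try:
            for i in range(ns):
                labels.append(field(0, 16, i))
                pmins.append(float(field(16 + 80 + 8, 8, i)))
                pmaxs.append(float(field(16 + 80 + 8 + 8, 8, i)))
                dmins.append(int(field(16 + 80 + 8 + 16, 8, i)))
                dmaxs.append(int(field(16 + 80 + 8 + 24, 8, i)))
                sprs.append(int(field(16 + 80 + 8 + 32 + 80, 8, i)))
        except ValueError as exc:
            raise EDFFormatError(f"{path}: unreadable signal header: {exc}") from exc

        rec_len = sum(sprs)
        raw = np.frombuffer(fh.read(n_records * rec_len * 2), dtype="<i2")
        if raw.size < n_records * rec_len:
            raise EDFFormatError(f"{path}: truncated data records")

    raw = raw.reshape(n_records, rec_len)
    data, col = [], 0
    for i in range(ns):
        d = raw[:, col: col + sprs[i]].reshape(-1).astype(float)
        col += sprs[i]
        scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        data.append((d - dmins[i]) * scale + pmins[i])

    by_label = dict(zip(labels, range(ns)))
    for name in montage.channel_names:
        if name not in by_label:
            raise MontageError(f"montage mismatch: missing channel {name}")
    for name in EMG_CHANNELS:
        if name not in by_label:
            raise EDFFormatError(f"{path}: missing EMG channel {name}")

    meta_path = metadata_path_for(path)
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
    else:
        meta = {"subject_id": path.stem, "group": "HC", "dominant_foot": "right"}

    eeg_rate = sprs[by_label[montage.channel_names[0]]] / record_dur
    emg_rate = sprs[by_label[EMG_CHANNELS[0]]] / record_dur
    n_eeg = int(meta.get("n_samples_eeg", n_records * int(eeg_rate * record_dur)))
    n_emg = int(meta.get("n_samples_emg", n_records * int(emg_rate * record_dur)))

    eeg = np.stack([data[by_label[n]][:n_eeg] for n in montage.channel_names])
    emg = np.stack([data[by_label[n]][:n_emg] for n in EMG_CHANNELS])

    cues: list[tuple[float, float]] = []
    ann = Path(annotations_path)
    if ann.exists():
        events: list[tuple[str, float]] = []
        with open(ann) as fh:
            headline = fh.readline()
            if not headline.startswith("event"):
                raise EDFFormatError(f"{ann}: expected 'event\\ttime_s' header")
            for line in fh:
                ev, t = line.rstrip("\n").split("\t")
                events.append((ev, float(t)))
        readies = [t for ev, t in events if ev == "ready"]
        gos = [t for ev, t in events if ev == "go"]
        if len(readies) != len(gos):
            raise EDFFormatError(f"{ann}: unmatched ready/go events")
        cues = list(zip(readies, gos))

    return RawSession(
        subject_id=str(meta["subject_id"]),
        group=Group(meta["group"]),
        dominant_foot=str(meta["dominant_foot"]),
        eeg=eeg,
        emg=emg,
        cues=cues,
        eeg_rate=eeg_rate,
        emg_rate=emg_rate,
        montage=montage,
    )
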