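"""ERD/ERS time-frequency maps over the motor cortex with bootstrap masks.

Oscillation path per subject: 0.05-50 Hz band-pass, trial QC (pre-cue muscle
activity, opposite-leg bursts), surface small-Laplacian at Cz/FC1/FC2,
5-cycle Morlet power on 1-50 Hz computed on 1 s-padded windows, and percent
change relative to the [-4, -2] s baseline pooled per group.  Within-group
significance uses the trial bootstrap on a time-decimated grid.

Writes results/band_summary.tsv; the bulky per-pixel map tables go to
scratch/maps/erd_<group>_<channel>.tsv (regenerable, not archived).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mrcplab.edf import read_session
from mrcplab.emg import detect_session_onsets, session_envelopes
from mrcplab.model import epoch_times, flip_lateral_channels
from mrcplab.oscillations import (
    DEFAULT_BANDS,
    band_summary,
    erd_ers,
    erd_long_table,
    morlet_trials,
    small_laplacian,
)
from mrcplab.preprocess import (
    bandpass_osc,
    cut_padded_windows,
    extract_epochs,
    reject_oscillation_outliers,
    remove_artifact_components,
)
from mrcplab.stats import bootstrap_significance

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
MAPS = ROOT / "scratch" / "maps"

CENTERS = ("Cz", "FC1", "FC2")
FREQS = np.arange(1.0, 51.0)
WINDOWS = {"pre_movement": (-2.0, 0.0), "movement": (0.0, 2.0),
           "post_movement": (2.0, 4.0)}
DECIM = 20


def main() -> None:
    paths = sorted(COHORT_DIR.glob("*.edf"))
    if not paths:
        raise SystemExit("no cohort found - run analysis/01_simulate_cohort.py")
    MAPS.mkdir(parents=True, exist_ok=True)
    times = epoch_times()
    power_by: dict[tuple[str, str], list[np.ndarray]] = {}
    n_rejected = 0
    for path in paths:
        sess = flip_lateral_channels(read_session(path))
        dets, _ = detect_session_onsets(sess)
        envs = session_envelopes(sess)
        side = sess.dominant_foot
        contra = "left" if side == "right" else "right"
        eeg = bandpass_osc(sess.eeg, sess.eeg_rate)
        eeg, _ = remove_artifact_components(eeg, sess.eeg_rate, sess.montage,
                                            seed=0)
        epochs, _ = extract_epochs(
            eeg, dets, sess.eeg_rate, subject_id=sess.subject_id,
            montage=sess.montage, ta_envelope=envs[f"TA_{side}"],
            sol_envelope=envs[f"SOL_{side}"],
            ta_contra_envelope=envs[f"TA_{contra}"])
        go_offsets = {d.trial_index: d.cue_go_time_s - d.onset_time_s
                      for d in dets if d.detected}
        kept, _rep = reject_oscillation_outliers(epochs, go_offsets)
        n_rejected += len(epochs) - len(kept)
        kept_idx = {ep.trial_index for ep in kept}
        for center in CENTERS:
            lap = small_laplacian(eeg, list(sess.montage.channel_names),
                                  center, sess.montage)
            wins, _ = cut_padded_windows(lap, dets, sess.eeg_rate, pad_s=1.0,
                                         trial_indices=kept_idx)
            power_by.setdefault((sess.group.value, center), []).append(
                morlet_trials(wins, sess.eeg_rate, FREQS, crop_pad=250))

    band_rows = []
    for (gname, center), stacks in sorted(power_by.items()):
        stack = np.concatenate(stacks)
        erd = erd_ers(stack, times=times, freqs=FREQS, channel=center)
        mask = bootstrap_significance(stack[:, :, ::DECIM], times[::DECIM],
                                      n_boot=500, seed=0)
        erd.significance_mask = np.repeat(mask, DECIM, axis=1)[:, :times.size]
        long = erd_long_table(erd)
        long = long[long.time_s.isin(times[::DECIM])]
        long.insert(0, "group", gname)
        long.to_csv(MAPS / f"erd_{gname}_{center}.tsv", sep="\t",
                    index=False, float_format="%.5g")
        for band in DEFAULT_BANDS.values():
            for wname, win in WINDOWS.items():
                band_rows.append({
                    "group": gname, "channel": center, "band": band.name,
                    "window": wname, "n_trials": stack.shape[0],
                    "erd_pct": band_summary(erd, band, win)})
    bands = pd.DataFrame(band_rows)
    bands.to_csv(RESULTS / "band_summary.tsv", sep="\t", index=False,
                 float_format="%.6g")

    print(f"{n_rejected} trials rejected by oscillation QC")
    view = bands.query("channel == 'Cz' and window == 'pre_movement'") \
        .pivot(index="group", columns="band", values="erd_pct")
    print("\nPre-movement ERD/ERS over Cz (% change vs baseline):")
    print(view[["theta", "low_beta", "high_beta"]].round(1).to_string())


if __name__ == "__main__":
    main()
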