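"""Single-trial MRCP features over Cz and their group statistics.

For every subject: 0.05-5 Hz zero-phase band-pass, extended-infomax ICA with
automated blink/EMG component rejection, onset-locked [-4, +4) s epochs, and
the five single-trial MRCP features plus the EMG-linked features.  Trials
whose peak time violates the [-1.5, 2] s window are dropped as outliers.
Group comparison: trial-level one-way ANOVA with gated Tukey HSD, plus the
waveform coefficient of variation over Cz/FC1/FC2 and the 13-point
topographic time series.

Writes results/mrcp_features.tsv, results/mrcp_group_summary.tsv,
results/mrcp_tukey.tsv, results/mrcp_cov.tsv, results/topo_series_<group>.tsv.
"""

from pathlib import Path

import pandas as pd

from mrcplab.edf import read_session
from mrcplab.emg import detect_session_onsets, session_envelopes
from mrcplab.model import flip_lateral_channels
from mrcplab.mrcp import (
    coefficient_of_variation,
    compute_features,
    features_table,
    topo_series,
)
from mrcplab.preprocess import bandpass_mrcp, extract_epochs, remove_artifact_components
from mrcplab.stats import feature_group_table

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

FEATURE_COLUMNS = ["peak_negativity_uv", "peak_time_ms", "ns1_uv_per_s",
                   "ns2_uv_per_s", "rebound_uv_per_s", "latency_mrcp_emg_ms",
                   "emg_peak_uv", "emg_peak_time_ms"]


def main() -> None:
    paths = sorted(COHORT_DIR.glob("*.edf"))
    if not paths:
        raise SystemExit("no cohort found - run analysis/01_simulate_cohort.py")
    all_rows = []
    epochs_by_group: dict[str, list] = {}
    for path in paths:
        sess = flip_lateral_channels(read_session(path))
        dets, _ = detect_session_onsets(sess)
        envs = session_envelopes(sess)
        side = sess.dominant_foot
        eeg = bandpass_mrcp(sess.eeg, sess.eeg_rate)
        eeg, _report = remove_artifact_components(eeg, sess.eeg_rate,
                                                  sess.montage, seed=0)
        epochs, _flags = extract_epochs(
            eeg, dets, sess.eeg_rate, subject_id=sess.subject_id,
            montage=sess.montage, ta_envelope=envs[f"TA_{side}"],
            sol_envelope=envs[f"SOL_{side}"])
        feats = [compute_features(ep) for ep in epochs]
        kept = [(f, ep) for f, ep in zip(feats, epochs) if not f.outlier]
        table = features_table([f for f, _ in kept])
        table.insert(1, "group", sess.group.value)
        all_rows.append(table)
        epochs_by_group.setdefault(sess.group.value, []).extend(
            ep for _, ep in kept)

    features = pd.concat(all_rows, ignore_index=True)
    features.to_csv(RESULTS / "mrcp_features.tsv", sep="\t", index=False,
                    float_format="%.6g")
    summary, anovas = feature_group_table(features, FEATURE_COLUMNS)
    summary.to_csv(RESULTS / "mrcp_group_summary.tsv", sep="\t", index=False,
                   float_format="%.6g")
    tukey = pd.DataFrame(
        [{"feature": a.feature, "group_a": ga, "group_b": gb,
          "mean_diff": d, "adj_p": p}
         for a in anovas for ga, gb, d, p in a.tukey_pairs])
    tukey.to_csv(RESULTS / "mrcp_tukey.tsv", sep="\t", index=False,
                 float_format="%.6g")

    cov_rows = []
    for gname, eps in epochs_by_group.items():
        for ch in ("Cz", "FC1", "FC2"):
            cov_rows.append({"group": gname, "channel": ch,
                             "cov": coefficient_of_variation(eps, ch)})
        topo = topo_series(eps)
        topo.insert(0, "channel", topo.index)
        topo.to_csv(RESULTS / f"topo_series_{gname}.tsv", sep="\t",
                    index=False, float_format="%.6g")
    pd.DataFrame(cov_rows).to_csv(RESULTS / "mrcp_cov.tsv", sep="\t",
                                  index=False, float_format="%.6g")

    print(f"{len(features)} non-outlier trials across "
          f"{features.group.nunique()} groups")
    print("\nGroup means (per-trial):")
    print(features.groupby("group")[
        ["peak_negativity_uv", "ns1_uv_per_s", "emg_peak_uv"]]
        .mean().round(2).to_string())
    print("\nANOVA across groups:")
    for a in anovas:
        marker = " *" if a.p <= 0.05 else ""
        print(f"  {a.feature}: F({a.df_between}, {a.df_within}) = "
              f"{a.F:.2f}, p = {a.p:.3g}{marker}")


if __name__ == "__main__":
    main()
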