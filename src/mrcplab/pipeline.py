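"""End-to-end orchestration from a single YAML config.

Stages: synthesize (or load) a cohort -> EMG onset detection -> MRCP path
(0.05–5 Hz, optional ICA, epochs, per-trial features) -> oscillation path
(0.05–50 Hz, Laplacian centers, Morlet power, ERD/ERS, resampling
significance) -> group statistics -> tab-separated tables plus a manifest
recording the config hash, seeds, software version and per-stage trial
bookkeeping (kept + rejected reconciles at every stage).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edf import read_session
from .emg import detect_session_onsets, session_envelopes
from .model import Group, flip_lateral_channels
from .mrcp import (
    coefficient_of_variation,
    compute_features,
    features_table,
    topo_series,
)
from .oscillations import (
    DEFAULT_BANDS,
    FIG_CAPTION_BANDS,
    erd_ers,
    erd_long_table,
    morlet_trials,
    small_laplacian,
)
from .preprocess import (
    bandpass_mrcp,
    bandpass_osc,
    cut_padded_windows,
    extract_epochs,
    reject_oscillation_outliers,
    remove_artifact_components,
)
from .stats import bootstrap_significance, feature_group_table, permutation_difference
from .synth import default_profiles, generate_cohort

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "source": "synth",              # "synth" | "load"
        "data_dir": None,               # directory of .edf files when loading
        "groups": ["HC", "PD_noFOG", "PD_mildFOG", "PD_severeFOG"],
        "n_subjects_per_group": 3,
        "n_trials": 15,
        "trial_spacing_s": 15.0,
        "left_dominant_fraction": 0.0,
    },
    "emg": {
        "threshold_k": 8.0,
        "min_hold_s": 0.05,
    },
    "ica": {
        "enabled": True,
        "blink_corr_threshold": 0.8,
        "emg_power_ratio_threshold": 1.0,
        "max_iter": 1000,
    },
    "mrcp": {
        "enabled": True,
        "channel": "Cz",
        "cov_channels": ["Cz", "FC1", "FC2"],
        "cov_mode": "waveform",
    },
    "oscillations": {
        "enabled": True,
        "centers": ["Cz", "FC1", "FC2"],
        "freq_min_hz": 1.0,
        "freq_max_hz": 50.0,
        "freq_step_hz": 1.0,
        "n_cycles": 5.0,
        "band_preset": "default",       # "default" | "fig_caption"
        "windows": {
            "pre_movement": [-2.0, 0.0],
            "movement": [0.0, 2.0],
            "post_movement": [2.0, 4.0],
        },
        "export_time_decim": 10,
    },
    "stats": {
        "alpha": 0.05,
        "bootstrap": True,
        "n_boot": 1000,
        "permutation_pairs": [],        # e.g. [["HC", "PD_severeFOG"]]
        "n_perm": 1000,
        "time_decim": 20,
    },
}


class ConfigError(ValueError):
    """Config does not validate against the documented schema."""


def _merge_validate(defaults: dict, given: dict, prefix: str = "") -> dict:
    merged = copy.deepcopy(defaults)
    bad = []
    for key, value in given.items():
        if key not in defaults:
            bad.append(prefix + key)
            continue
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            merged[key] = _merge_validate(defaults[key], value, f"{prefix}{key}.")
        else:
            merged[key] = value
    if bad:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(bad))}")
    return merged


def load_config(config: str | Path | dict | None) -> dict:
    if config is None:
        given = {}
    elif isinstance(config, dict):
        given = config
    else:
        with open(config) as fh:
            given = yaml.safe_load(fh) or {}
    try:
        return _merge_validate(DEFAULT_CONFIG, given)
    except ConfigError:
        raise
    except AttributeError as exc:
        raise ConfigError(f"malformed config: {exc}") from exc


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: str | Path | dict | None, out_dir: str | Path) -> Path:
    """Run the full analysis; returns the run directory.

    Writes per-subject onset tables, the per-trial MRCP feature table, group
    summary/ANOVA tables, coefficient-of-variation and topographic tables,
    long-format ERD maps with significance masks, band summaries, and
    ``manifest.json``.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "stages": {},
        "subjects": {},
    }

    # ---- cohort -----------------------------------------------------------
    if cfg["cohort"]["source"] == "synth":
        profiles = default_profiles()
        selected = [profiles[Group(g)] for g in cfg["cohort"]["groups"]]
        sessions, truth = generate_cohort(
            selected, cfg["cohort"]["n_subjects_per_group"],
            n_trials=cfg["cohort"]["n_trials"], seed=seed,
            trial_spacing_s=cfg["cohort"]["trial_spacing_s"],
            left_dominant_fraction=cfg["cohort"]["left_dominant_fraction"])
        truth.trials.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    elif cfg["cohort"]["source"] == "load":
        data_dir = cfg["cohort"]["data_dir"]
        if not data_dir:
            raise ConfigError("cohort.data_dir required with source=load")
        sessions = [read_session(p) for p in sorted(Path(data_dir).glob("*.edf"))]
        if not sessions:
            raise ConfigError(f"no .edf files in {data_dir}")
    else:
        raise ConfigError(f"unknown cohort.source {cfg['cohort']['source']!r}")

    # ---- per-subject processing ------------------------------------------
    onset_rows, feature_sets = [], []
    osc_power: dict[tuple[str, str], list[np.ndarray]] = {}
    mrcp_epochs_by_group: dict[str, list] = {}
    reject_rows = []
    freqs = np.arange(cfg["oscillations"]["freq_min_hz"],
                      cfg["oscillations"]["freq_max_hz"] + 1e-9,
                      cfg["oscillations"]["freq_step_hz"])

    for sess in sessions:
        sess = flip_lateral_channels(sess)
        counts = {"trials": len(sess.cues)}
        detections, threshold = detect_session_onsets(
            sess, k=cfg["emg"]["threshold_k"],
            min_hold_s=cfg["emg"]["min_hold_s"])
        counts["detected"] = sum(d.detected for d in detections)
        for d in detections:
            onset_rows.append({
                "subject_id": sess.subject_id, "group": sess.group.value,
                "trial": d.trial_index, "go_s": d.cue_go_time_s,
                "onset_s": d.onset_time_s if d.detected else np.nan,
                "detected": d.detected, "threshold": threshold})
        envs = session_envelopes(sess)
        side = sess.dominant_foot
        contra = "left" if side == "right" else "right"
        ta_env, sol_env = envs[f"TA_{side}"], envs[f"SOL_{side}"]
        ta_contra = envs[f"TA_{contra}"]
        go_offsets = {d.trial_index: d.cue_go_time_s - d.onset_time_s
                      for d in detections if d.detected}

        ica_kw = dict(seed=seed,
                      blink_corr_threshold=cfg["ica"]["blink_corr_threshold"],
                      emg_power_ratio_threshold=cfg["ica"]["emg_power_ratio_threshold"],
                      max_iter=cfg["ica"]["max_iter"])

        if cfg["mrcp"]["enabled"]:
            eeg = bandpass_mrcp(sess.eeg, sess.eeg_rate)
            if cfg["ica"]["enabled"]:
                eeg, ica_rep = remove_artifact_components(
                    eeg, sess.eeg_rate, sess.montage, **ica_kw)
                counts["ica_rejected_mrcp"] = len(ica_rep.rejected)
            epochs, flags = extract_epochs(
                eeg, detections, sess.eeg_rate, subject_id=sess.subject_id,
                montage=sess.montage, ta_envelope=ta_env, sol_envelope=sol_env,
                ta_contra_envelope=ta_contra)
            for ti, reason in flags:
                reject_rows.append({"subject_id": sess.subject_id, "path": "mrcp",
                                    "trial": ti, "reason": reason})
            feats = [compute_features(ep, cfg["mrcp"]["channel"]) for ep in epochs]
            n_out = sum(f.outlier for f in feats)
            counts["mrcp_epochs"] = len(epochs)
            counts["mrcp_outliers"] = n_out
            for f, ep in zip(feats, epochs):
                if f.outlier:
                    reject_rows.append({
                        "subject_id": sess.subject_id, "path": "mrcp",
                        "trial": f.trial_index, "reason": "peak-time outlier"})
                else:
                    mrcp_epochs_by_group.setdefault(sess.group.value, []).append(ep)
            feature_sets.extend(
                [(sess.group.value, f) for f in feats if not f.outlier])

        if cfg["oscillations"]["enabled"]:
            eeg = bandpass_osc(sess.eeg, sess.eeg_rate)
            if cfg["ica"]["enabled"]:
                eeg, ica_rep = remove_artifact_components(
                    eeg, sess.eeg_rate, sess.montage, **ica_kw)
                counts["ica_rejected_osc"] = len(ica_rep.rejected)
            epochs, flags = extract_epochs(
                eeg, detections, sess.eeg_rate, subject_id=sess.subject_id,
                montage=sess.montage, ta_envelope=ta_env, sol_envelope=sol_env,
                ta_contra_envelope=ta_contra)
            kept, rep = reject_oscillation_outliers(epochs, go_offsets)
            counts["osc_epochs"] = len(epochs)
            counts["osc_rejected"] = len(epochs) - len(kept)
            for row in rep.to_dict("records"):
                reject_rows.append({**row, "path": "osc"})
            kept_idx = {ep.trial_index for ep in kept}
            pad = int(round(sess.eeg_rate))  # 1 s decomposition context
            for center in cfg["oscillations"]["centers"]:
                if not kept:
                    continue
                lap = small_laplacian(eeg, list(sess.montage.channel_names),
                                      center, sess.montage)
                wins, _ = cut_padded_windows(lap, detections, sess.eeg_rate,
                                             pad_s=1.0, trial_indices=kept_idx)
                if not wins.size:
                    continue
                power = morlet_trials(wins, sess.eeg_rate, freqs,
                                      cfg["oscillations"]["n_cycles"],
                                      crop_pad=pad)
                osc_power.setdefault((sess.group.value, center), []).append(power)
        manifest["subjects"][sess.subject_id] = counts

    _write_tsv(pd.DataFrame(onset_rows), out / "onsets.tsv")
    if reject_rows:
        _write_tsv(pd.DataFrame(reject_rows), out / "rejections.tsv")

    epoch_times_axis = None
    # ---- group-level MRCP outputs ----------------------------------------
    if cfg["mrcp"]["enabled"] and feature_sets:
        table = features_table([f for _g, f in feature_sets])
        table.insert(1, "group", [g for g, _f in feature_sets])
        _write_tsv(table, out / "mrcp_features.tsv")
        feat_cols = ["peak_negativity_uv", "peak_time_ms", "ns1_uv_per_s",
                     "ns2_uv_per_s", "rebound_uv_per_s", "latency_mrcp_emg_ms",
                     "emg_peak_uv", "emg_peak_time_ms"]
        summary, anovas = feature_group_table(
            table, feat_cols, alpha=cfg["stats"]["alpha"])
        _write_tsv(summary, out / "feature_group_summary.tsv")
        tukey_rows = [
            {"feature": a.feature, "group_a": ga, "group_b": gb,
             "mean_diff": d, "adj_p": p}
            for a in anovas for ga, gb, d, p in a.tukey_pairs]
        _write_tsv(pd.DataFrame(
            tukey_rows, columns=["feature", "group_a", "group_b",
                                 "mean_diff", "adj_p"]), out / "tukey.tsv")

        cov_rows = []
        for gname, eps in mrcp_epochs_by_group.items():
            for ch in cfg["mrcp"]["cov_channels"]:
                if len(eps) >= 2:
                    cov_rows.append({
                        "group": gname, "channel": ch,
                        "cov": coefficient_of_variation(
                            eps, ch, mode=cfg["mrcp"]["cov_mode"])})
            topo = topo_series(eps)
            topo.insert(0, "channel", topo.index)
            _write_tsv(topo, out / f"topo_series_{gname}.tsv")
            epoch_times_axis = eps[0].times
        _write_tsv(pd.DataFrame(cov_rows), out / "cov.tsv")

    # ---- group-level oscillation outputs ---------------------------------
    if cfg["oscillations"]["enabled"] and osc_power:
        from .model import epoch_times
        times = epoch_times() if epoch_times_axis is None else epoch_times_axis
        bands = (FIG_CAPTION_BANDS if cfg["oscillations"]["band_preset"] ==
                 "fig_caption" else DEFAULT_BANDS)
        decim = int(cfg["stats"]["time_decim"])
        export_decim = int(cfg["oscillations"]["export_time_decim"])
        band_rows = []
        group_power = {key: np.concatenate(stacks)
                       for key, stacks in osc_power.items()}
        for (gname, center), stack in group_power.items():
            erd = erd_ers(stack, times=times, freqs=freqs, channel=center)
            if cfg["stats"]["bootstrap"] and stack.shape[0] >= 10:
                mask = bootstrap_significance(
                    stack[:, :, ::decim], times[::decim],
                    alpha=cfg["stats"]["alpha"],
                    n_boot=max(cfg["stats"]["n_boot"], 200), seed=seed)
                full = np.repeat(mask, decim, axis=1)[:, : times.size]
                erd.significance_mask = full
            long = erd_long_table(erd)
            long = long[long["time_s"].isin(times[::export_decim])]
            long.insert(0, "group", gname)
            _write_tsv(long, out / f"erd_{gname}_{center}.tsv")
            for band in bands.values():
                for wname, (w0, w1) in cfg["oscillations"]["windows"].items():
                    from .oscillations import band_summary
                    band_rows.append({
                        "group": gname, "channel": center, "band": band.name,
                        "window": wname,
                        "erd_pct": band_summary(erd, band, (w0, w1))})
        _write_tsv(pd.DataFrame(band_rows), out / "band_summary.tsv")

        for pair in cfg["stats"]["permutation_pairs"]:
            ga, gb = pair
            for center in cfg["oscillations"]["centers"]:
                if (ga, center) not in group_power or (gb, center) not in group_power:
                    continue
                diff = permutation_difference(
                    group_power[(ga, center)][:, :, ::decim],
                    group_power[(gb, center)][:, :, ::decim],
                    times[::decim], freqs=freqs,
                    alpha=cfg["stats"]["alpha"],
                    n_perm=max(cfg["stats"]["n_perm"], 500),
                    seed=seed, channel=center)
                df = pd.DataFrame({
                    "freq_hz": np.repeat(freqs, diff.times.size),
                    "time_s": np.tile(diff.times, freqs.size),
                    "diff_pct": diff.diff_pct.ravel(),
                    "p": diff.p_values.ravel(),
                    "significant": diff.significance_mask.ravel()})
                df.insert(0, "contrast", f"{ga}-{gb}")
                df.insert(1, "channel", center)
                _write_tsv(df, out / f"diff_{ga}_vs_{gb}_{center}.tsv")

    # ---- manifest ---------------------------------------------------------
    totals: dict[str, int] = {}
    for counts in manifest["subjects"].values():
        for key, val in counts.items():
            totals[key] = totals.get(key, 0) + int(val)
    manifest["stages"] = totals
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
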