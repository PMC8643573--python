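"""Group comparisons: one-way ANOVA with Tukey post hoc, bootstrap
within-group significance maps, permutation between-group difference maps.

The unit of analysis for the feature ANOVA is the single trial pooled across
subjects (matching F degrees of freedom like F(2, 284) for ~287 trials in 3
groups); subject-level aggregation is available via the caller simply
passing per-subject means.  Resampling procedures are percentile-based,
pointwise, and seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as scs

DEFAULT_ALPHA = 0.05
DEFAULT_N_BOOT = 1000
DEFAULT_N_PERM = 1000


@dataclass
class AnovaResult:
    feature: str
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    #: (groupA, groupB, mean difference, Tukey-adjusted p); filled only when
    #: the omnibus test is significant at alpha, mirroring the gated post hoc.
    tukey_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)


def anova_oneway(values_by_group: dict[str, np.ndarray | list[float]],
                 feature: str = "", alpha: float = DEFAULT_ALPHA) -> AnovaResult:
    """Classical one-way ANOVA across groups with gated Tukey HSD post hoc.

    Requires >= 2 groups with >= 2 values each.  Tukey-adjusted pairwise
    p-values are computed only when the omnibus p <= alpha.
    """
    names = list(values_by_group)
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for g, s in zip(names, samples):
        if s.size < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    k = len(samples)
    n_total = sum(s.size for s in samples)
    F, p = scs.f_oneway(*samples)
    result = AnovaResult(
        feature=feature, F=float(F), df_between=k - 1, df_within=n_total - k,
        p=float(p), group_means={g: float(s.mean()) for g, s in zip(names, samples)})
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if p <= alpha and ss_within > 0:
        hsd = scs.tukey_hsd(*samples)
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(samples[i].mean() - samples[j].mean())
                result.tukey_pairs.append(
                    (names[i], names[j], diff, float(hsd.pvalue[i, j])))
    return result


def _erd_from_power(stack: np.ndarray, baseline_cols: np.ndarray) -> np.ndarray:
    """Trial-average power -> baseline-normalized percent change."""
    mean_power = stack.mean(axis=0)
    baseline = mean_power[:, baseline_cols].mean(axis=1)
    return 100.0 * (mean_power - baseline[:, None]) / baseline[:, None]


def bootstrap_significance(
    trials_power: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float] = (-4.0, -2.0),
    alpha: float = DEFAULT_ALPHA,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> np.ndarray:
    """Within-group bootstrap significance of an ERD/ERS map.

    For each (f, t) pixel, trials are resampled with replacement ``n_boot``
    times and the group ERD value recomputed; a pixel is significant when
    the (alpha/2, 1-alpha/2) percentile interval excludes 0.  Deterministic
    for a fixed seed.  ``trials_power``: (n_trials, n_freqs, n_times).
    """
    stack = np.asarray(trials_power, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 10:
        raise ValueError("need at least 10 trials of (n_freqs, n_times) power")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    rng = np.random.default_rng(seed)
    n = stack.shape[0]
    cols = (times >= baseline_window[0]) & (times < baseline_window[1])
    boot = np.empty((n_boot,) + stack.shape[1:], dtype=np.float32)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[b] = _erd_from_power(stack[idx], cols)
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    return (lo > 0.0) | (hi < 0.0)


@dataclass
class DiffMap:
    """Between-group ERD difference (A − B) with permutation p-values."""

    channel: str
    freqs: np.ndarray
    times: np.ndarray
    diff_pct: np.ndarray
    p_values: np.ndarray
    significance_mask: np.ndarray
    alpha: float


def permutation_difference(
    group_a_power: np.ndarray,
    group_b_power: np.ndarray,
    times: np.ndarray,
    freqs: np.ndarray | None = None,
    baseline_window: tuple[float, float] = (-4.0, -2.0),
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    channel: str = "",
) -> DiffMap:
    """Pointwise permutation test of the ERD difference between two groups.

    The observed map is ERD(A) − ERD(B); the null is built by shuffling
    trial-to-group labels ``n_perm`` times.  Two-sided p with add-one
    smoothing: p = (1 + #{|diff*| >= |diff|}) / (n_perm + 1).  Exactly
    antisymmetric in (A, B): the permutation stream is attached to a
    canonical ordering of the two samples (by content hash), so swapping
    the groups negates the difference map and preserves p-values and mask.
    """
    import hashlib

    a = np.asarray(group_a_power, dtype=float)
    b = np.asarray(group_b_power, dtype=float)
    if a.shape[0] < 10 or b.shape[0] < 10:
        raise ValueError("both groups need at least 10 trials")
    if n_perm < 500:
        raise ValueError("n_perm must be >= 500")
    sign = 1.0
    if hashlib.sha1(b.tobytes()).digest() < hashlib.sha1(a.tobytes()).digest():
        a, b, sign = b, a, -1.0
    cols = (times >= baseline_window[0]) & (times < baseline_window[1])
    observed = _erd_from_power(a, cols) - _erd_from_power(b, cols)
    pooled = np.concatenate([a, b], axis=0)
    n_a, n_tot = a.shape[0], a.shape[0] + b.shape[0]
    rng = np.random.default_rng(seed)
    count = np.zeros(observed.shape, dtype=np.int64)
    abs_obs = np.abs(observed)
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        d = _erd_from_power(pooled[perm[:n_a]], cols) \
            - _erd_from_power(pooled[perm[n_a:]], cols)
        count += np.abs(d) >= abs_obs
    p = (1.0 + count) / (n_perm + 1.0)
    observed = sign * observed
    if freqs is None:
        freqs = np.arange(observed.shape[0], dtype=float)
    return DiffMap(channel=channel, freqs=np.asarray(freqs), times=times,
                   diff_pct=observed, p_values=p,
                   significance_mask=p <= alpha, alpha=alpha)


def feature_group_table(
    features: pd.DataFrame,
    feature_columns: list[str],
    group_column: str = "group",
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, list[AnovaResult]]:
    """Per group per feature: n, mean, SD — plus the omnibus ANOVA/Tukey.

    ``features`` is the long per-trial table (one row per trial); outlier
    trials should be dropped by the caller beforehand.
    """
    rows = []
    anovas: list[AnovaResult] = []
    groups = list(features[group_column].unique())
    for col in feature_columns:
        clean = features[[group_column, col]].dropna()
        by_group = {g: clean.loc[clean[group_column] == g, col].to_numpy()
                    for g in groups}
        by_group = {g: v for g, v in by_group.items() if v.size >= 2}
        res = None
        if len(by_group) >= 2:
            res = anova_oneway(by_group, feature=col, alpha=alpha)
            anovas.append(res)
        for g in groups:
            v = clean.loc[clean[group_column] == g, col].to_numpy()
            rows.append({
                "feature": col, "group": g, "n": int(v.size),
                "mean": float(v.mean()) if v.size else np.nan,
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "anova_F": res.F if res else np.nan,
                "anova_p": res.p if res else np.nan,
                "significant": bool(res and res.p <= alpha),
            })
    return pd.DataFrame(rows), anovas
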