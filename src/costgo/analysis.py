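"""ROC-based decision-onset detection and batch statistics.

The decision onset between two groups of trials (e.g. trials that ended on
the central vs. a lateral target, under the same force and reward
condition) is estimated from kinematics alone: at every sample the area
under the ROC curve between the groups' transverse-position distributions
measures how well an ideal observer discriminates them, and the onset is
the first time the AUC stays at or above a threshold (0.75 by default) for
a sustained run of samples.

Works on simulated batches and on externally supplied trial tables in the
package's CSV schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RocResult", "auc", "roc_onset", "switch_frequency", "endpoint_stats",
           "group_series", "onset_from_auc", "bootstrap_onset_ci"]


@dataclass
class RocResult:
    """Per-time discriminability and the detected decision onset.

    ``times`` are milliseconds from movement onset; ``auc`` the per-time
    area-under-ROC values; ``onset`` the first sustained crossing of
    ``threshold`` (``None`` when discrimination never reaches it).
    """

    times: np.ndarray
    auc: np.ndarray
    onset: float | None
    threshold: float
    sustain: int


def auc(samples_a: Sequence[float], samples_b: Sequence[float]) -> float:
    """P(draw from b > draw from a), ties counted half (rank-sum AUC)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    u = stats.mannwhitneyu(b, a, alternative="two-sided").statistic
    return float(u) / (a.size * b.size)


def onset_from_auc(times: np.ndarray, auc_series: np.ndarray,
                   threshold: float, sustain: int) -> float | None:
    """First time with ``sustain`` consecutive AUC samples >= threshold."""
    above = np.asarray(auc_series) >= threshold
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= sustain:
            return float(times[i - sustain + 1])
    return None


def roc_onset(group_a: np.ndarray, group_b: np.ndarray,
              times: np.ndarray | None = None,
              threshold: float = 0.75, sustain: int = 5) -> RocResult:
    """Decision onset between two groups of aligned position time series.

    ``group_a``/``group_b`` are (n_trials, n_samples) arrays on a common
    time base (rows = trials).  The per-time AUC is the probability that an
    ideal observer assigns a random trial of ``group_b`` the larger value.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share a common time base")
    if min(a.shape[0], b.shape[0]) < 2:
        raise ValueError("need at least two trials per group")
    if times is None:
        times = np.arange(a.shape[1], dtype=float)
    times = np.asarray(times, dtype=float)
    if times.shape[0] != a.shape[1]:
        raise ValueError("times length must match the series length")
    series = np.array([auc(a[:, k], b[:, k]) for k in range(a.shape[1])])
    onset = onset_from_auc(times, series, threshold, sustain)
    return RocResult(times=times, auc=series, onset=onset,
                     threshold=threshold, sustain=sustain)


def bootstrap_onset_ci(group_a: np.ndarray, group_b: np.ndarray,
                       times: np.ndarray | None = None,
                       threshold: float = 0.75, sustain: int = 5,
                       n_boot: int = 200, ci: float = 0.95,
                       rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Percentile confidence interval for the ROC onset (convenience only).

    Resamples trials within each group with replacement; replicates whose
    AUC never crosses the threshold are dropped from the percentile.
    """
    rng = np.random.default_rng() if rng is None else rng
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    onsets = []
    for _ in range(n_boot):
        ra = a[rng.integers(0, a.shape[0], a.shape[0])]
        rb = b[rng.integers(0, b.shape[0], b.shape[0])]
        res = roc_onset(ra, rb, times, threshold=threshold, sustain=sustain)
        if res.onset is not None:
            onsets.append(res.onset)
    if not onsets:
        return (np.nan, np.nan)
    lo, hi = np.quantile(onsets, [(1 - ci) / 2, (1 + ci) / 2])
    return float(lo), float(hi)


def group_series(df: pd.DataFrame, value: str = "px",
                 time: str = "t_ms", trial: str = "trial") -> tuple[np.ndarray, np.ndarray]:
    """Pivot a long trajectory table into (trials × samples, times)."""
    wide = df.pivot_table(index=trial, columns=time, values=value, sort=True)
    if wide.isna().any().any():
        raise ValueError("misaligned time series: trials do not share a time base")
    return wide.to_numpy(), wide.columns.to_numpy(dtype=float)


def switch_frequency(final_options: Sequence[int] | pd.Series,
                     labels: Sequence[str] | None = None) -> dict:
    """Proportion of trials ending on each final target (sums to 1)."""
    finals = np.asarray(final_options, dtype=int)
    if finals.size == 0:
        return {}
    n_opt = (max(finals.max() + 1, len(labels)) if labels is not None
             else finals.max() + 1)
    counts = np.bincount(finals, minlength=n_opt).astype(float)
    props = counts / finals.size
    keys = labels if labels is not None else [str(i) for i in range(n_opt)]
    return {str(k): float(p) for k, p in zip(keys, props)}


def endpoint_stats(df: pd.DataFrame, trial: str = "trial") -> dict:
    """Terminal mean and unbiased variance along x and y.

    A single trial yields ``None`` variances (undefined), with the count.
    """
    last = df.sort_values("t_ms").groupby(trial).tail(1)
    n = len(last)
    out = {"n": int(n),
           "mean_x": float(last["px"].mean()), "mean_y": float(last["py"].mean())}
    if n > 1:
        out["var_x"] = float(last["px"].var(ddof=1))
        out["var_y"] = float(last["py"].var(ddof=1))
    else:
        out["var_x"] = None
        out["var_y"] = None
    return out
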