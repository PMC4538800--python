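"""Evaluation statistics for spike-in normalization experiments.

Four read-outs quantify how well a normalization strategy works:

* **fixed-slope R²** — in a 2-fold serial-dilution experiment the log2
  normalized counts of a fold-change control should track its log2 relative
  input with slope exactly 1; the coefficient of determination of that
  slope-1 fit (intercept free) measures recovery of the designed
  fold-changes.
* **ΔR²** — the gain in R² of normalized over raw counts, per control.
* **replicate SD** — the per-feature standard deviation of log2 counts over
  technical replicates; good normalization shifts its distribution down.
* **group log-ratio** — per-feature log2 ratio of group means, summarized by
  median and kernel-density mode; with invariant-anchor normalization a true
  global shift between groups is preserved instead of being leveled out.

Counts are log-transformed with a pseudo-count (default 1) so zeros remain
defined; the pseudo-count is applied only here, never in the size-factor
estimator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def fixed_slope_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Coefficient of determination of a slope-1 fit of y on x.

    The intercept is estimated as mean(y − x); R² compares the slope-1
    residuals to the variance of y. Returns NaN when y has zero variance
    (undefined). Values can be negative when the fit is worse than the mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired points")
    c = np.mean(y - x)
    ss_res = np.sum((y - x - c) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - ss_res / ss_tot)


def dilution_r2(counts: pd.DataFrame, log2_input: pd.Series,
                pseudocount: float = 1.0) -> pd.Series:
    """Fixed-slope R² per feature for a dilution series.

    *counts* is features × mixes (raw or normalized); *log2_input* gives the
    log2 relative input per mix (shared by all features).
    """
    x = log2_input[counts.columns].values.astype(float)
    out = {}
    for feat, row in counts.iterrows():
        y = np.log2(row.values.astype(float) + pseudocount)
        out[feat] = fixed_slope_r2(x, y)
    return pd.Series(out)


def delta_r2(r2_normalized: pd.Series, r2_raw: pd.Series) -> pd.Series:
    """Per-feature R² improvement of normalized over raw counts."""
    if not r2_normalized.index.equals(r2_raw.index):
        raise ValueError("R² series must cover the same features")
    return r2_normalized - r2_raw


def replicate_sd(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.Series:
    """Per-feature sample SD (ddof=1) of log2(count + pseudocount)."""
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 replicate samples")
    logc = np.log2(counts.astype(float) + pseudocount)
    return logc.std(axis=1, ddof=1)


def _kde_mode(values: np.ndarray) -> float:
    """Location of the density maximum (Gaussian KDE, Silverman bandwidth)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 3 or np.ptp(values) == 0:
        return float(np.median(values)) if values.size else float("nan")
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def distribution_summary(values: pd.Series | np.ndarray) -> dict[str, float]:
    """Median and KDE-mode summary of a statistic's distribution."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    return {
        "n": int(arr.size),
        "median": float(np.median(arr)) if arr.size else float("nan"),
        "kde_mode": _kde_mode(arr),
    }


def group_log_ratio(counts: pd.DataFrame,
                    group_a: Sequence[str], group_b: Sequence[str],
                    pseudocount: float = 1.0
                    ) -> tuple[pd.Series, dict[str, float]]:
    """Per-feature log2 ratio of group-A mean over group-B mean.

    Means are taken over each group's (normalized) counts before the ratio;
    features with zero counts in both groups are excluded. Returns the
    per-feature ratios and a distribution summary (median, KDE mode).
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be non-empty")
    mean_a = counts[list(group_a)].astype(float).mean(axis=1)
    mean_b = counts[list(group_b)].astype(float).mean(axis=1)
    keep = (mean_a > 0) | (mean_b > 0)
    ratios = np.log2((mean_a[keep] + pseudocount)
                     / (mean_b[keep] + pseudocount))
    return ratios, distribution_summary(ratios)
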