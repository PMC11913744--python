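"""Stage- and depth-wise aggregation and group comparison statistics.

Aggregation follows a strict two-level order: values are first averaged
across the neurons of a field of view (FOV), then FOV means are averaged
(with SEM) across FOVs of the same group — so FOVs with many neurons do not
dominate the group mean.  Group comparisons use two-sided Kolmogorov-Smirnov
or Mann-Whitney U tests with Bonferroni correction; the number of
comparisons is supplied explicitly per panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["aggregate", "compare_groups", "fraction_significant",
           "significance_stars"]


def aggregate(values: pd.DataFrame, value_col: str,
              group_keys: list[str], fov_key: str = "fov") -> pd.DataFrame:
    """Two-level mean +/- SEM: neurons -> FOV means -> group mean across FOVs.

    ``values`` must carry one row per neuron (or neuron-frame) with the FOV
    and grouping keys.  Empty groups are dropped with a warning.  Returns
    columns ``group_keys + [mean, sem, n_fovs]``.
    """
    for col in [value_col, fov_key, *group_keys]:
        if col not in values.columns:
            raise ValueError(f"missing column {col!r}")
    clean = values.dropna(subset=[value_col])
    if len(clean) < len(values):
        warnings.warn("dropped rows with missing values before aggregation")
    fov_means = (clean.groupby([*group_keys, fov_key], sort=True)[value_col]
                 .mean().reset_index())
    out = (fov_means.groupby(group_keys, sort=True)[value_col]
           .agg(mean="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else 0.0,
                n_fovs="count")
           .reset_index())
    return out


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(x: np.ndarray, y: np.ndarray, test: str = "ks",
                   n_comparisons: int = 1) -> tuple[float, str]:
    """Bonferroni-corrected two-sample comparison.

    ``test``: "ks" (two-sided Kolmogorov-Smirnov) or "mannwhitney"
    (two-sided Mann-Whitney U).  The raw p-value is multiplied by
    ``n_comparisons`` and capped at 1.  Returns (corrected p, star code).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 values")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if test == "ks":
        p = stats.ks_2samp(x, y, alternative="two-sided").pvalue
    elif test == "mannwhitney":
        p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    corrected = min(1.0, float(p) * n_comparisons)
    return corrected, significance_stars(corrected)


def fraction_significant(flags: pd.DataFrame, flag_col: str,
                         group_keys: list[str]) -> pd.DataFrame:
    """Fraction of neurons flagged significant per group (donut fractions)."""
    if flag_col not in flags.columns:
        raise ValueError(f"missing column {flag_col!r}")
    clean = flags.dropna(subset=[flag_col])
    out = (clean.groupby(group_keys, sort=True)[flag_col]
           .agg(fraction="mean", n="count").reset_index())
    return out
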