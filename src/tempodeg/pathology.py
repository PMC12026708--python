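"""Percent axonal injury and shared nonparametric group comparisons.

Axonal injury is quantified as the percentage of outlined injured
white-matter area over total brain area per subject.  Group comparisons use
the two-sided Wilcoxon rank-sum test — exact by full enumeration for the
small cohorts typical of animal studies, a midrank normal approximation
above n = 25 per group or in the presence of ties — with Bonferroni
adjustment over the group pairs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = ["percent_axonal_injury", "rank_sum_test", "wilcoxon_bonferroni"]

EXACT_MAX_N = 25


def percent_axonal_injury(injured_area, total_area):
    """100 * injured_area / total_area, unit-invariant."""
    injured = np.asarray(injured_area, dtype=float)
    total = np.asarray(total_area, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total area must be positive")
    if np.any(injured < 0):
        raise ValueError("injured area must be non-negative")
    if np.any(injured > total):
        raise ValueError("injured area exceeds total area")
    return 100.0 * injured / total


def rank_sum_test(x, y) -> tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum p-value.

    Returns ``(p, exact)``; exact enumeration is used when both groups have
    at most 25 values and there are no ties across the pooled sample,
    otherwise the midrank normal approximation (with continuity correction)
    is used and flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (not has_ties) and len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N
    method = "exact" if exact else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(min(res.pvalue, 1.0)), exact


def wilcoxon_bonferroni(values_by_group: dict) -> pd.DataFrame:
    """Pairwise rank-sum tests with Bonferroni over the number of pairs.

    Groups with fewer than 3 values are skipped (flagged in the output).
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pairs = list(combinations(groups, 2))
    n_pairs = len(pairs)
    rows = []
    for g1, g2 in pairs:
        x = np.asarray(values_by_group[g1], dtype=float)
        y = np.asarray(values_by_group[g2], dtype=float)
        if len(x) < 3 or len(y) < 3:
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "pvalue": np.nan,
                    "p_adj": np.nan,
                    "exact": False,
                    "skipped": True,
                    "median_diff": np.nan,
                }
            )
            continue
        p, exact = rank_sum_test(x, y)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "pvalue": p,
                "p_adj": min(1.0, p * n_pairs),
                "exact": exact,
                "skipped": False,
                "median_diff": float(np.median(y) - np.median(x)),
            }
        )
    return pd.DataFrame(rows)
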