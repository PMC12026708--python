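"""Per-gene two-group negative-binomial Wald test.

Counts in each group are modeled as NB with mean ``s_j * q`` and variance
``mu + alpha * mu**2``.  The log2 fold change is the log ratio of group
means of normalized counts (pseudocount 0.5 on both means); its standard
error comes from the delta method with ``Var(count_j / s_j) = q / s_j +
alpha * q**2``.  The Wald statistic is referred to a standard normal, and
Benjamini-Hochberg adjustment is applied across tested genes.

Dispersion is estimated per gene by method of moments on normalized counts
pooled across the two groups after removing group means, floored at 1e-8.
No empirical-Bayes shrinkage is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm as normal
from statsmodels.stats.multitest import multipletests

from .io import CountExperiment

__all__ = [
    "DEResult",
    "estimate_dispersion",
    "wald_test",
    "call_degs",
    "top_degs",
    "ALPHA_MIN",
]

ALPHA_MIN = 1e-8
_LN2 = np.log(2.0)


@dataclass
class DEResult:
    """Per-gene statistics for one two-group comparison (B over A)."""

    table: pd.DataFrame  # columns: base_mean, log2FC, se, stat, pvalue, fdr, dispersion
    group_a: str
    group_b: str

    @property
    def comparison(self) -> str:
        return f"{self.group_b}_vs_{self.group_a}"

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def estimate_dispersion(
    counts_for_gene: np.ndarray, s: np.ndarray, group_labels: np.ndarray
) -> float:
    """Method-of-moments NB dispersion for one gene.

    ``alpha = max((v - m) / m**2, ALPHA_MIN)`` where ``m`` and ``v`` are the
    mean and pooled within-group variance of the normalized counts.
    """
    y = np.asarray(counts_for_gene, dtype=float) / np.asarray(s, dtype=float)
    labels = np.asarray(group_labels)
    m = y.mean()
    if m <= 0:
        warnings.warn("zero mean count; dispersion floored")
        return ALPHA_MIN
    resid = np.empty_like(y)
    n_groups = 0
    for g in np.unique(labels):
        mask = labels == g
        resid[mask] = y[mask] - y[mask].mean()
        n_groups += 1
    v = (resid**2).sum() / max(len(y) - n_groups, 1)
    return max((v - m) / m**2, ALPHA_MIN)


def wald_test(
    exp: CountExperiment,
    s: pd.Series,
    comparison: tuple[str, str],
    dispersion: pd.Series | None = None,
) -> DEResult:
    """NB Wald test of group B over group A for every gene.

    ``comparison`` is ``(group_a, group_b)`` with A the reference; the
    returned log2FC is B over A.
    """
    group_a, group_b = comparison
    groups = exp.sample_table["group"]
    idx_a = groups[groups == group_a].index
    idx_b = groups[groups == group_b].index
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"empty group in comparison {group_b} vs {group_a}")

    counts_a = exp.counts[idx_a].to_numpy(dtype=float)
    counts_b = exp.counts[idx_b].to_numpy(dtype=float)
    if not counts_a.any() or not counts_b.any():
        raise ValueError("a group has all-zero counts for every gene")
    s_a = s.loc[idx_a].to_numpy()
    s_b = s.loc[idx_b].to_numpy()
    y_a = counts_a / s_a[None, :]
    y_b = counts_b / s_b[None, :]
    n_a, n_b = y_a.shape[1], y_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 samples per group")

    q_a = y_a.mean(axis=1)
    q_b = y_b.mean(axis=1)

    if dispersion is None:
        # pooled method-of-moments across the two groups, vectorized
        y = np.concatenate([y_a, y_b], axis=1)
        resid = np.concatenate([y_a - q_a[:, None], y_b - q_b[:, None]], axis=1)
        m = y.mean(axis=1)
        v = (resid**2).sum(axis=1) / max(y.shape[1] - 2, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, ALPHA_MIN)
        alpha = np.maximum(alpha, ALPHA_MIN)
    else:
        alpha = dispersion.loc[exp.gene_ids].to_numpy()

    qa5 = q_a + 0.5
    qb5 = q_b + 0.5
    log2fc = np.log2(qb5 / qa5)

    # delta method: Var(mean of count_j/s_j) with Var(count_j/s_j) = q/s_j + alpha q^2
    var_qa = (q_a[:, None] / s_a[None, :] + alpha[:, None] * q_a[:, None] ** 2).sum(axis=1) / n_a**2
    var_qb = (q_b[:, None] / s_b[None, :] + alpha[:, None] * q_b[:, None] ** 2).sum(axis=1) / n_b**2
    var_ln = var_qb / qb5**2 + var_qa / qa5**2
    se = np.sqrt(var_ln) / _LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = 2.0 * normal.sf(np.abs(stat))
    pvalue = np.minimum(pvalue, 1.0)
    fdr = multipletests(pvalue, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "base_mean": (q_a * n_a + q_b * n_b) / (n_a + n_b),
            "log2FC": log2fc,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
            "fdr": fdr,
            "dispersion": alpha,
        },
        index=exp.gene_ids,
    )
    return DEResult(table=table, group_a=group_a, group_b=group_b)


def _table_of(de) -> pd.DataFrame:
    return de.table if isinstance(de, DEResult) else de


def call_degs(
    de,
    p_max: float = 0.05,
    lfc_min: float = 1.0,
    fdr_mode: bool = False,
) -> pd.DataFrame:
    """DEG calls at ``p <= p_max`` and ``|log2FC| >= lfc_min`` (inclusive).

    With ``fdr_mode`` the BH-adjusted p is thresholded instead of the raw p.
    Returns a frame indexed by called gene with ``direction`` and ``log2FC``.
    """
    table = _table_of(de)
    sig_col = "fdr" if fdr_mode else "pvalue"
    called = table[(table[sig_col] <= p_max) & (table["log2FC"].abs() >= lfc_min)]
    return pd.DataFrame(
        {
            "direction": np.where(called["log2FC"] >= 0, "up", "down"),
            "log2FC": called["log2FC"],
            sig_col: called[sig_col],
        },
        index=called.index,
    )


def top_degs(de, k: int = 5, fdr_max: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k up and top-k down genes among ``fdr <= fdr_max``.

    Ranked by log2FC magnitude; ties broken by smaller fdr then gene id.
    Fewer than k rows are returned when the FDR stratum is small.
    """
    table = _table_of(de)
    stratum = table[table["fdr"] <= fdr_max].copy()
    stratum = stratum.reset_index().rename(columns={stratum.index.name or "index": "gene"})
    up = stratum.sort_values(
        ["log2FC", "fdr", "gene"], ascending=[False, True, True]
    ).head(k)
    down = stratum.sort_values(
        ["log2FC", "fdr", "gene"], ascending=[True, True, True]
    ).head(k)
    up = up[up["log2FC"] > 0].set_index("gene")
    down = down[down["log2FC"] < 0].set_index("gene")
    return up, down
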