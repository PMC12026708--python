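"""Cell-type specificity scoring with the tau index.

For a gene with expression ``x_i`` across n cell types, ``x_hat = x / max(x)``
and ``tau = sum(1 - x_hat) / (n - 1)``.  tau is 1 for a gene expressed in a
single cell type and 0 for perfectly uniform expression.  Genes with
``tau >= 0.8`` are called specific to their maximal cell type; ``tau >= 0.6``
is cell-type enriched.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["tau_score", "assign_celltypes", "pattern_celltype_table"]

TAU_SPECIFIC = 0.8
TAU_ENRICHED = 0.6


def tau_score(expression_row) -> float:
    """tau specificity of one gene's expression profile across cell types.

    Returns NaN (with a warning) for an all-zero profile, where the score
    is undefined.
    """
    x = np.asarray(expression_row, dtype=float)
    if x.size < 2:
        raise ValueError("tau needs at least two cell types")
    if np.any(x < 0):
        raise ValueError("expression must be non-negative")
    mx = x.max()
    if mx <= 0:
        warnings.warn("all-zero expression row: tau undefined")
        return float("nan")
    return float((1.0 - x / mx).sum() / (x.size - 1))


def assign_celltypes(
    ref: pd.DataFrame,
    tau_specific: float = TAU_SPECIFIC,
    tau_enriched: float = TAU_ENRICHED,
) -> pd.DataFrame:
    """Per-gene tau, argmax cell type, and specificity tier.

    ``ref`` is cell types x genes, non-negative.  A tie at the maximum makes
    specificity ill-defined: the gene is flagged ambiguous and given tier
    "none" regardless of tau.
    """
    if ref.shape[0] < 2:
        raise ValueError("reference needs at least two cell types")
    X = ref.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("reference must be non-negative")
    mx = X.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = np.where(mx > 0, X / np.where(mx > 0, mx, 1.0), np.nan)
    n = X.shape[0]
    tau = (1.0 - xhat).sum(axis=0) / (n - 1)
    argmax = ref.index.to_numpy()[X.argmax(axis=0)]
    ambiguous = (X == mx[None, :]).sum(axis=0) > 1
    tier = np.full(X.shape[1], "none", dtype=object)
    tier[(tau >= tau_enriched) & ~ambiguous] = "enriched"
    tier[(tau >= tau_specific) & ~ambiguous] = "specific"
    out = pd.DataFrame(
        {
            "tau": tau,
            "cell_type": argmax,
            "tier": tier,
            "ambiguous": ambiguous,
        },
        index=ref.columns,
    )
    out.loc[mx <= 0, ["tau"]] = np.nan
    out.loc[mx <= 0, "tier"] = "none"
    return out


def pattern_celltype_table(
    calls: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Counts of specific-tier genes per (pattern, cell type, direction).

    ``calls`` is the temporal classification table; ``assignments`` the
    output of :func:`assign_celltypes` on the same gene universe.  Only
    genes with tier "specific" contribute.
    """
    shared = calls.index.intersection(assignments.index)
    merged = calls.loc[shared, ["pattern", "direction"]].join(
        assignments.loc[shared, ["cell_type", "tier"]]
    )
    specific = merged[merged["tier"] == "specific"]
    table = (
        specific.groupby(["pattern", "cell_type", "direction"], observed=True)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    return table
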