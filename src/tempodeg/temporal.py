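"""Six-way temporal classification of differentially expressed genes.

Three pairwise comparisons anchor the classification: A (1 day vs sham),
B (1 week vs sham), and C (1 week vs 1 day).  The significance triple
(A, B, C) maps a gene to exactly one label:

==========  =========  =====================================================
(A, B, C)   pattern    meaning
==========  =========  =====================================================
(T, F, F)   Early      changed only at 1 day vs sham
(T, F, T)   Transient  changed at 1 day, resolved by 1 week
(T, T, F)   Persistent changed at 1 day and still changed at 1 week
(T, T, T)   Intensified changed at 1 day and changed further at 1 week
(F, T, T)   Delayed    changed only at 1 week, vs both sham and 1 day
(F, T, F)   Late       changed only at 1 week vs sham
(F, F, T)   Unclassified  never significant vs sham
(F, F, F)   NotDE
==========  =========  =====================================================

The six named patterns partition the set of genes significant vs sham at
either timepoint; ``partition_check`` asserts this.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .diffexp import DEResult, call_degs

__all__ = [
    "PATTERNS",
    "TRUTH_TABLE",
    "classify_temporal",
    "partition_check",
    "overlap_sets",
]

PATTERNS = ("Early", "Transient", "Persistent", "Intensified", "Delayed", "Late")

TRUTH_TABLE: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): "Early",
    (True, False, True): "Transient",
    (True, True, False): "Persistent",
    (True, True, True): "Intensified",
    (False, True, True): "Delayed",
    (False, True, False): "Late",
    (False, False, True): "Unclassified",
    (False, False, False): "NotDE",
}


def _flags_and_lfc(de, p_max, lfc_min, fdr_mode):
    table = de.table if isinstance(de, DEResult) else de
    calls = call_degs(table, p_max=p_max, lfc_min=lfc_min, fdr_mode=fdr_mode)
    sig = pd.Series(False, index=table.index)
    sig.loc[calls.index] = True
    return sig, table["log2FC"]


def classify_temporal(
    de_a,
    de_b,
    de_c,
    p_max: float = 0.05,
    lfc_min: float = 1.0,
    fdr_mode: bool = False,
) -> pd.DataFrame:
    """Classify every gene from the three comparison tables.

    Returns a frame indexed by gene with ``pattern``, ``direction``
    ("up"/"down"/"discordant"/"none"), the three significance flags and the
    three log2 fold changes.  Direction is the shared sign of the
    significant sham-anchored comparisons; a sign conflict between two
    significant sham comparisons is reported as "discordant".
    """
    sig_a, lfc_a = _flags_and_lfc(de_a, p_max, lfc_min, fdr_mode)
    sig_b, lfc_b = _flags_and_lfc(de_b, p_max, lfc_min, fdr_mode)
    sig_c, lfc_c = _flags_and_lfc(de_c, p_max, lfc_min, fdr_mode)
    if not (sig_a.index.equals(sig_b.index) and sig_a.index.equals(sig_c.index)):
        raise ValueError("the three comparisons must share one gene universe")

    patterns = []
    directions = []
    for a, b, la, lb in zip(sig_a, sig_b, lfc_a, lfc_b):
        if a and b:
            directions.append(
                ("up" if la >= 0 else "down") if np.sign(la) == np.sign(lb) else "discordant"
            )
        elif a:
            directions.append("up" if la >= 0 else "down")
        elif b:
            directions.append("up" if lb >= 0 else "down")
        else:
            directions.append("none")
    for a, b, c in zip(sig_a, sig_b, sig_c):
        patterns.append(TRUTH_TABLE[(bool(a), bool(b), bool(c))])

    return pd.DataFrame(
        {
            "pattern": patterns,
            "direction": directions,
            "sig_1d_vs_sham": sig_a.to_numpy(),
            "sig_1wk_vs_sham": sig_b.to_numpy(),
            "sig_1wk_vs_1d": sig_c.to_numpy(),
            "log2FC_1d_vs_sham": lfc_a.to_numpy(),
            "log2FC_1wk_vs_sham": lfc_b.to_numpy(),
            "log2FC_1wk_vs_1d": lfc_c.to_numpy(),
        },
        index=sig_a.index,
    )


def partition_check(calls: pd.DataFrame) -> tuple[bool, pd.DataFrame, list[str]]:
    """Verify that the six named patterns exactly cover the sham-significant
    genes, and tabulate counts per pattern and direction."""
    sham_sig = calls["sig_1d_vs_sham"] | calls["sig_1wk_vs_sham"]
    named = calls["pattern"].isin(PATTERNS)
    offenders = calls.index[sham_sig != named].tolist()
    table = (
        calls[named]
        .groupby(["pattern", "direction"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(PATTERNS, fill_value=0)
    )
    return len(offenders) == 0, table, offenders


def overlap_sets(sets_by_stratum: dict) -> pd.DataFrame:
    """Exclusive (upset-style) intersection regions of DEG sets.

    ``sets_by_stratum`` maps a stratum key (e.g. ``("FC", "1d")``) to a set
    of gene ids.  Each non-empty region is reported with the strata it
    belongs to, its cardinality, and the sorted member list.  Direction
    stratification is the caller's job (pass up- and down-sets separately).
    """
    if len(sets_by_stratum) < 2:
        raise ValueError("need at least two strata")
    keys = list(sets_by_stratum)
    rows = []
    for r in range(1, len(keys) + 1):
        for inc in combinations(keys, r):
            region = set.intersection(*(set(sets_by_stratum[k]) for k in inc))
            for k in keys:
                if k not in inc:
                    region -= set(sets_by_stratum[k])
            if region:
                rows.append(
                    {
                        "strata": tuple(inc),
                        "n": len(region),
                        "members": sorted(region),
                    }
                )
    return pd.DataFrame(rows, columns=["strata", "n", "members"])
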