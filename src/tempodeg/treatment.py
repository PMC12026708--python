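"""Dampened / accelerated classification of treatment effects.

Three sham-anchored comparisons drive the labels: A (1 day vs sham),
B (1 week vs sham) and T (treated vs sham).

* **dampened** — significant at 1 day but not under treatment
  (``sig_A and not sig_T``, regardless of B): the injury response is pulled
  back to sham level by the drug.
* **accelerated** — significant at 1 week and under treatment but not yet at
  1 day, with the treated change in the same direction as the 1-week change
  (``sig_B and sig_T and not sig_A`` with sign concordance): the treated arm
  reaches the late injury level within one day.
* **unaffected** — no comparison significant; everything else is **other**
  and reported with its flag triple.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .temporal import _flags_and_lfc

__all__ = ["classify_treatment", "venn_summary", "DAMPENED_REGIONS", "ACCELERATED_REGIONS"]

#: Venn regions (membership of A, B, T) carrying the treatment labels
DAMPENED_REGIONS = (("A",), ("A", "B"))
ACCELERATED_REGIONS = (("B", "T"),)


def classify_treatment(
    de_a,
    de_b,
    de_t,
    p_max: float = 0.05,
    lfc_min: float = 1.0,
    fdr_mode: bool = False,
) -> pd.DataFrame:
    """Label every gene dampened / accelerated / unaffected / other.

    Direction comes from the anchoring comparison: A for dampened genes,
    B for accelerated ones.
    """
    sig_a, lfc_a = _flags_and_lfc(de_a, p_max, lfc_min, fdr_mode)
    sig_b, lfc_b = _flags_and_lfc(de_b, p_max, lfc_min, fdr_mode)
    sig_t, lfc_t = _flags_and_lfc(de_t, p_max, lfc_min, fdr_mode)
    if not (sig_a.index.equals(sig_b.index) and sig_a.index.equals(sig_t.index)):
        raise ValueError("the three comparisons must share one gene universe")

    a = sig_a.to_numpy()
    b = sig_b.to_numpy()
    t = sig_t.to_numpy()
    la = lfc_a.to_numpy()
    lb = lfc_b.to_numpy()
    lt = lfc_t.to_numpy()

    dampened = a & ~t
    accelerated = b & t & ~a & (np.sign(lb) == np.sign(lt))
    unaffected = ~a & ~b & ~t

    label = np.full(len(a), "other", dtype=object)
    label[unaffected] = "unaffected"
    label[accelerated] = "accelerated"
    label[dampened] = "dampened"

    direction = np.full(len(a), "none", dtype=object)
    direction[dampened] = np.where(la[dampened] >= 0, "up", "down")
    direction[accelerated] = np.where(lb[accelerated] >= 0, "up", "down")

    return pd.DataFrame(
        {
            "label": label,
            "direction": direction,
            "sig_1d_vs_sham": a,
            "sig_1wk_vs_sham": b,
            "sig_treated_vs_sham": t,
            "log2FC_1d_vs_sham": la,
            "log2FC_1wk_vs_sham": lb,
            "log2FC_treated_vs_sham": lt,
        },
        index=sig_a.index,
    )


def venn_summary(set_a: set, set_b: set, set_t: set) -> pd.DataFrame:
    """Cardinalities of the seven exclusive Venn regions of {A, B, T}.

    Regions carrying the dampened (A-only, A&B) and accelerated (B&T)
    labels are starred.  Pass up- and down-regulated sets separately for a
    direction-stratified summary.
    """
    a, b, t = set(set_a), set(set_b), set(set_t)
    regions = {
        ("A",): a - b - t,
        ("B",): b - a - t,
        ("T",): t - a - b,
        ("A", "B"): (a & b) - t,
        ("A", "T"): (a & t) - b,
        ("B", "T"): (b & t) - a,
        ("A", "B", "T"): a & b & t,
    }
    rows = []
    for key, members in regions.items():
        star = ""
        if key in DAMPENED_REGIONS:
            star = "dampened"
        elif key in ACCELERATED_REGIONS:
            star = "accelerated"
        if members:
            rows.append(
                {
                    "region": "&".join(key),
                    "n": len(members),
                    "label": star,
                    "members": sorted(members),
                }
            )
    return pd.DataFrame(rows, columns=["region", "n", "label", "members"])
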