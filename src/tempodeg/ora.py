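"""Gene-set overrepresentation analysis.

One-sided Fisher's exact (hypergeometric tail) test of a gene list against
a GMT-backed gene-set collection, restricted to a stated background
universe (the post-filter gene set), with Benjamini-Hochberg adjustment
across sets and greedy collapsing of similar significant terms to the
representative with the highest fold enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "fisher_ora", "collapse_terms"]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: needs name, description, members")
        name, desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValueError(f"malformed GMT line {lineno}: set {name!r} has no members")
        if name in sets:
            raise ValueError(f"duplicate set name {name!r} at line {lineno}")
        sets[name] = set(members)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in collection.sets:
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(collection.sets[name])]))
    Path(path).write_text("\n".join(lines) + "\n")


def fisher_ora(
    gene_list,
    collection: GeneSetCollection,
    universe,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided enrichment test of ``gene_list`` against every set.

    For overlap k, universe-restricted set size K, list size m and universe
    size N, the p-value is the hypergeometric upper tail P(X >= k) and the
    fold enrichment is (k/m) / (K/N).  BH adjustment runs across sets;
    ``significant`` marks ``fdr <= fdr_max``.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not universe or not genes:
        raise ValueError("universe and gene list must be non-empty")
    if not genes <= universe:
        raise ValueError(f"gene list not contained in universe: {sorted(genes - universe)[:10]}")
    N = len(universe)
    m = len(genes)
    rows = []
    for name, members in collection.sets.items():
        members_u = members & universe
        K = len(members_u)
        k = len(members_u & genes)
        p = float(hypergeom.sf(k - 1, N, K, m)) if K > 0 else 1.0
        fold = (k / m) / (K / N) if K > 0 else 0.0
        rows.append(
            {
                "term": name,
                "description": collection.descriptions.get(name, ""),
                "k": k,
                "K": K,
                "m": m,
                "N": N,
                "fold_enrichment": fold,
                "pvalue": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    if len(table):
        table["fdr"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
    else:
        table["fdr"] = []
    table["significant"] = table["fdr"] <= fdr_max
    if len(table):
        table = table.sort_values(["fdr", "pvalue", "term"])
    return table


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def collapse_terms(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    universe,
    similarity_threshold: float = 0.5,
) -> pd.DataFrame:
    """Collapse similar significant terms onto one representative each.

    Significant terms are visited in decreasing fold enrichment (ties:
    smaller fdr, then name); each unvisited term seeds a cluster of all
    remaining terms whose universe-restricted member sets have Jaccard
    similarity >= threshold with it, and represents the cluster.
    """
    universe = set(universe)
    sig = results[results["significant"]].copy()
    order = sig.assign(_name=sig.index).sort_values(
        ["fold_enrichment", "fdr", "_name"], ascending=[False, True, True], kind="mergesort"
    )
    members = {name: collection.sets[name] & universe for name in order.index}
    remaining = list(order.index)
    representatives = []
    collapsed_into: dict[str, str] = {}
    while remaining:
        seed = remaining.pop(0)
        representatives.append(seed)
        still = []
        for other in remaining:
            if _jaccard(members[seed], members[other]) >= similarity_threshold:
                collapsed_into[other] = seed
            else:
                still.append(other)
        remaining = still
    out = order.loc[representatives].drop(columns="_name")
    out["n_collapsed"] = [
        sum(1 for o, s in collapsed_into.items() if s == rep) for rep in representatives
    ]
    return out
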