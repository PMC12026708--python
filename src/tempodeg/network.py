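"""Signed weighted co-expression network and module detection.

The workflow follows the standard weighted co-expression recipe: a
biweight midcorrelation (bicor) matrix between gene expression profiles, a
signed soft-threshold adjacency ``a_ij = ((1 + cor)/2)**beta``, a
topological overlap measure (TOM) with the "mean" denominator, and
average-linkage hierarchical clustering of ``1 - TOM``.  The tree is cut
at a height placed within the dendrogram's merge-height range according to
the ``deep_split`` sensitivity, branches below
the minimum module size are left unassigned (module 0), module eigengenes
(first principal component of the standardized module expression) are
merged when closer than ``merge_cut_height`` in correlation dissimilarity,
and genes are reassigned between modules when their module membership
(kME, bicor with the eigengene) is markedly higher elsewhere.

This is a static approximation of the dynamic hybrid tree cut; the
contract is recovery of planted correlation structure, not label-for-label
parity with any particular implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .pathology import rank_sum_test

__all__ = [
    "NetworkParams",
    "ModuleSet",
    "bicor_matrix",
    "signed_adjacency",
    "tom_similarity",
    "detect_modules",
    "hub_genes",
    "module_group_test",
    "classify_module_treatment",
]

#: deep_split sensitivity -> tree-cut height as a fraction of the dendrogram
#: merge-height range (5th percentile to maximum).  Higher sensitivity cuts
#: lower, splitting branches more aggressively, as in dynamic tree cutting;
#: anchoring the cut to the observed height range keeps the behavior stable
#: across datasets whose absolute 1 - TOM scales differ.
DEEP_SPLIT_FRACTIONS = {0: 0.99, 1: 0.95, 2: 0.90, 3: 0.85, 4: 0.80}


@dataclass
class NetworkParams:
    beta: int = 12
    min_module_size: int = 10
    merge_cut_height: float = 0.15
    deep_split: int = 4
    reassign_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if self.deep_split not in DEEP_SPLIT_FRACTIONS:
            raise ValueError("deep_split must be an integer in 0..4")


@dataclass
class ModuleSet:
    """Module assignment (0 = unassigned), eigengene scores, and kME."""

    assignments: pd.Series  # gene -> module id
    eigengenes: pd.DataFrame  # samples x modules ("ME1", ...)
    kme: pd.DataFrame  # genes x modules
    params: NetworkParams = field(default_factory=NetworkParams)

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.assignments) - {0})


def _bicor_basis(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise biweight midcovariance basis vectors, unit-normalized.

    Rows with zero MAD fall back to the Pearson (mean-centered) basis and
    are flagged.  The dot product of two basis rows is the (bi)correlation.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)
    basis = np.empty_like(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * np.where(mad > 0, mad, 1.0))
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    b = (X - med) * w
    if np.any(fallback):
        b[fallback] = X[fallback] - X[fallback].mean(axis=1, keepdims=True)
    norms = np.sqrt((b**2).sum(axis=1, keepdims=True))
    degenerate = norms[:, 0] == 0
    norms[degenerate] = 1.0
    basis = b / norms
    basis[degenerate] = 0.0
    return basis, fallback


def bicor_matrix(normexpr) -> pd.DataFrame:
    """Biweight midcorrelation between all gene pairs (9-MAD tuning).

    ``normexpr`` is genes x samples.  Genes with zero MAD use Pearson
    correlation instead (standard fallback); the result is symmetric with
    unit diagonal and values in [-1, 1].
    """
    X = np.asarray(normexpr, dtype=float)
    if X.shape[1] < 4:
        raise ValueError("need at least 4 samples for bicor")
    basis, _ = _bicor_basis(X)
    cor = np.clip(basis @ basis.T, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    if isinstance(normexpr, pd.DataFrame):
        return pd.DataFrame(cor, index=normexpr.index, columns=normexpr.index)
    return cor


def signed_adjacency(cor, beta: int = 12):
    """Signed soft-threshold adjacency ``((1 + cor)/2)**beta``, unit diagonal."""
    C = np.asarray(cor, dtype=float)
    if np.any(C < -1 - 1e-9) or np.any(C > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    A = ((1.0 + np.clip(C, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(A, index=cor.index, columns=cor.columns)
    return A


def tom_similarity(adj):
    """Topological overlap with the mean denominator.

    ``tom_ij = (l_ij + a_ij) / ((k_i + k_j)/2 - a_ij + 1)`` where
    ``l_ij = sum_u a_iu a_uj`` over ``u != i, j`` and ``k_i`` is the
    connectivity of node i excluding itself; the diagonal is 1.
    """
    A = np.asarray(adj, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0  # (A0^2)_ij = sum_{u != i,j} a_iu a_uj for i != j (diag terms removed)
    k = A0.sum(axis=1)
    denom = (k[:, None] + k[None, :]) / 2.0 - A0 + 1.0
    tom = (L + A0) / denom
    np.fill_diagonal(tom, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def _eigengene(X_module: np.ndarray) -> np.ndarray:
    """First PC of standardized module expression, sign-oriented to the
    module mean profile and scaled to unit variance."""
    Z = X_module - X_module.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = Z / sd
    # first right singular vector spans the sample scores
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    score = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(score, mean_profile) < 0:
        score = -score
    sd_score = score.std()
    return score / (sd_score if sd_score > 0 else 1.0)


def _eigengene_table(X: np.ndarray, labels: np.ndarray) -> dict[int, np.ndarray]:
    return {
        mid: _eigengene(X[labels == mid])
        for mid in sorted(set(labels) - {0})
    }


def _merge_modules(
    X: np.ndarray, labels: np.ndarray, merge_cut_height: float
) -> np.ndarray:
    """Iteratively merge module pairs with eigengene dissimilarity
    (1 - Pearson cor) below the cut height, closest pair first."""
    labels = labels.copy()
    while True:
        ids = sorted(set(labels) - {0})
        if len(ids) < 2:
            return labels
        eig = _eigengene_table(X, labels)
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                c = np.corrcoef(eig[a], eig[b])[0, 1]
                d = 1.0 - c
                if d < merge_cut_height and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            return labels
        _, a, b = best
        labels[labels == b] = a


def _kme(X: np.ndarray, eigengenes: dict[int, np.ndarray]) -> np.ndarray:
    """bicor of every gene with every module eigengene."""
    ids = sorted(eigengenes)
    gene_basis, _ = _bicor_basis(X)
    eig_basis, _ = _bicor_basis(np.array([eigengenes[m] for m in ids]))
    return np.clip(gene_basis @ eig_basis.T, -1.0, 1.0)


def detect_modules(normexpr, params: NetworkParams | None = None) -> ModuleSet:
    """Detect co-expression modules in a genes x samples expression matrix.

    Returns a :class:`ModuleSet` with modules renumbered 1..M in decreasing
    size; genes in no module carry id 0.  A warning-worthy all-noise input
    yields an empty module set.
    """
    params = params or NetworkParams()
    if isinstance(normexpr, pd.DataFrame):
        genes = normexpr.index
        samples = normexpr.columns
        X = normexpr.to_numpy(dtype=float)
    else:
        X = np.asarray(normexpr, dtype=float)
        genes = pd.RangeIndex(X.shape[0])
        samples = pd.RangeIndex(X.shape[1])
    if X.shape[0] < params.min_module_size:
        raise ValueError("fewer genes than min_module_size")

    cor = bicor_matrix(X)
    adj = signed_adjacency(cor, params.beta)
    tom = tom_similarity(adj)
    diss = 1.0 - np.asarray(tom)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    Z = average(squareform(diss, checks=False))
    heights = Z[:, 2]
    q5, top = float(np.quantile(heights, 0.05)), float(heights.max())
    cut = q5 + DEEP_SPLIT_FRACTIONS[params.deep_split] * (top - q5)
    raw = fcluster(Z, t=cut, criterion="distance")

    labels = np.zeros(X.shape[0], dtype=int)
    next_id = 1
    for cl in np.unique(raw):
        mask = raw == cl
        if mask.sum() >= params.min_module_size:
            labels[mask] = next_id
            next_id += 1

    if not labels.any():
        empty = ModuleSet(
            assignments=pd.Series(labels, index=genes, name="module"),
            eigengenes=pd.DataFrame(index=samples),
            kme=pd.DataFrame(index=genes),
            params=params,
        )
        return empty

    labels = _merge_modules(X, labels, params.merge_cut_height)

    # kME-based reassignment between modules (one pass)
    eig = _eigengene_table(X, labels)
    ids = sorted(eig)
    kme = _kme(X, eig)
    col_of = {m: j for j, m in enumerate(ids)}
    for g in range(X.shape[0]):
        own = labels[g]
        if own == 0:
            continue
        best_j = int(np.argmax(kme[g]))
        best_m = ids[best_j]
        if best_m != own and kme[g, best_j] - kme[g, col_of[own]] >= params.reassign_threshold:
            labels[g] = best_m

    # drop modules that fell below the minimum size, then renumber by size
    for m in sorted(set(labels) - {0}):
        if (labels == m).sum() < params.min_module_size:
            labels[labels == m] = 0
    ids_by_size = sorted(
        set(labels) - {0}, key=lambda m: (-(labels == m).sum(), m)
    )
    renumber = {old: new for new, old in enumerate(ids_by_size, start=1)}
    labels = np.array([renumber.get(m, 0) for m in labels])

    if not labels.any():
        return ModuleSet(
            assignments=pd.Series(labels, index=genes, name="module"),
            eigengenes=pd.DataFrame(index=samples),
            kme=pd.DataFrame(index=genes),
            params=params,
        )

    eig = _eigengene_table(X, labels)
    ids = sorted(eig)
    kme = _kme(X, eig)
    eigengenes = pd.DataFrame(
        {f"ME{m}": eig[m] for m in ids}, index=samples
    )
    kme_df = pd.DataFrame(kme, index=genes, columns=[f"ME{m}" for m in ids])
    return ModuleSet(
        assignments=pd.Series(labels, index=genes, name="module"),
        eigengenes=eigengenes,
        kme=kme_df,
        params=params,
    )


def hub_genes(moduleset: ModuleSet, k: int = 5) -> pd.DataFrame:
    """Top-k genes per module by own-module kME."""
    rows = []
    for m in moduleset.module_ids:
        col = f"ME{m}"
        members = moduleset.assignments.index[moduleset.assignments == m]
        ranked = moduleset.kme.loc[members, col].sort_values(ascending=False).head(k)
        for rank, (gene, val) in enumerate(ranked.items(), start=1):
            rows.append({"module": m, "rank": rank, "gene": gene, "kME": val})
    return pd.DataFrame(rows, columns=["module", "rank", "gene", "kME"])


def module_group_test(
    moduleset: ModuleSet, sample_table: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum on eigengene scores, Bonferroni-adjusted
    over group pairs within each module."""
    from itertools import combinations

    groups = sample_table["group"]
    names = [g for g in groups.unique()]
    pairs = list(combinations(names, 2))
    rows = []
    for m in moduleset.module_ids:
        scores = moduleset.eigengenes[f"ME{m}"]
        for g1, g2 in pairs:
            x = scores[groups == g1].to_numpy()
            y = scores[groups == g2].to_numpy()
            if len(x) < 3 or len(y) < 3:
                rows.append(
                    {
                        "module": m, "group1": g1, "group2": g2,
                        "pvalue": np.nan, "p_adj": np.nan,
                        "exact": False, "skipped": True, "median_diff": np.nan,
                    }
                )
                continue
            p, exact = rank_sum_test(x, y)
            rows.append(
                {
                    "module": m, "group1": g1, "group2": g2,
                    "pvalue": p, "p_adj": min(1.0, p * len(pairs)),
                    "exact": exact, "skipped": False,
                    "median_diff": float(np.median(y) - np.median(x)),
                }
            )
    return pd.DataFrame(rows)


def classify_module_treatment(test_table: pd.DataFrame, p_max: float = 0.05) -> pd.Series:
    """Label each module dampened / accelerated / other from eigengene tests.

    Mirrors the gene-level logic on eigengene scores: accelerated when the
    treated arm differs from sham in the same direction as the 1-week arm
    (both adjusted p <= 0.05) while the 1-day arm does not; dampened when
    the 1-day arm differs from sham but the treated arm does not, and the
    treated arm differs from the 1-day arm.
    """
    required = {"sham", "injured_1d", "injured_1wk", "treated_1d"}
    present = set(test_table["group1"]) | set(test_table["group2"])
    if not required <= present:
        raise ValueError(f"missing groups: {sorted(required - present)}")

    def lookup(df, g1, g2):
        row = df[((df.group1 == g1) & (df.group2 == g2))]
        if len(row):
            return row.iloc[0]["p_adj"], row.iloc[0]["median_diff"]
        row = df[((df.group1 == g2) & (df.group2 == g1))]
        if len(row):
            return row.iloc[0]["p_adj"], -row.iloc[0]["median_diff"]
        raise ValueError(f"pair ({g1}, {g2}) missing from test table")

    labels = {}
    for m, df in test_table.groupby("module"):
        p_1d, d_1d = lookup(df, "sham", "injured_1d")
        p_1wk, d_1wk = lookup(df, "sham", "injured_1wk")
        p_tr, d_tr = lookup(df, "sham", "treated_1d")
        p_tr1d, _ = lookup(df, "injured_1d", "treated_1d")
        sig = lambda p: (not np.isnan(p)) and p <= p_max
        if sig(p_tr) and sig(p_1wk) and not sig(p_1d) and np.sign(d_tr) == np.sign(d_1wk):
            labels[m] = "accelerated"
        elif sig(p_1d) and not sig(p_tr) and sig(p_tr1d):
            labels[m] = "dampened"
        else:
            labels[m] = "other"
    return pd.Series(labels, name="label").rename_axis("module")
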