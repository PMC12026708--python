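"""Count I/O, filtering, median-of-ratios normalization, and sample QC.

The preprocessing chain mirrors a standard bulk RNA-seq workflow: drop
shallow samples, drop genes that are low in too many samples, estimate
per-sample size factors by the median-of-ratios method, transform to
``log2(count / size_factor + 1)``, and remove multivariate outlier samples
by Mahalanobis distance in principal-component space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from scipy.stats import chi2
from sklearn.decomposition import PCA

__all__ = [
    "GROUPS",
    "REGIONS",
    "CountExperiment",
    "NormalizedExperiment",
    "read_counts",
    "write_counts",
    "filter_samples",
    "filter_genes",
    "size_factors",
    "normalize_transform",
    "mahalanobis_outliers",
    "qc_housekeeping",
    "HOUSEKEEPING_GENES",
]

GROUPS = frozenset({"sham", "injured_1d", "injured_1wk", "treated_1d"})
REGIONS = frozenset({"FC", "HA"})

#: stably expressed genes used as a normalization sanity check
HOUSEKEEPING_GENES = ("RTF2", "PPIB", "YIPF3", "PSMB4")


@dataclass
class CountExperiment:
    """A genes x samples integer count matrix with sample metadata.

    ``sample_table`` is indexed by sample id and must carry ``group`` and
    ``region`` columns from the closed vocabularies, plus ``subject`` and an
    optional ``aligned_read_count``.
    """

    counts: pd.DataFrame
    sample_table: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:10]}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:10]}")
        values = c.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
            self.counts = c.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(c.columns) - set(self.sample_table.index)
        extra = set(self.sample_table.index) - set(c.columns)
        if missing or extra:
            raise ValueError(
                f"counts/metadata sample mismatch: missing from metadata "
                f"{sorted(missing)}, missing from counts {sorted(extra)}"
            )
        self.sample_table = self.sample_table.loc[c.columns]
        bad_groups = set(self.sample_table["group"]) - GROUPS
        if bad_groups:
            raise ValueError(f"unknown groups: {sorted(bad_groups)}")
        bad_regions = set(self.sample_table["region"]) - REGIONS
        if bad_regions:
            raise ValueError(f"unknown regions: {sorted(bad_regions)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset(self, genes=None, samples=None, note: str | None = None) -> "CountExperiment":
        counts = self.counts
        if genes is not None:
            counts = counts.loc[genes]
        if samples is not None:
            counts = counts[samples]
        log = list(self.log)
        if note:
            log.append(note)
        return CountExperiment(
            counts=counts, sample_table=self.sample_table.loc[counts.columns], log=log
        )


@dataclass
class NormalizedExperiment:
    """Size factors plus ``log2(count/size_factor + 1)`` expression."""

    size_factors: pd.Series
    normexpr: pd.DataFrame
    sample_table: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if not np.isfinite(self.normexpr.to_numpy()).all():
            raise ValueError("normalized expression must be finite")


def _read_mtx_triplet(counts_path: Path) -> pd.DataFrame:
    rows_path = counts_path.with_suffix(counts_path.suffix + ".rows")
    cols_path = counts_path.with_suffix(counts_path.suffix + ".cols")
    for p in (rows_path, cols_path):
        if not p.exists():
            raise FileNotFoundError(f"MTX sidecar file not found: {p}")
    mat = scipy.io.mmread(counts_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = rows_path.read_text().split()
    samples = cols_path.read_text().split()
    return pd.DataFrame(np.asarray(mat), index=genes, columns=samples)


def read_counts(counts_path: str | Path, metadata_path: str | Path) -> CountExperiment:
    """Read a count matrix (TSV or MatrixMarket triplet) and metadata TSV.

    A ``.mtx`` counts file needs ``<file>.mtx.rows`` and ``<file>.mtx.cols``
    sidecars listing gene and sample ids, one per line.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        counts = _read_mtx_triplet(counts_path)
    else:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return CountExperiment(counts=counts, sample_table=metadata)


def write_counts(exp: CountExperiment, out_dir: str | Path, fmt: str = "tsv") -> None:
    """Write counts (TSV or MTX triplet) and the sample metadata table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        exp.counts.to_csv(out / "counts.tsv", sep="\t")
    elif fmt == "mtx":
        path = out / "counts.mtx"
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(exp.counts.to_numpy()))
        path.with_suffix(".mtx.rows").write_text("\n".join(exp.gene_ids) + "\n")
        path.with_suffix(".mtx.cols").write_text("\n".join(exp.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    exp.sample_table.to_csv(out / "metadata.tsv", sep="\t")


def filter_samples(exp: CountExperiment, min_aligned_reads: float = 10_000_000) -> CountExperiment:
    """Drop samples with fewer than ``min_aligned_reads`` aligned reads."""
    if min_aligned_reads <= 0:
        return exp
    if "aligned_read_count" not in exp.sample_table.columns:
        raise ValueError("sample filter needs an aligned_read_count metadata column")
    keep = exp.sample_table["aligned_read_count"] >= min_aligned_reads
    if not keep.any():
        raise ValueError("sample filter removed every sample")
    dropped = exp.sample_table.index[~keep].tolist()
    return exp.subset(
        samples=exp.sample_table.index[keep],
        note=f"filter_samples(min_aligned_reads={min_aligned_reads}): dropped {dropped}",
    )


def filter_genes(
    exp: CountExperiment, min_count: int = 50, max_low_samples: int = 20
) -> CountExperiment:
    """Keep a gene iff it is low (< ``min_count``) in at most
    ``max_low_samples`` samples (strictly "more than" removes)."""
    if min_count < 0 or max_low_samples < 0:
        raise ValueError("thresholds must be non-negative")
    if min_count == 0:
        return exp
    n_low = (exp.counts < min_count).sum(axis=1)
    keep = n_low <= max_low_samples
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return exp.subset(
        genes=exp.gene_ids[keep],
        note=(
            f"filter_genes(min_count={min_count}, max_low_samples={max_low_samples}): "
            f"dropped {int((~keep).sum())} genes"
        ),
    )


def size_factors(exp: CountExperiment) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-gene geometric mean over samples, restricted to
    genes with strictly positive counts in every sample; each sample's size
    factor is the median of its count/reference ratios over those genes.
    No rescaling is applied afterwards.
    """
    counts = exp.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has strictly positive counts in every sample; "
            "median-of-ratios needs at least one (pseudo-reference fallback is disabled)"
        )
    ref = np.exp(np.log(counts[all_pos]).mean(axis=1))
    ratios = counts[all_pos] / ref[:, None]
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=exp.sample_ids, name="size_factor")


def normalize_transform(exp: CountExperiment, s: pd.Series) -> NormalizedExperiment:
    """``log2(count / size_factor + 1)`` expression."""
    if (s.loc[exp.sample_ids] <= 0).any():
        raise ValueError("size factors must be positive")
    normexpr = np.log2(exp.counts / s.loc[exp.sample_ids] + 1.0)
    return NormalizedExperiment(
        size_factors=s.loc[exp.sample_ids],
        normexpr=normexpr,
        sample_table=exp.sample_table,
        provenance=list(exp.log),
    )


def mahalanobis_outliers(
    norm: NormalizedExperiment, n_pcs: int = 10, quantile: float = 0.975
) -> tuple[list[str], list[str], pd.Series]:
    """Flag outlier samples by squared Mahalanobis distance on PC scores.

    Samples are projected onto the top ``n_pcs`` principal components
    (genes as features, centered); a sample is removed when its squared
    Mahalanobis distance under the scores' covariance exceeds the
    ``chi2(n_pcs)`` quantile.  ``n_pcs`` is capped at ``n_samples - 2``.
    """
    X = norm.normexpr.to_numpy().T  # samples x genes
    n_samples = X.shape[0]
    k = min(n_pcs, n_samples - 2)
    if k < 2:
        raise ValueError("need n_samples > n_pcs >= 2")
    if np.allclose(X, X.mean(axis=0, keepdims=True)):
        d2 = pd.Series(np.zeros(n_samples), index=norm.normexpr.columns, name="d2")
        return list(norm.normexpr.columns), [], d2
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # component variances; drop numerically dead directions
    variances = scores.var(axis=0, ddof=1)
    total = variances.sum()
    if total <= 1e-12:
        d2 = pd.Series(np.zeros(n_samples), index=norm.normexpr.columns, name="d2")
        return list(norm.normexpr.columns), [], d2
    alive = variances > 1e-12 * total
    if not alive.all():
        scores = scores[:, alive]
        variances = variances[alive]
    if scores.shape[1] < 2:
        raise ValueError("covariance of PC scores is singular; use fewer PCs")
    # PCA scores are uncorrelated, so the covariance is diagonal
    d2_vals = ((scores**2) / variances[None, :]).sum(axis=1)
    cutoff = chi2.ppf(quantile, df=scores.shape[1])
    d2 = pd.Series(d2_vals, index=norm.normexpr.columns, name="d2")
    removed = d2.index[d2_vals > cutoff].tolist()
    kept = d2.index[d2_vals <= cutoff].tolist()
    return kept, removed, d2


def qc_housekeeping(
    norm: NormalizedExperiment,
    housekeeping_ids: tuple[str, ...] = HOUSEKEEPING_GENES,
    cv_threshold: float = 0.2,
) -> tuple[pd.DataFrame, bool]:
    """Coefficient of variation of housekeeping-gene expression.

    Returns the per-gene CV table (absent ids flagged) and a pass flag that
    is true iff every present housekeeping gene has CV below the threshold.
    """
    rows = []
    present_any = False
    for gid in housekeeping_ids:
        if gid not in norm.normexpr.index:
            warnings.warn(f"housekeeping gene {gid!r} absent from matrix")
            rows.append({"gene": gid, "mean": np.nan, "cv": np.nan, "present": False})
            continue
        present_any = True
        x = norm.normexpr.loc[gid].to_numpy()
        mean = x.mean()
        cv = x.std(ddof=1) / mean if mean > 0 else np.inf
        rows.append({"gene": gid, "mean": mean, "cv": cv, "present": True})
    if not present_any:
        raise ValueError("no housekeeping gene present in the matrix")
    table = pd.DataFrame(rows).set_index("gene")
    ok = bool((table.loc[table["present"], "cv"] < cv_threshold).all())
    return table, ok
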