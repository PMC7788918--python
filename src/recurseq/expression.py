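"""Expression normalization and pair-similarity clustering.

Raw gene-level counts are scaled between samples with the trimmed mean of
M-values (TMM) method and expressed as log2 counts-per-million
(``log2normCPM``), the expression scale used by every downstream stage.
Primary/recurrence transcriptional similarity is quantified by hierarchical
clustering on the most variable genes under a 1 - Pearson correlation
distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ._util import pearson_with_p

__all__ = [
    "ExpressionMatrix",
    "PairSimilarity",
    "tmm_factors",
    "lognorm_cpm",
    "variable_genes",
    "cluster_pairs",
    "similarity_vs_dfs",
    "linkage_to_newick",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples count matrix with derived normalized values.

    Parameters
    ----------
    counts
        Non-negative integer counts, genes as rows, samples as columns.

    Attributes
    ----------
    libsize : pandas.Series
        Column sums of ``counts``.
    tmm_factor : pandas.Series or None
        Per-sample TMM scaling factors (geometric mean 1); set by
        :meth:`normalize`.
    lognorm : pandas.DataFrame or None
        log2-scale TMM-normalized CPM values; set by :meth:`normalize`.
    """

    counts: pd.DataFrame
    libsize: pd.Series = field(init=False)
    tmm_factor: pd.Series | None = field(init=False, default=None)
    lognorm: pd.DataFrame | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.libsize = self.counts.sum(axis=0)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def normalize(self, prior: float = 0.5) -> "ExpressionMatrix":
        """Compute TMM factors and log2normCPM values in place."""
        self.tmm_factor = tmm_factors(self.counts)
        self.lognorm = lognorm_cpm(self.counts, self.tmm_factor, prior=prior)
        return self


@dataclass
class PairSimilarity:
    """Transcriptional similarity of one primary/recurrence pair."""

    case_id: str
    pearson_r: float
    nearest_neighbor_is_partner: bool


def _tmm_one(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Scaling factor of one sample against the reference (log2 scale -> 2^f).

    Doubly trims the per-gene log ratios (M) and average abundances (A),
    then takes a precision-weighted mean of the retained M values, weights
    being inverse approximate binomial variances.
    """
    valid = (obs > 0) & (ref > 0)
    o, r = obs[valid].astype(float), ref[valid].astype(float)
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # approximate binomial variance of M on the log2 scale
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)

    if keep.sum() < 10:
        warnings.warn(
            f"fewer than 10 genes survive TMM trimming ({int(keep.sum())}); "
            "falling back to the untrimmed mean of M-values",
            RuntimeWarning,
            stacklevel=3,
        )
        return float(2.0 ** np.mean(m))

    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples. Returned factors
    are rescaled so their geometric mean is 1; a factor below 1 means the
    sample's counts are inflated relative to the cohort and get scaled down.

    Raises
    ------
    ValueError
        If fewer than 2 samples are given or any sample is all zeros.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero) > 0:
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")

    x = counts.values.astype(float)
    lib = libsize.values.astype(float)
    # genes absent from every sample carry no between-sample information and
    # would only deflate the reference-selection quantile
    x = x[x.sum(axis=1) > 0]
    # 75th percentile of raw counts over genes, as a fraction of library size
    f75 = np.quantile(x, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.array(
        [
            _tmm_one(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def lognorm_cpm(
    counts: pd.DataFrame,
    tmm_factor: pd.Series,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 TMM-normalized counts per million with a pseudo-count.

    ``lognorm[g, s] = log2((count + prior) / (libsize * factor + 2 * prior) * 1e6)``

    The small default prior (0.5) keeps low counts on a near-log scale and
    allows negative values for genes expressed below 1 CPM.
    """
    if prior <= 0:
        raise ValueError("prior pseudo-count must be positive")
    libsize = counts.sum(axis=0)
    eff = libsize * tmm_factor.reindex(counts.columns) + 2.0 * prior
    vals = np.log2((counts.values + prior) / eff.values[None, :] * 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def variable_genes(lognorm: pd.DataFrame, top_fraction: float = 0.10) -> list[str]:
    """Genes with the largest interquartile range across samples.

    Returns ``ceil(top_fraction * n_genes)`` genes; ties broken by
    lexicographic gene ID so the selection is deterministic.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    q1, q3 = np.quantile(lognorm.values, [0.25, 0.75], axis=1)
    iqr = pd.Series(q3 - q1, index=lognorm.index)
    k = math.ceil(top_fraction * len(iqr))
    order = iqr.to_frame("iqr").reset_index(names="gene")
    order = order.sort_values(["iqr", "gene"], ascending=[False, True])
    return order["gene"].head(k).tolist()


def _pearson_distance(lognorm: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson distance between sample columns.

    Zero-variance columns get distance 1 to every other sample (flagged via
    warning), keeping the matrix well defined.
    """
    x = lognorm.values
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            "zero-variance sample(s) in clustering input: "
            + ", ".join(np.asarray(lognorm.columns)[degenerate]),
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    d = 1.0 - corr
    d[degenerate, :] = 1.0
    d[:, degenerate] = 1.0
    np.fill_diagonal(d, 0.0)
    # numerical guard: tiny negative values from corr rounding
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=lognorm.columns, columns=lognorm.columns)


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height - 0.0:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def cluster_pairs(
    lognorm: pd.DataFrame,
    gene_subset: list[str],
    cases: pd.DataFrame,
) -> tuple[np.ndarray, str, pd.DataFrame]:
    """Average-linkage clustering of samples under 1 - Pearson distance.

    Parameters
    ----------
    lognorm
        Normalized expression, genes x samples.
    gene_subset
        Genes used for the distance (typically the top-IQR set).
    cases
        Case table with columns ``case_id``, ``primary_sample``,
        ``recurrence_sample``.

    Returns
    -------
    linkage, newick, pairs
        The scipy linkage matrix, its Newick rendering, and one
        :class:`PairSimilarity` row per case (``nearest_neighbor_is_partner``
        is true when the recurrence's nearest sample is its matched primary).
    """
    if lognorm.shape[1] < 3:
        raise ValueError("clustering requires at least 3 samples")
    sub = lognorm.loc[gene_subset].sort_index(axis=1)  # deterministic order
    dist = _pearson_distance(sub)
    link = hierarchy.linkage(
        dist.values[np.triu_indices(dist.shape[0], k=1)], method="average"
    )
    newick = linkage_to_newick(link, list(dist.columns))

    rows = []
    for case in cases.itertuples():
        p, r = case.primary_sample, case.recurrence_sample
        if p not in dist.columns or r not in dist.columns:
            continue
        others = dist.loc[r].drop(r)
        # ties broken by sample-ID order (index is sorted above)
        nearest = others.index[int(np.argmin(others.values))]
        rows.append(
            PairSimilarity(
                case_id=case.case_id,
                pearson_r=float(1.0 - dist.loc[p, r]),
                nearest_neighbor_is_partner=bool(nearest == p),
            )
        )
    pairs = pd.DataFrame([vars(s) for s in rows])
    return link, newick, pairs


def similarity_vs_dfs(pairs: pd.DataFrame, dfs: pd.Series) -> tuple[float, float]:
    """Pearson correlation of pair similarity against disease-free survival.

    Returns (r, two-sided p); (nan, nan) with a warning when either axis is
    constant.
    """
    merged = pairs.set_index("case_id")["pearson_r"].to_frame().join(
        dfs.rename("dfs"), how="inner"
    ).dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 cases with finite values")
    return pearson_with_p(merged["pearson_r"].values, merged["dfs"].values)
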