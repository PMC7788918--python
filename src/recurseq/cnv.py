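"""Gene-level copy number from segments, purity adjustment, and concordance.

Segment calls (0-based half-open, copy number 2 = diploid) are aggregated
per gene as a probe-count-weighted mean of the overlapping segments, then
corrected for normal-cell contamination under a linear two-population
mixture: ``cn = max(0, (cn_obs - 2 * (1 - purity)) / purity)``. Pair
concordance is the Pearson correlation of gene-level values between the
primary and the recurrence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import pearson_with_p

__all__ = [
    "purity_adjust_cn",
    "gene_cn",
    "pair_cna_concordance",
    "cn_expression_correlation",
]


def purity_adjust_cn(cn_obs, purity: float):
    """Invert linear dilution by diploid normal cells; floored at 0."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    return np.maximum(0.0, (np.asarray(cn_obs, dtype=float) - 2.0 * (1.0 - purity)) / purity)


def gene_cn(segments: pd.DataFrame, gene_intervals: pd.DataFrame,
            purity: float, round_calls: bool = False) -> pd.DataFrame:
    """Purity-adjusted gene-level copy number for one sample.

    Parameters
    ----------
    segments
        One sample's segments: ``chrom, start, end, cn_obs, n_probes``
        (0-based half-open).
    gene_intervals
        ``gene, chrom, start, end`` on the same coordinate system.
    purity
        Tumor cell fraction in (0, 1].
    round_calls
        Round the adjusted value to the nearest integer (call-style output);
        off by default since downstream use is correlation.

    Returns
    -------
    One row per gene: ``gene, cn, n_probes_used, missing``; genes overlapped
    by no segment are flagged missing with NaN copy number.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    for df, what in ((segments, "segment"), (gene_intervals, "gene interval")):
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"malformed {what}: start must be < end")

    rows = []
    by_chrom = dict(tuple(segments.groupby("chrom")))
    for g in gene_intervals.itertuples():
        seg = by_chrom.get(g.chrom)
        if seg is not None:
            # half-open overlap
            hit = seg[(seg["start"] < g.end) & (seg["end"] > g.start)]
        else:
            hit = None
        if hit is None or hit.empty:
            rows.append({"gene": g.gene, "cn": np.nan, "n_probes_used": 0,
                         "missing": True})
            continue
        w = hit["n_probes"].to_numpy(dtype=float)
        mean_obs = float(np.average(hit["cn_obs"].to_numpy(dtype=float), weights=w))
        cn = float(purity_adjust_cn(mean_obs, purity))
        if round_calls:
            cn = float(np.rint(cn))
        rows.append({"gene": g.gene, "cn": cn,
                     "n_probes_used": int(w.sum()), "missing": False})
    return pd.DataFrame(rows)


def pair_cna_concordance(cn_primary: pd.DataFrame, cn_recurrence: pd.DataFrame,
                         threshold: float = 0.5,
                         min_genes: int = 20) -> tuple[float, bool]:
    """Pearson r of gene CN between primary and recurrence, plus a
    discordance flag (``r < threshold``)."""
    merged = cn_primary.merge(cn_recurrence, on="gene", suffixes=("_p", "_r")).dropna(
        subset=["cn_p", "cn_r"]
    )
    if len(merged) < min_genes:
        raise ValueError(
            f"only {len(merged)} genes with copy number in both samples (< {min_genes})"
        )
    r, _ = pearson_with_p(merged["cn_p"].values, merged["cn_r"].values)
    return r, bool(np.isnan(r) or r < threshold)


def cn_expression_correlation(cn_by_sample: pd.DataFrame,
                              lognorm: pd.DataFrame, gene: str) -> tuple[float, float]:
    """Pearson r between one gene's CN and its expression across samples.

    ``cn_by_sample`` holds ``sample_id, gene, cn``; samples present in both
    inputs are used.
    """
    sub = cn_by_sample[cn_by_sample["gene"] == gene].dropna(subset=["cn"])
    shared = [s for s in sub["sample_id"] if s in lognorm.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 samples with both CN and expression")
    cn = sub.set_index("sample_id").loc[shared, "cn"].to_numpy(dtype=float)
    expr = lognorm.loc[gene, shared].to_numpy(dtype=float)
    return pearson_with_p(cn, expr)
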