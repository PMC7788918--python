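"""Paired differential expression with moderated variance and BH FDR.

For each gene the per-case recurrence-minus-primary deltas are tested with
a paired t statistic whose variance is shrunk toward the cohort-wide mean
gene variance with a prior of ``d0`` degrees of freedom (``d0 = 0`` is the
textbook paired t). This is an unweighted approximation of the
limma-voom empirical-Bayes pipeline: precision weights are omitted and the
shrinkage target is the plain mean variance rather than a fitted prior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["paired_de", "bh_adjust", "report_filter"]


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if np.any((p[ok] <= 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def paired_de(lognorm: pd.DataFrame, cases: pd.DataFrame, d0: float = 4.0) -> pd.DataFrame:
    """Moderated paired t test of recurrence vs primary expression per gene.

    Parameters
    ----------
    lognorm
        Normalized expression, genes x samples.
    cases
        Case subset with ``primary_sample``/``recurrence_sample`` columns;
        every case must have both samples present.
    d0
        Prior degrees of freedom of the variance moderation; 0 recovers the
        ordinary paired t test.

    Returns
    -------
    One row per gene with ``log2fc`` (mean paired delta), ``avg_expr``
    (mean lognorm over all samples in the contrast), ``t_stat``,
    ``p_nominal`` (two-sided, n - 1 + d0 df), ``p_fdr`` and ``n_pairs``.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 cases for a paired test")
    missing = [s for c in cases.itertuples()
               for s in (c.primary_sample, c.recurrence_sample)
               if s not in lognorm.columns]
    if missing:
        raise ValueError(f"samples missing from expression matrix: {missing}")

    prim = lognorm[[c.primary_sample for c in cases.itertuples()]].values
    rec = lognorm[[c.recurrence_sample for c in cases.itertuples()]].values
    d = rec - prim
    n = d.shape[1]
    mean_d = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    s2_prior = float(np.mean(s2))
    df_res = n - 1
    s2_mod = (d0 * s2_prior + df_res * s2) / (d0 + df_res) if d0 > 0 else s2

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / np.sqrt(s2_mod / n)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_res + d0)
    degenerate = s2_mod == 0
    t[degenerate] = np.nan
    p[degenerate] = np.nan  # zero moderated variance: test undefined

    res = pd.DataFrame({
        "gene": lognorm.index,
        "log2fc": mean_d,
        "avg_expr": np.concatenate([prim, rec], axis=1).mean(axis=1),
        "t_stat": t,
        "p_nominal": np.minimum(p, 1.0),
        "n_pairs": n,
        "variance_degenerate": degenerate,
    })
    res["p_fdr"] = bh_adjust(res["p_nominal"])
    return res


def report_filter(results: pd.DataFrame, min_avg: float = 2.0,
                  max_p: float = 0.05, min_abs_lfc: float = 0.5) -> pd.DataFrame:
    """Reporting filter for candidate genes.

    Keeps genes with ``avg_expr >= min_avg``, nominal p < ``max_p`` and
    ``|log2fc| > min_abs_lfc``, sorted by p then gene ID.
    """
    keep = (
        (results["avg_expr"] >= min_avg)
        & (results["p_nominal"] < max_p)
        & (results["log2fc"].abs() > min_abs_lfc)
    )
    out = results[keep.fillna(False)]
    return out.sort_values(["p_nominal", "gene"]).reset_index(drop=True)
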