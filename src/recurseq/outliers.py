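"""Per-case outlier expression gain/loss classification.

Each gene's recurrence-minus-primary log2 fold change is judged against
Tukey fences computed from that case's own distribution of log2FC values
over all genes: beyond Q1/Q3 -/+ 1.5*IQR is an outlier loss/gain, beyond
-/+ 3*IQR an extreme loss/gain, and everything in between (boundaries
included) is stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "OutlierFences",
    "pair_deltas",
    "case_fences",
    "classify",
    "classify_case",
    "classify_cohort",
    "recurrence_tally",
    "select_depleted_cases",
]

CATEGORIES = ("ExtremeLoss", "OutlierLoss", "Stable", "OutlierGain", "ExtremeGain")

_QUANTILE_METHODS = {7: "linear", 6: "weibull"}


@dataclass
class OutlierFences:
    """Case-specific Tukey fences on the log2FC distribution."""

    case_id: str
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower_out(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def lower_ext(self) -> float:
        return self.q1 - 3.0 * self.iqr

    @property
    def upper_out(self) -> float:
        return self.q3 + 1.5 * self.iqr

    @property
    def upper_ext(self) -> float:
        return self.q3 + 3.0 * self.iqr


def pair_deltas(lognorm: pd.DataFrame, cases: pd.DataFrame,
                counts: pd.DataFrame | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-gene recurrence-minus-primary log2FC, one column per case.

    When raw ``counts`` are supplied, a boolean mask of genes with zero
    counts in both samples of a case is returned alongside; those deltas are
    forced to 0 (they carry no signal, only pseudo-count arithmetic).
    """
    deltas = {}
    zeros = {}
    for c in cases.itertuples():
        d = lognorm[c.recurrence_sample] - lognorm[c.primary_sample]
        if counts is not None:
            z = (counts[c.recurrence_sample] == 0) & (counts[c.primary_sample] == 0)
            d = d.where(~z, 0.0)
            zeros[c.case_id] = z
        deltas[c.case_id] = d
    dd = pd.DataFrame(deltas)
    zz = pd.DataFrame(zeros) if counts is not None else None
    return dd, zz


def case_fences(deltas, case_id: str = "", quartile_type: int = 7) -> OutlierFences:
    """Tukey fences from one case's log2FC values.

    Quartiles use linear interpolation between order statistics by default
    (quantile type 7); type 6 is available since the convention shifts
    fences at small n.
    """
    x = np.asarray(deltas, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 genes to compute fences")
    method = _QUANTILE_METHODS[quartile_type]
    q1, q3 = np.quantile(x, [0.25, 0.75], method=method)
    return OutlierFences(case_id=case_id, q1=float(q1), q3=float(q3))


def classify(delta: float, fences: OutlierFences) -> str:
    """Category of one log2FC given the case fences.

    Extreme categories take precedence over outlier ones; values equal to a
    fence are Stable (strict inequalities).
    """
    if delta < fences.lower_ext:
        return "ExtremeLoss"
    if delta < fences.lower_out:
        return "OutlierLoss"
    if delta > fences.upper_ext:
        return "ExtremeGain"
    if delta > fences.upper_out:
        return "OutlierGain"
    return "Stable"


def classify_case(deltas: pd.Series, case_id: str,
                  zero_mask: pd.Series | None = None,
                  quartile_type: int = 7) -> tuple[pd.DataFrame, OutlierFences]:
    """Classify every gene of one case; returns (calls, fences)."""
    fences = case_fences(deltas.values, case_id, quartile_type)
    x = deltas.values.astype(float)
    cat = np.full(x.shape, "Stable", dtype=object)
    cat[x < fences.lower_out] = "OutlierLoss"
    cat[x < fences.lower_ext] = "ExtremeLoss"
    cat[x > fences.upper_out] = "OutlierGain"
    cat[x > fences.upper_ext] = "ExtremeGain"
    if zero_mask is not None:
        cat[zero_mask.values] = "Stable"  # zero-in-both genes are uninformative
    calls = pd.DataFrame({
        "case_id": case_id, "gene": deltas.index, "log2fc": x, "category": cat,
    })
    return calls, fences


def classify_cohort(deltas: pd.DataFrame, zero_masks: pd.DataFrame | None = None,
                    quartile_type: int = 7
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify all cases; returns (calls, fence table)."""
    all_calls, fence_rows = [], []
    for case_id in deltas.columns:
        zm = zero_masks[case_id] if zero_masks is not None else None
        calls, f = classify_case(deltas[case_id], case_id, zm, quartile_type)
        all_calls.append(calls)
        fence_rows.append({
            "case_id": case_id, "q1": f.q1, "q3": f.q3, "iqr": f.iqr,
            "lower_out": f.lower_out, "lower_ext": f.lower_ext,
            "upper_out": f.upper_out, "upper_ext": f.upper_ext,
        })
    return pd.concat(all_calls, ignore_index=True), pd.DataFrame(fence_rows)


def recurrence_tally(calls: pd.DataFrame, n_cases: int | None = None) -> pd.DataFrame:
    """Per-gene counts and rounded percentages of gain/loss cases.

    Sorted by ``max(n_gain, n_loss)`` descending, then gene ID, mirroring an
    OncoPrint ordered by event recurrence.
    """
    if calls.empty:
        raise ValueError("no classified cases")
    if n_cases is None:
        n_cases = calls["case_id"].nunique()
    gain = calls["category"].isin(["OutlierGain", "ExtremeGain"])
    loss = calls["category"].isin(["OutlierLoss", "ExtremeLoss"])
    tally = pd.DataFrame({
        "n_gain": calls[gain].groupby("gene").size(),
        "n_loss": calls[loss].groupby("gene").size(),
    }).reindex(calls["gene"].unique()).fillna(0).astype(int)
    tally.index.name = "gene"
    tally["pct_gain"] = (tally["n_gain"] / n_cases * 100).round().astype(int)
    tally["pct_loss"] = (tally["n_loss"] / n_cases * 100).round().astype(int)
    tally["n_max"] = tally[["n_gain", "n_loss"]].max(axis=1)
    tally = tally.sort_values(["n_max", "gene"], ascending=[False, True])
    return tally.drop(columns="n_max").reset_index()


def select_depleted_cases(calls: pd.DataFrame, gene: str = "ESR1") -> list[str]:
    """Cases whose recurrence shows an outlier/extreme expression loss of ``gene``."""
    sub = calls[calls["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from the classified panel")
    hit = sub[sub["category"].isin(["OutlierLoss", "ExtremeLoss"])]
    return sorted(hit["case_id"].tolist())
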