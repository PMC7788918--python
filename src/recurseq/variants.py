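"""Recurrence-enriched variant determination.

A variant is called *recurrence-enriched* when it survives a cascade of
filters patterned on paired tumor/recurrence panel sequencing practice:

1. candidacy — covered >= 40X in both tumors, AF >= 0.05 in at least one
   tumor with >= 5 supporting reads in that tumor;
2. germline exclusion — normal AF > 0.30 when a matched normal exists;
3. cohort blacklist — sites called in >= 3 normals are presumed
   fixation/sequencing artifacts and removed;
4. enrichment — one-sided Fisher exact test on the (alt, ref) read table
   (p < 0.05), a > 2-fold gain in purity-adjusted AF, purity-adjusted
   recurrence AF >= 0.10, a non-silent functional class, and population
   AF < 0.01.

Allele frequencies are corrected for tumor purity by linear rescaling
(``af / purity``, capped at 1), the simplest model of dilution by
contaminating normal cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import pearson_with_p

__all__ = [
    "EnrichmentParams",
    "Blacklist",
    "candidate_filter",
    "purity_adjust_af",
    "germline_exclude",
    "build_blacklist",
    "enrichment_test",
    "enriched_call",
    "enrich_variants",
    "enrichment_vs_dfs",
    "oncoprint_matrix",
    "patient_match_check",
]

NONSILENT = {"missense", "nonsense", "splice", "frameshift", "other_nonsilent"}


@dataclass
class EnrichmentParams:
    """Thresholds of the enrichment cascade (defaults are the working values)."""

    min_coverage: int = 40
    min_af: float = 0.05
    min_alt_reads: int = 5
    coverage_rule: str = "both"  # or "either"
    germline_af: float = 0.30
    blacklist_min_support: int = 3
    max_p: float = 0.05
    min_fold: float = 2.0
    min_recurrence_af: float = 0.10
    max_pop_af: float = 0.01


@dataclass
class Blacklist:
    """Sites called in multiple cohort normals, presumed technical artifacts."""

    entries: dict[tuple, int] = field(default_factory=dict)  # site -> support_count

    def __contains__(self, key: tuple) -> bool:
        return key in self.entries

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "support_count": v}
             for k, v in sorted(self.entries.items())],
            columns=["chrom", "pos", "ref", "alt", "support_count"],
        )


def _require(v, fields: list[str]) -> None:
    for f in fields:
        if f not in v or pd.isna(v[f]):
            role = f.split("_")[0]
            raise KeyError(f"variant record missing {f!r} for sample role {role!r}")


def candidate_filter(v, params: EnrichmentParams = EnrichmentParams()) -> tuple[bool, list]:
    """Candidacy check on one variant record (mapping or Series).

    Pass requires coverage >= ``min_coverage`` in both tumors, AF >=
    ``min_af`` in at least one tumor, and >= ``min_alt_reads`` supporting
    reads in a tumor that meets the AF criterion.
    """
    _require(v, ["primary_depth", "primary_alt", "primary_af",
                 "recurrence_depth", "recurrence_alt", "recurrence_af"])
    trace = []
    depths = [v["primary_depth"], v["recurrence_depth"]]
    if params.coverage_rule == "both":
        cov_ok = min(depths) >= params.min_coverage
    else:
        cov_ok = max(depths) >= params.min_coverage
    trace.append(("coverage", bool(cov_ok)))

    af_roles = [r for r in ("primary", "recurrence") if v[f"{r}_af"] >= params.min_af]
    trace.append(("allele_frequency", bool(af_roles)))

    reads_ok = any(v[f"{r}_alt"] >= params.min_alt_reads for r in af_roles)
    trace.append(("supporting_reads", bool(reads_ok)))

    return all(ok for _, ok in trace), trace


def purity_adjust_af(af: float, purity: float) -> float:
    """Linear purity correction: ``min(1, af / purity)``."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    if not 0 <= af <= 1:
        raise ValueError("af must be in [0, 1]")
    return min(1.0, af / purity)


def germline_exclude(variants: pd.DataFrame, has_normal: bool,
                     germline_af: float = 0.30) -> pd.DataFrame:
    """Drop variants with normal AF above the germline threshold.

    For cases without a matched normal the table passes through unchanged
    with ``no_normal=True`` recorded, since germline status cannot be
    resolved there.
    """
    out = variants.copy()
    if not has_normal:
        out["no_normal"] = True
        return out
    out["no_normal"] = False
    return out[~(out["normal_af"] > germline_af)].copy()


def _called_in_normal(df: pd.DataFrame) -> pd.Series:
    # minimal-evidence call: >= 2 alt reads and AF >= 0.05 in that normal
    return (df["normal_alt"] >= 2) & (df["normal_af"] >= 0.05)


def build_blacklist(variants: pd.DataFrame, cases: pd.DataFrame,
                    min_support: int = 3) -> Blacklist:
    """Sites called in at least ``min_support`` distinct cohort normals."""
    normal_cases = cases[cases["normal_sample"].notna()]["case_id"]
    if len(normal_cases) < min_support:
        warnings.warn(
            f"only {len(normal_cases)} normal samples available "
            f"(< min_support={min_support}); blacklist is empty",
            RuntimeWarning,
            stacklevel=2,
        )
        return Blacklist()
    v = variants[variants["case_id"].isin(normal_cases) & variants["normal_depth"].notna()]
    called = v[_called_in_normal(v)]
    support = (
        called.groupby(["chrom", "pos", "ref", "alt"])["case_id"].nunique()
    )
    entries = {site: int(n) for site, n in support.items() if n >= min_support}
    return Blacklist(entries)


def enrichment_test(primary_alt, primary_depth, recurrence_alt, recurrence_depth):
    """One-sided Fisher exact p for the recurrence alt proportion being greater.

    Exact hypergeometric tail sum on the 2x2 table
    ``[(alt, ref) primary; (alt, ref) recurrence]``. Vectorized over arrays.
    """
    a1 = np.asarray(primary_alt)
    d1 = np.asarray(primary_depth)
    a2 = np.asarray(recurrence_alt)
    d2 = np.asarray(recurrence_depth)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("zero-depth records must be rejected upstream")
    # P(X >= a2) for X ~ Hypergeom(N = d1+d2, successes = a1+a2, draws = d2)
    p = stats.hypergeom.sf(a2 - 1, d1 + d2, a1 + a2, d2)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return float(p) if p.ndim == 0 else p


def enriched_call(v, purity_primary: float, purity_recurrence: float,
                  blacklist: Blacklist | None = None,
                  params: EnrichmentParams = EnrichmentParams()) -> dict | None:
    """Apply the five enrichment criteria to one candidate variant.

    Returns the enriched-variant record (with purity-adjusted AFs, Fisher p,
    fold gain, and the full filter trace) or None on rejection. A missing
    ``pop_af`` is treated as 0 and flagged.
    """
    trace = []
    if blacklist is not None:
        site = (v["chrom"], v["pos"], v["ref"], v["alt"])
        if site in blacklist:
            return None

    p = enrichment_test(v["primary_alt"], v["primary_depth"],
                        v["recurrence_alt"], v["recurrence_depth"])
    trace.append(("somatic_p", p < params.max_p))

    adj_p = purity_adjust_af(v["primary_af"], purity_primary)
    adj_r = purity_adjust_af(v["recurrence_af"], purity_recurrence)
    if adj_p == 0:
        fold = float("inf") if adj_r > 0 else 0.0
    else:
        fold = adj_r / adj_p
    trace.append(("fold_gain", fold > params.min_fold))
    trace.append(("recurrence_af", adj_r >= params.min_recurrence_af))
    trace.append(("non_silent", v["effect_class"] in NONSILENT))

    pop_af = v.get("pop_af", np.nan)
    pop_af_missing = pd.isna(pop_af)
    pop_af = 0.0 if pop_af_missing else float(pop_af)
    trace.append(("population_af", pop_af < params.max_pop_af))

    if not all(ok for _, ok in trace):
        return None
    rec = dict(v)
    rec.update(
        adjusted_primary_af=adj_p,
        adjusted_recurrence_af=adj_r,
        enrichment_p=p,
        fold_gain=fold,
        pop_af_missing=pop_af_missing,
        filter_trace=trace,
    )
    return rec


def enrich_variants(variants: pd.DataFrame, cases: pd.DataFrame,
                    params: EnrichmentParams = EnrichmentParams(),
                    blacklist: Blacklist | None = None
                    ) -> tuple[pd.DataFrame, Blacklist]:
    """Full cascade over a cohort variant table.

    Runs candidacy, germline exclusion, blacklist construction/removal and
    the enrichment criteria per case; output is sorted by (case, chrom, pos)
    and therefore independent of input row order.
    """
    if blacklist is None:
        blacklist = build_blacklist(variants, cases, params.blacklist_min_support)
    case_info = cases.set_index("case_id")
    enriched_rows = []
    for case_id, tab in variants.groupby("case_id", sort=True):
        info = case_info.loc[case_id]
        passing = [i for i, (_, row) in enumerate(tab.iterrows())
                   if candidate_filter(row, params)[0]]
        tab = tab.iloc[passing]
        tab = germline_exclude(tab, pd.notna(info["normal_sample"]), params.germline_af)
        for _, row in tab.iterrows():
            rec = enriched_call(row, info["purity_primary"], info["purity_recurrence"],
                                blacklist, params)
            if rec is not None:
                enriched_rows.append(rec)
    cols = list(variants.columns) + [
        "no_normal", "adjusted_primary_af", "adjusted_recurrence_af",
        "enrichment_p", "fold_gain", "pop_af_missing", "filter_trace",
    ]
    enriched = pd.DataFrame(enriched_rows, columns=cols)
    enriched = enriched.sort_values(["case_id", "chrom", "pos"]).reset_index(drop=True)
    return enriched, blacklist


def enrichment_vs_dfs(enriched: pd.DataFrame, cases: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of per-case enriched non-silent SNV counts vs DFS."""
    if len(cases) < 3:
        raise ValueError("need at least 3 cases")
    counts = enriched[enriched["effect_class"].isin(NONSILENT)] \
        .groupby("case_id").size()
    counts = counts.reindex(cases["case_id"], fill_value=0)
    return pearson_with_p(counts.values.astype(float), cases["dfs_months"].values)


def oncoprint_matrix(enriched: pd.DataFrame, cases: pd.DataFrame) -> pd.DataFrame:
    """Case x gene mutation-class matrix (missense / nonsense / other / none)."""

    def cls(effect: str) -> str:
        return effect if effect in ("missense", "nonsense") else "other"

    mat = pd.DataFrame("none", index=sorted(enriched["gene"].unique()),
                       columns=list(cases["case_id"]))
    for row in enriched.itertuples():
        mat.loc[row.gene, row.case_id] = cls(row.effect_class)
    return mat


def patient_match_check(table_a: pd.DataFrame, table_b: pd.DataFrame,
                        min_depth: int = 40, min_sites: int = 20,
                        threshold: float = 0.80) -> tuple[float, str]:
    """Genotype-concordance check that two samples come from one patient.

    Each table holds per-site columns ``chrom,pos,ref,alt,depth,af``. AFs at
    shared well-covered sites are discretized into absent/het/hom-like bins
    (< 0.15, 0.15-0.70, > 0.70); the concordance is the fraction of matching
    bins and a matched-pair call requires concordance >= ``threshold``.
    """
    key = ["chrom", "pos", "ref", "alt"]
    merged = table_a.merge(table_b, on=key, suffixes=("_a", "_b"))
    merged = merged[(merged["depth_a"] >= min_depth) & (merged["depth_b"] >= min_depth)]
    if len(merged) < min_sites:
        return float("nan"), "inconclusive"

    def bin_af(af: pd.Series) -> np.ndarray:
        a = af.to_numpy(dtype=float)
        return np.where(a < 0.15, 0, np.where(a <= 0.70, 1, 2))

    conc = float((bin_af(merged["af_a"]) == bin_af(merged["af_b"])).mean())
    return conc, ("matched" if conc >= threshold else "unmatched")
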