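"""RNA-level confirmation of DNA-called variants.

A variant is RNA-supported when the RNA pileup shows at least 2 reads of
the altered allele with an allele frequency of at least 0.05 in the primary
or the recurrence; unexpressed sites (depth 0) are simply unsupported.
DNA/RNA agreement is summarized by the Pearson correlation of paired allele
frequencies over supported variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import pearson_with_p

__all__ = ["rna_support", "support_table", "dna_rna_af_correlation"]

ROLES = ("primary", "recurrence")


def rna_support(rna_alt: dict[str, int], rna_depth: dict[str, int],
                min_alt_reads: int = 2, min_af: float = 0.05) -> dict:
    """Support record for one variant from per-role RNA pileup counts.

    ``supported`` is true when some role has >= ``min_alt_reads`` altered
    reads and AF >= ``min_af`` (boundary inclusive).
    """
    rec: dict = {}
    supported = False
    for role in ROLES:
        d = int(rna_depth.get(role, 0))
        a = int(rna_alt.get(role, 0))
        if a > d:
            raise ValueError(f"rna_alt > rna_depth for role {role!r}")
        af = a / d if d > 0 else 0.0
        rec[f"{role}_rna_depth"] = d
        rec[f"{role}_rna_alt"] = a
        rec[f"{role}_rna_af"] = af
        if a >= min_alt_reads and af >= min_af:
            supported = True
    rec["supported"] = supported
    return rec


def support_table(variants: pd.DataFrame, pileups: pd.DataFrame,
                  min_alt_reads: int = 2, min_af: float = 0.05) -> pd.DataFrame:
    """RNA support for every variant in a cohort table.

    ``pileups`` holds rows (case_id, chrom, pos, ref, alt, role, rna_depth,
    rna_alt); sites absent from the pileup count as depth 0.
    """
    key = ["case_id", "chrom", "pos", "ref", "alt"]
    wide = pileups.pivot_table(index=key, columns="role",
                               values=["rna_depth", "rna_alt"], fill_value=0)
    wide.columns = [f"{role}_{val}" for val, role in wide.columns]
    out = variants[key + [c for c in ("gene", "effect_class") if c in variants]] \
        .merge(wide.reset_index(), on=key, how="left")
    for role in ROLES:
        for val in ("rna_depth", "rna_alt"):
            col = f"{role}_{val}"
            if col not in out:
                out[col] = 0
            out[col] = out[col].fillna(0).astype(int)
        d = out[f"{role}_rna_depth"].to_numpy()
        a = out[f"{role}_rna_alt"].to_numpy()
        out[f"{role}_rna_af"] = np.where(d > 0, a / np.maximum(d, 1), 0.0)
    ok = False
    for role in ROLES:
        ok = ok | ((out[f"{role}_rna_alt"] >= min_alt_reads)
                   & (out[f"{role}_rna_af"] >= min_af))
    out["supported"] = ok
    return out


def dna_rna_af_correlation(support: pd.DataFrame, dna: pd.DataFrame,
                           pool_roles: bool = True):
    """Pearson r between DNA and RNA allele frequencies of supported variants.

    Primary and recurrence observations are pooled by default; with
    ``pool_roles=False`` a per-role result is returned instead.
    """
    key = ["case_id", "chrom", "pos", "ref", "alt"]
    merged = support[support["supported"]].merge(dna[key + ["primary_af", "recurrence_af"]],
                                                 on=key)
    points = []
    for role in ROLES:
        sub = merged[[f"{role}_af", f"{role}_rna_af", f"{role}_rna_depth"]].copy()
        sub = sub[sub[f"{role}_rna_depth"] > 0]
        sub.columns = ["dna_af", "rna_af", "rna_depth"]
        sub["role"] = role
        points.append(sub)
    pts = pd.concat(points, ignore_index=True).dropna(subset=["dna_af", "rna_af"])
    if pool_roles:
        if len(pts) < 3:
            raise ValueError("need at least 3 variants with both AFs")
        return pearson_with_p(pts["dna_af"].values, pts["rna_af"].values)
    out = {}
    for role in ROLES:
        sub = pts[pts["role"] == role]
        if len(sub) < 3:
            raise ValueError("need at least 3 variants with both AFs")
        out[role] = pearson_with_p(sub["dna_af"].values, sub["rna_af"].values)
    return out
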