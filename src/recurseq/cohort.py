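"""Synthetic paired primary/recurrence cohort generator.

Emulates a small clinical cohort of ER-positive breast cancers with a
locoregional recurrence sampled per patient: a targeted RNA panel
(negative-binomial counts with strong patient-level expression profiles),
DNA variant tables for primary/recurrence/optional normal with germline,
shared-lineage somatic, recurrence-enriched, and fixation-artifact variants,
and copy-number segments diluted by tumor purity. Every planted signal is
recorded in a truth bundle so each downstream analysis stage can be scored
for recovery without any external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimConfig",
    "CaseRecord",
    "CohortBundle",
    "make_panel",
    "generate_cohort",
    "write_bundle",
    "read_bundle",
]

# Marker genes given real names so that biologically meaningful stages
# (ESR1-loss selection, focal amplifications, basal program) are addressable.
NAMED_GENES = (
    "ESR1", "ERBB2", "CDK12", "CCND1", "TP53", "PIK3CA", "AKAP9", "KMT2C",
    "ARID1A", "BRD1", "NCOR2", "KLK7", "PROM1", "NDRG1", "FGFR4", "KIT",
    "IGF1R", "BCL2", "TP63", "EPOR", "IDH2", "CEBPA", "RUNX2", "NFKB1",
)

DEFAULT_BASAL_PROGRAM = ("KLK7", "PROM1", "NDRG1", "FGFR4", "TP63", "EPOR", "IDH2", "CEBPA")
DEFAULT_AMPLIFIED = ("ERBB2", "CDK12", "CCND1")

# Disease-free survival (months) and HER2 status patterned on a 12-case
# ER-positive locoregional-recurrence cohort.
DEFAULT_DFS_MONTHS = (86, 61, 76, 69, 19, 37, 25, 26, 3, 10, 5, 59)
DEFAULT_HER2 = ("neg", "pos", "na", "neg", "pos", "pos", "neg", "neg", "neg", "neg", "neg", "pos")

_BASES = np.array(list("ACGT"))


@dataclass
class CaseRecord:
    """One patient: sample identifiers, purities, and clinical covariates."""

    case_id: str
    primary_sample: str
    recurrence_sample: str
    normal_sample: str | None
    purity_primary: float
    purity_recurrence: float
    dfs_months: float
    er_status: str = "pos"
    her2_status: str = "neg"


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    The defaults describe the emulated cohort: 12 patients, a ~1385-gene
    pan-cancer RNA/DNA panel, six patients with a matched normal, five
    ESR1-depleted recurrences with a coordinated basal-program shift, and
    recurrence-enriched somatic variants whose per-case count scales with
    disease-free survival.
    """

    n_cases: int = 12
    n_genes: int = 1385
    panel_gene_names: tuple[str, ...] | None = None
    depth_dna: float = 100.0
    libsize_rna: float = 5e6
    nb_dispersion: float = 0.02
    case_effect_sd: float = 1.0
    n_outlier_genes_per_case: int = 10
    outlier_log2fc_range: tuple[float, float] = (2.0, 4.0)
    frac_esr1_depleted_cases: float = 5.0 / 12.0
    basal_program_genes: tuple[str, ...] = DEFAULT_BASAL_PROGRAM
    basal_log2fc_range: tuple[float, float] = (1.5, 3.0)
    n_enriched_variants_per_case: int = 5
    enriched_dfs_correlated: bool = True
    enriched_af_primary: tuple[float, float] = (0.0, 0.02)
    enriched_af_recurrence: tuple[float, float] = (0.30, 0.60)
    n_shared_somatic_per_case: int = 8
    n_germline_variants: int = 40
    n_artifact_variants: int = 10
    artifact_af_normal: tuple[float, float] = (0.07, 0.12)
    artifact_af_tumor: tuple[float, float] = (0.02, 0.10)
    purity_range: tuple[float, float] = (0.3, 0.9)
    normal_case_indices: tuple[int, ...] = (0, 1, 4, 5, 7, 9)
    amplified_genes: tuple[str, ...] = DEFAULT_AMPLIFIED
    n_discordant_cn_cases: int = 1
    cn_noise_sd: float = 0.05
    rna_depth_per_cpm: float = 3.0
    dfs_months: tuple[float, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        for name in ("frac_esr1_depleted_cases",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "outlier_log2fc_range", "basal_log2fc_range", "enriched_af_primary",
            "enriched_af_recurrence", "artifact_af_normal", "artifact_af_tumor",
            "purity_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered low <= high")
        for name in ("enriched_af_primary", "enriched_af_recurrence",
                     "artifact_af_normal", "artifact_af_tumor", "purity_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        planted = set(self.basal_program_genes) | set(self.amplified_genes) | {"ESR1"}
        if len(planted) + self.n_outlier_genes_per_case > self.n_genes:
            raise ValueError("planted gene lists exceed n_genes")
        n_depl = round(self.frac_esr1_depleted_cases * self.n_cases)
        if self.frac_esr1_depleted_cases > 0 and self.basal_program_genes and n_depl < 1:
            raise ValueError(
                "frac_esr1_depleted_cases * n_cases < 1 while a basal program is requested"
            )
        if self.dfs_months is not None and len(self.dfs_months) != self.n_cases:
            raise ValueError("dfs_months must have one entry per case")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class CohortBundle:
    """Everything a paired-cohort analysis consumes, plus the planted truth."""

    cases: list[CaseRecord]
    counts: pd.DataFrame  # genes x tumor samples, raw integer counts
    variants: pd.DataFrame
    segments: pd.DataFrame
    panel: pd.DataFrame  # gene, chrom, start, end (0-based half-open)
    rna_pileups: pd.DataFrame
    truth: dict[str, pd.DataFrame]
    config: SimConfig

    @property
    def case_table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.cases])


def make_panel(n_genes: int, gene_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Deterministic synthetic gene panel on 10 synthetic chromosomes.

    Genes are uniformly spaced (10 kb genes every 100 kb); marker genes are
    scattered evenly through the panel so they fall on different chromosomes.
    """
    if gene_names is not None:
        if len(gene_names) != n_genes:
            raise ValueError("panel_gene_names length must equal n_genes")
        names = list(gene_names)
    else:
        names = [f"SYN{i:04d}" for i in range(n_genes)]
        stride = max(1, n_genes // len(NAMED_GENES))
        for k, g in enumerate(NAMED_GENES):
            idx = (k * stride) % n_genes
            names[idx] = g
    per_chrom = int(np.ceil(n_genes / 10))
    rows = []
    for i, g in enumerate(names):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * 100_000
        rows.append((g, chrom, start, start + 10_000))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _draw_site(rng: np.random.Generator, panel: pd.DataFrame, used: set,
               genes: pd.DataFrame | None = None) -> tuple:
    """One unique (chrom, pos, ref, alt, gene) site inside a panel gene."""
    pool = panel if genes is None else genes
    while True:
        row = pool.iloc[int(rng.integers(len(pool)))]
        pos = int(rng.integers(row.start + 1, row.end + 1))  # 1-based inclusive
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        key = (row.chrom, pos, ref, alt)
        if key not in used:
            used.add(key)
            return row.chrom, pos, ref, alt, row.gene


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / dispersion, dispersion * mu)
    return rng.poisson(lam)


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Simulate a full paired cohort from one seed, bit-for-bit reproducible."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = make_panel(config.n_genes, config.panel_gene_names)
    genes = panel["gene"].tolist()
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_cases, n_genes = config.n_cases, config.n_genes

    # ---- cases ------------------------------------------------------------
    if config.dfs_months is not None:
        dfs = np.asarray(config.dfs_months, dtype=float)
    elif n_cases == len(DEFAULT_DFS_MONTHS):
        dfs = np.asarray(DEFAULT_DFS_MONTHS, dtype=float)
    else:
        dfs = rng.integers(3, 90, size=n_cases).astype(float)
    normal_idx = {i for i in config.normal_case_indices if i < n_cases}
    cases: list[CaseRecord] = []
    for i in range(n_cases):
        cid = f"LR_{i + 1:02d}"
        her2 = DEFAULT_HER2[i] if n_cases == len(DEFAULT_HER2) else "neg"
        cases.append(
            CaseRecord(
                case_id=cid,
                primary_sample=f"{cid}_P1",
                recurrence_sample=f"{cid}_R1",
                normal_sample=f"{cid}_N1" if i in normal_idx else None,
                purity_primary=float(rng.uniform(*config.purity_range)),
                purity_recurrence=float(rng.uniform(*config.purity_range)),
                dfs_months=float(dfs[i]),
                her2_status=her2,
            )
        )

    # ---- gene baselines (log2 CPM scale) ----------------------------------
    baseline = rng.normal(4.0, 2.0, size=n_genes)
    baseline[gene_idx["ESR1"]] = 9.5  # receptor highly expressed in ER+ disease
    for g in config.amplified_genes:
        baseline[gene_idx[g]] = rng.uniform(6.0, 8.0)
    for g in config.basal_program_genes:
        baseline[gene_idx[g]] = rng.uniform(3.0, 6.0)

    case_offset = rng.normal(0.0, config.case_effect_sd, size=(n_genes, n_cases))
    # expression of focally amplified oncogenes is dosage-driven: damp the
    # patient-level regulatory offset so copy number dominates their variance
    amp_mask = np.isin(genes, config.amplified_genes)
    case_offset[amp_mask, :] *= 0.25

    # ---- copy number truth -------------------------------------------------
    n_depleted = round(config.frac_esr1_depleted_cases * n_cases)
    depleted_ids = sorted(
        rng.choice([c.case_id for c in cases], size=n_depleted, replace=False).tolist()
    ) if n_depleted else []
    discordant_ids = sorted(
        rng.choice([c.case_id for c in cases], size=min(config.n_discordant_cn_cases, n_cases),
                   replace=False).tolist()
    ) if config.n_discordant_cn_cases else []

    def draw_cn_profile() -> np.ndarray:
        cn = np.full(n_genes, 2.0)
        for chrom, idx in panel.groupby("chrom", sort=False).indices.items():
            idx = np.sort(idx)
            n_seg = int(rng.integers(2, 5))
            cuts = np.sort(rng.choice(np.arange(1, len(idx)), size=n_seg - 1, replace=False)) \
                if len(idx) > n_seg else np.array([], dtype=int)
            for block in np.split(idx, cuts):
                if rng.random() < 0.55:
                    val = 2.0
                else:
                    val = float(rng.choice([1.0, 1.5, 3.0, 4.0], p=[0.3, 0.2, 0.3, 0.2]))
                cn[block] = val
        return cn

    cn_true: dict[str, np.ndarray] = {}
    for c in cases:
        prof_p = draw_cn_profile()
        prof_r = draw_cn_profile() if c.case_id in discordant_ids else prof_p.copy()
        for prof in (prof_p, prof_r):
            for g in config.amplified_genes:
                # focal amplification in a subset of samples, diploid otherwise
                prof[gene_idx[g]] = float(rng.uniform(4.0, 8.0)) if rng.random() < 0.4 else 2.0
        cn_true[c.primary_sample] = prof_p
        cn_true[c.recurrence_sample] = prof_r

    # ---- planted expression shifts (recurrence only) -----------------------
    shift = {}  # sample -> per-gene log2 shift
    reserved = set(config.basal_program_genes) | set(config.amplified_genes) | {"ESR1"}
    eligible = [g for g in genes if g not in reserved and baseline[gene_idx[g]] >= 3.0]
    outlier_truth = []
    lo, hi = config.outlier_log2fc_range
    for c in cases:
        s = np.zeros(n_genes)
        if config.n_outlier_genes_per_case:
            chosen = rng.choice(eligible, size=config.n_outlier_genes_per_case, replace=False)
            for g in chosen:
                mag = float(rng.uniform(lo, hi))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                s[gene_idx[g]] = sign * mag
                outlier_truth.append(
                    {"case_id": c.case_id, "gene": g,
                     "direction": "gain" if sign > 0 else "loss",
                     "log2fc_planted": sign * mag}
                )
        if c.case_id in depleted_ids:
            s[gene_idx["ESR1"]] = -hi  # receptor loss at the top of the planted range
            for g in config.basal_program_genes:
                s[gene_idx[g]] = float(rng.uniform(*config.basal_log2fc_range))
        shift[c.recurrence_sample] = s
        shift[c.primary_sample] = np.zeros(n_genes)

    # ---- counts -------------------------------------------------------------
    sample_ids = []
    mu_cols = []
    libsizes = rng.uniform(0.7, 1.3, size=2 * n_cases) * config.libsize_rna
    for j, c in enumerate(cases):
        for k, s in enumerate((c.primary_sample, c.recurrence_sample)):
            m = baseline + case_offset[:, j] + shift[s] \
                + np.log2(np.maximum(cn_true[s], 0.25) / 2.0) * amp_mask
            p = 2.0 ** m
            mu_cols.append(libsizes[2 * j + k] * p / p.sum())
            sample_ids.append(s)
    mu = np.column_stack(mu_cols)
    counts = pd.DataFrame(
        _nb_counts(rng, mu, config.nb_dispersion), index=genes, columns=sample_ids
    )

    # ---- variants -----------------------------------------------------------
    used_sites: set = set()
    records: list[dict] = []
    effect_somatic = np.array(["missense", "nonsense", "splice", "frameshift"])
    effect_any = np.array(["silent", "missense", "nonsense", "splice", "other_nonsilent"])

    def depth_alt(p_true: float) -> tuple[int, int, float]:
        d = max(int(rng.poisson(config.depth_dna)), 1)
        a = int(rng.binomial(d, min(max(p_true, 0.0), 1.0)))
        return d, a, a / d

    def add_record(c: CaseRecord, site: tuple, effect: str, pop_af: float,
                   p_primary: float, p_recurrence: float, p_normal: float | None,
                   origin: str) -> None:
        chrom, pos, ref, alt, gene = site
        rec = {
            "case_id": c.case_id, "chrom": chrom, "pos": pos, "ref": ref,
            "alt": alt, "gene": gene, "effect_class": effect, "pop_af": pop_af,
            "origin": origin,
        }
        for role, p in (("primary", p_primary), ("recurrence", p_recurrence)):
            d, a, af = depth_alt(p)
            rec[f"{role}_depth"], rec[f"{role}_alt"], rec[f"{role}_af"] = d, a, af
        if c.normal_sample is not None:
            d, a, af = depth_alt(p_normal if p_normal is not None else 0.001)
            rec["normal_depth"], rec["normal_alt"], rec["normal_af"] = d, a, af
        else:
            rec["normal_depth"] = rec["normal_alt"] = rec["normal_af"] = np.nan
        records.append(rec)

    # population SNP pool shared across individuals (patient-match signal)
    pool_size = 2 * config.n_germline_variants
    snp_pool = [_draw_site(rng, panel, used_sites) for _ in range(pool_size)]
    snp_maf = rng.uniform(0.10, 0.40, size=pool_size)
    for c in cases:
        genotypes = rng.binomial(2, snp_maf)
        for site, maf, gt in zip(snp_pool, snp_maf, genotypes):
            if gt == 0:
                continue
            af = 0.5 if gt == 1 else 1.0  # germline: undiluted by tumor purity
            eff = str(rng.choice(effect_any))
            add_record(c, site, eff, float(maf), af, af, af, "germline")

    # fixation artifacts: present in every normal, recur across the cohort
    artifact_sites = [_draw_site(rng, panel, used_sites)
                      for _ in range(config.n_artifact_variants)]
    for c in cases:
        for site in artifact_sites:
            p_n = float(rng.uniform(*config.artifact_af_normal))
            p_t1 = float(rng.uniform(*config.artifact_af_tumor))
            p_t2 = float(rng.uniform(*config.artifact_af_tumor))
            eff = str(rng.choice(effect_somatic))
            add_record(c, site, eff, 0.0, p_t1, p_t2, p_n, "artifact")

    # shared-lineage somatic variants (same clonal AF in both tumors)
    for c in cases:
        for _ in range(config.n_shared_somatic_per_case):
            site = _draw_site(rng, panel, used_sites)
            af = float(rng.uniform(0.10, 0.40))
            eff = str(rng.choice(effect_any))
            add_record(c, site, eff, 0.0,
                       af * c.purity_primary, af * c.purity_recurrence, None, "shared_somatic")

    # recurrence-enriched variants
    enriched_truth = []
    mean_dfs = dfs.mean()
    for i, c in enumerate(cases):
        if config.enriched_dfs_correlated and mean_dfs > 0:
            n_e = int(round(config.n_enriched_variants_per_case * dfs[i] / mean_dfs))
        else:
            n_e = config.n_enriched_variants_per_case
        for _ in range(n_e):
            site = _draw_site(rng, panel, used_sites)
            af_p = float(rng.uniform(*config.enriched_af_primary))
            af_r = float(rng.uniform(*config.enriched_af_recurrence))
            eff = str(rng.choice(effect_somatic))
            add_record(c, site, eff, 0.0,
                       af_p * c.purity_primary, af_r * c.purity_recurrence, None, "enriched")
            enriched_truth.append(
                {"case_id": c.case_id, "chrom": site[0], "pos": site[1],
                 "ref": site[2], "alt": site[3], "gene": site[4],
                 "af_primary_true": af_p, "af_recurrence_true": af_r}
            )

    variants = pd.DataFrame(records)

    # ---- segments ------------------------------------------------------------
    seg_rows = []
    for c in cases:
        for s, purity in ((c.primary_sample, c.purity_primary),
                          (c.recurrence_sample, c.purity_recurrence)):
            prof = cn_true[s]
            for chrom, idx in panel.groupby("chrom", sort=False).indices.items():
                idx = np.sort(idx)
                run_start = 0
                vals = prof[idx]
                for k in range(1, len(idx) + 1):
                    if k == len(idx) or vals[k] != vals[run_start]:
                        block = idx[run_start:k]
                        obs = 2.0 * (1.0 - purity) + purity * vals[run_start] \
                            + float(rng.normal(0.0, config.cn_noise_sd))
                        seg_rows.append({
                            "sample_id": s, "chrom": chrom,
                            "start": int(panel.iloc[block[0]].start),
                            "end": int(panel.iloc[block[-1]].end),
                            "cn_obs": max(obs, 0.0), "n_probes": len(block),
                        })
                        run_start = k
    segments = pd.DataFrame(seg_rows)

    # ---- RNA pileups over the variant sites -----------------------------------
    cpm = counts / counts.sum(axis=0) * 1e6
    pile_rows = []
    sample_of = {(c.case_id, "primary"): c.primary_sample for c in cases}
    sample_of.update({(c.case_id, "recurrence"): c.recurrence_sample for c in cases})
    for rec in records:
        for role in ("primary", "recurrence"):
            samp = sample_of[(rec["case_id"], role)]
            g_cpm = float(cpm.loc[rec["gene"], samp])
            d = int(rng.poisson(g_cpm * config.rna_depth_per_cpm))
            p = rec[f"{role}_af"]  # RNA allele balance mirrors the DNA AF
            a = int(rng.binomial(d, min(max(p, 0.0), 1.0))) if d > 0 else 0
            pile_rows.append({
                "case_id": rec["case_id"], "chrom": rec["chrom"], "pos": rec["pos"],
                "ref": rec["ref"], "alt": rec["alt"], "role": role,
                "rna_depth": d, "rna_alt": a, "rna_af": a / d if d else 0.0,
            })
    rna_pileups = pd.DataFrame(pile_rows)

    truth = {
        "enriched": pd.DataFrame(
            enriched_truth,
            columns=["case_id", "chrom", "pos", "ref", "alt", "gene",
                     "af_primary_true", "af_recurrence_true"],
        ),
        "outliers": pd.DataFrame(
            outlier_truth, columns=["case_id", "gene", "direction", "log2fc_planted"]
        ),
        "depleted_cases": pd.DataFrame({"case_id": depleted_ids}),
        "discordant_cn_cases": pd.DataFrame({"case_id": discordant_ids}),
        "gene_cn": pd.DataFrame(
            [{"sample_id": s, "gene": g, "cn_true": cn_true[s][gene_idx[g]]}
             for s in cn_true for g in genes]
        ),
        "artifact_sites": pd.DataFrame(
            [{"chrom": s[0], "pos": s[1], "ref": s[2], "alt": s[3], "gene": s[4]}
             for s in artifact_sites],
            columns=["chrom", "pos", "ref", "alt", "gene"],
        ),
    }
    return CohortBundle(
        cases=cases, counts=counts, variants=variants, segments=segments,
        panel=panel, rna_pileups=rna_pileups, truth=truth, config=config,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=recurseq-simulated
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Functional class">
##INFO=<ID=POP_AF,Number=1,Type=Float,Description="Population allele frequency">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Ref,alt read counts">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">
"""


def _chrom_order(chrom: str) -> tuple:
    return (len(chrom), chrom)


def _write_case_vcf(path: Path, case: CaseRecord, variants: pd.DataFrame,
                    contigs: list[str]) -> None:
    roles = [("primary", case.primary_sample), ("recurrence", case.recurrence_sample)]
    if case.normal_sample is not None:
        roles.append(("normal", case.normal_sample))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(s for _, s in roles) + "\n")
        v = variants.sort_values(["chrom", "pos"], key=lambda s: s.map(_chrom_order)
                                 if s.name == "chrom" else s)
        for row in v.itertuples():
            info = f"GENE={row.gene};EFFECT={row.effect_class};POP_AF={row.pop_af:.6g}"
            cells = []
            for role, _ in roles:
                d = int(getattr(row, f"{role}_depth"))
                a = int(getattr(row, f"{role}_alt"))
                af = getattr(row, f"{role}_af")
                cells.append(f"{d}:{d - a},{a}:{af:.6g}")
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}"
                     f"\tDP:AD:AF\t" + "\t".join(cells) + "\n")


def write_bundle(bundle: CohortBundle, directory: str | Path) -> pd.DataFrame:
    """Write the full bundle to TSV/VCF/SEG/YAML files; returns the manifest.

    The manifest lists every emitted file with its sha256 checksum and is
    also written as ``manifest.json``.
    """
    out = Path(directory)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "vcf").mkdir(exist_ok=True)
        (out / "segments").mkdir(exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)

        files: list[Path] = []

        def emit(df: pd.DataFrame, rel: str, index: bool = False) -> None:
            p = out / rel
            df.to_csv(p, sep="\t", index=index)
            files.append(p)

        emit(bundle.counts, "counts.tsv", index=True)
        emit(bundle.case_table, "metadata.tsv")
        emit(bundle.variants, "variants.tsv")
        emit(bundle.panel, "panel.tsv")
        emit(bundle.rna_pileups, "rna_pileups.tsv")
        for name, df in bundle.truth.items():
            emit(df, f"truth/{name}.tsv")
        contigs = sorted(bundle.panel["chrom"].unique(), key=_chrom_order)
        for case in bundle.cases:
            p = out / "vcf" / f"{case.case_id}.vcf"
            _write_case_vcf(p, case,
                            bundle.variants[bundle.variants["case_id"] == case.case_id],
                            contigs)
            files.append(p)
        for sample_id, seg in bundle.segments.groupby("sample_id"):
            emit(seg, f"segments/{sample_id}.seg")
        bundle.config.to_yaml(out / "config.yaml")
        files.append(out / "config.yaml")
    except OSError as exc:
        raise OSError(f"bundle write failed at {exc.filename!r} (stage: file output)") from exc

    manifest = pd.DataFrame(
        {
            "file": [str(p.relative_to(out)) for p in files],
            "sha256": [hashlib.sha256(p.read_bytes()).hexdigest() for p in files],
        }
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.set_index("file")["sha256"].to_dict(), indent=1)
    )
    return manifest


def read_bundle(directory: str | Path) -> CohortBundle:
    """Reconstruct a bundle from :func:`write_bundle` output (TSV route)."""
    out = Path(directory)
    config = SimConfig.from_yaml(out / "config.yaml")
    meta = pd.read_csv(out / "metadata.tsv", sep="\t", float_precision="round_trip")
    cases = []
    for row in meta.itertuples(index=False):
        d = row._asdict()
        if pd.isna(d["normal_sample"]):
            d["normal_sample"] = None
        cases.append(CaseRecord(**d))
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col=0)
    variants = pd.read_csv(out / "variants.tsv", sep="\t", float_precision="round_trip")
    panel = pd.read_csv(out / "panel.tsv", sep="\t")
    rna = pd.read_csv(out / "rna_pileups.tsv", sep="\t", float_precision="round_trip")
    segs = []
    for p in sorted((out / "segments").glob("*.seg")):
        segs.append(pd.read_csv(p, sep="\t", float_precision="round_trip"))
    segments = pd.concat(segs, ignore_index=True) if segs else pd.DataFrame()
    truth = {}
    for p in sorted((out / "truth").glob("*.tsv")):
        truth[p.stem] = pd.read_csv(p, sep="\t", float_precision="round_trip")
    return CohortBundle(cases=cases, counts=counts, variants=variants,
                        segments=segments, panel=panel, rna_pileups=rna,
                        truth=truth, config=config)


def read_case_vcf(path: str | Path) -> pd.DataFrame:
    """Read one simulated case VCF back into flat per-role rows via pysam."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows = []
    for rec in vf:
        row = {
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0],
            "gene": rec.info["GENE"], "effect_class": rec.info["EFFECT"],
            "pop_af": float(rec.info["POP_AF"]),
        }
        for s in samples:
            call = rec.samples[s]
            row[f"{s}_depth"] = call["DP"]
            row[f"{s}_alt"] = call["AD"][1]
            row[f"{s}_af"] = float(call["AF"])
        rows.append(row)
    return pd.DataFrame(rows)
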