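# Methods

This document records the statistical model behind each pipeline stage, the
assumptions and defaults of the synthetic-cohort generator, and the numerical
choices made in the implementation. It makes no empirical claims beyond what
the code computes on simulated data.

## Expression preparation

**TMM normalization** (`tmm_factors`). Normalization factors follow the
trimmed mean of M-values method. Genes with zero counts in every sample are
dropped first; the reference sample is the one whose 75th-percentile count
fraction is closest to the mean of those fractions. For each sample, per-gene
log-ratios M and average log-abundances A against the reference are doubly
trimmed (30% of M-ranks and 5% of A-ranks on each side, the conventional
defaults), and the factor is 2 to the precision-weighted mean of the
surviving M values, where weights are inverse approximate binomial variances
(1/count − 1/library per sample, summed). Factors are rescaled so their
geometric mean is 1. When fewer than 10 genes survive filtering, the trim is
skipped with a `RuntimeWarning` and an unweighted mean is used; if the
maximum |M| is below 1e-6 the factor is exactly 1. The implementation is
validated against `edgeR::calcNormFactors` (4.0.16) on 20 frozen
negative-binomial count tables; the worst relative deviation observed is
about 3e-4, far inside the 2% acceptance tolerance.

**log2 normalized CPM** (`lognorm_cpm`). log2((count + prior) /
(libsize × factor + 2 × prior) × 1e6), with prior count 0.5. The prior keeps
zeros finite; values below ~0 simply indicate expression under 1 CPM.

**Variable genes and clustering.** The most variable genes are the top 10%
by interquartile range of log2 CPM (type-7 quantiles; ties broken
lexicographically by gene ID for determinism). Samples are clustered with
average linkage on 1 − Pearson correlation distance (`scipy`); a gene with
zero variance contributes distance 1 with a warning. `cluster_pairs` also
reports, per case, the primary–recurrence Pearson r and whether the matched
primary is the recurrence's nearest neighbor.

## Variant enrichment cascade

Applied per case, in order:

1. **Candidacy**: depth ≥ 40 in both tumors, allele frequency ≥ 0.05 in at
   least one tumor, and ≥ 5 alternate reads in whichever sample satisfies
   the AF criterion.
2. **Germline exclusion**: when a matched normal exists, variants with
   normal AF > 0.30 are removed (strict inequality). Cases without a normal
   are flagged `no_normal` rather than silently passed.
3. **Blacklist**: sites called (≥ 2 alt reads and AF ≥ 0.05) in ≥ 3 distinct
   normals across the cohort are treated as recurrent artifacts and removed.
   If the cohort has fewer normals than the support threshold, an empty
   blacklist is returned with a warning.
4. **Purity adjustment**: observed AF is divided by tumor purity and capped
   at 1 (`min(1, af / purity)`), the linear dilution model with a diploid
   normal background.
5. **Enrichment test**: one-sided Fisher exact p for the alternate/total
   read 2×2 table, computed as the hypergeometric survival function
   (`scipy.stats.hypergeom.sf`), validated exhaustively against a gammaln
   tail summation for all tables with depths ≤ 60.
6. **Call criteria**: enriched iff p < 0.05, adjusted fold gain > 2
   (infinite when the primary AF is 0), adjusted recurrence AF ≥ 0.10,
   non-silent effect class, and population AF < 0.01. A missing population
   AF is treated as 0 and flagged `pop_af_missing`. Every decision is
   recorded in a per-variant `filter_trace`.

`patient_match_check` bins shared-site AFs into absent (< 0.15),
heterozygous-like (≤ 0.70), and homozygous-like (> 0.70) states and reports
the fraction of concordant states between two samples, calling "matched" at
≥ 0.80 concordance over ≥ 20 sites of depth ≥ 40.

## RNA concordance

A DNA variant is RNA-supported when either tumor's RNA pileup shows ≥ 2
alternate reads **and** AF ≥ 0.05 (inclusive boundary). Sites with zero RNA
depth are unsupported, not errors — unexpressed genes cannot confirm a
variant. `dna_rna_af_correlation` pools primary and recurrence observations
and reports the Pearson correlation between DNA and RNA allele frequencies.

## Outlier classifier

Per case, gene-level deltas (recurrence − primary log2 CPM) form the
reference distribution. Tukey fences use type-7 quartiles: inner fences at
Q1 − 1.5·IQR / Q3 + 1.5·IQR, outer fences at 3·IQR. Categories: beyond an
outer fence → ExtremeLoss/ExtremeGain; beyond an inner fence →
OutlierLoss/OutlierGain; otherwise Stable. Inequalities are strict, so a
delta exactly on a fence is Stable. Genes with zero raw counts in both
samples of a pair are forced Stable — the delta there reflects only the
prior count. `select_depleted_cases` returns the cases whose ESR1 delta is
classified as a loss. Classification is validated against a from-scratch
sorted-quartile oracle on random vectors, and the null non-Stable rate on
N(0,1) deltas (~0.7%) is checked against its asymptotic expectation.

## Paired differential expression

For each gene, per-case deltas d give t = mean(d) / sqrt(s²_mod / n) with a
moderated variance s²_mod = (d₀·mean(s²) + (n−1)·s²) / (d₀ + n−1), where
mean(s²) pools variances across genes and d₀ (default 4) is the prior
degrees of freedom; p-values use df = n − 1 + d₀. With d₀ = 0 this is
exactly the textbook paired t-test, verified against
`scipy.stats.ttest_rel` at 1e-10 relative tolerance. Genes with degenerate
(zero) delta variance are flagged and given NaN p-values. FDR adjustment is
Benjamini–Hochberg via `statsmodels`, with NaNs excluded from the effective
test count and propagated. The reporting filter keeps genes with average
expression ≥ 2 log2 CPM, nominal p < 0.05, and |log2FC| > 0.5 (all
boundaries exclusive), sorted by p-value.

## Copy number

Gene-level CN is the probe-count-weighted mean of `cn_obs` over all segments
intersecting the gene interval (0-based half-open arithmetic), then purity
adjusted: cn = max(0, (cn_mean − 2·(1 − purity)) / purity). This exactly
inverts a linear mixture of tumor at purity p with diploid normal, verified
to 1e-9 noise-free. Genes with no overlapping segment are flagged missing
rather than imputed. Pair concordance is the Pearson r of gene CN between
primary and recurrence over ≥ 20 shared genes, with a discordance flag at
r < 0.5 (configurable). No integer rounding is applied by default because
the downstream use is correlation; a rounding mode exists for call-style
output.

## Synthetic cohort generator

### What it emulates

A 12-patient paired cohort on a ~1385-gene pan-cancer RNA/DNA panel laid out
on 10 synthetic chromosomes (10 kb genes every 100 kb). Six patients carry a
matched normal. Recurrences carry planted signal: per-case expression
outliers, five ESR1-depleted cases with a coordinated basal-like program
(KLK7, PROM1, NDRG1, FGFR4, TP63, EPOR, IDH2, CEBPA), recurrence-enriched
somatic variants whose per-case count scales with disease-free survival,
shared-lineage clonal variants, germline SNPs drawn from a population pool
(creating realistic patient-match signal), fixation artifacts present in
every normal, per-chromosome copy-number segments with one discordant case,
and focally amplified oncogenes (ERBB2, CDK12, CCND1) whose expression is
dosage-driven. RNA pileups at every variant site mirror the DNA allele
frequency at expression-dependent depth.

### Model and defaults

| Parameter | Default | Rationale |
|---|---|---|
| `n_cases` / `n_genes` | 12 / 1385 | emulated cohort and panel size |
| `nb_dispersion` | 0.02 | residual within-pair dispersion (BCV ≈ 0.14); patient-level biology is carried by per-case offsets, not this term |
| `case_effect_sd` | 1.0 | log2-scale patient effect; makes pairs cluster together |
| `libsize_rna` | 5e6 × U(0.7, 1.3) | targeted-panel depth with realistic spread |
| `depth_dna` | 100 | Poisson mean sequencing depth at variant sites |
| `purity_range` | (0.3, 0.9) | typical clinical tumor-purity spread |
| `n_outlier_genes_per_case` | 10 | planted outliers, log2 shift U(2, 4), random sign, on genes with baseline ≥ 3 log2 CPM |
| `frac_esr1_depleted_cases` | 5/12 | ESR1 shift −4 log2; basal program +U(1.5, 3) |
| `enriched_af_primary` / `..._recurrence` | U(0, 0.02) / U(0.30, 0.60) | pre-purity allele fractions of planted enriched variants |
| `n_enriched_variants_per_case` | 5 (mean) | scaled by each case's DFS when `enriched_dfs_correlated` |
| `n_germline_variants` | 40 | drawn from a shared pool of 80 population SNPs, MAF U(0.10, 0.40); AF 0.5/1.0, undiluted by purity |
| `n_artifact_variants` | 10 | AF U(0.07, 0.12) in normals, U(0.02, 0.10) in tumors |
| `cn_noise_sd` | 0.05 | Gaussian noise on observed segment CN |
| `rna_depth_per_cpm` | 3.0 | RNA pileup depth ~ Poisson(cpm × 3) |

Counts are gamma-Poisson (negative binomial with variance μ + φμ²). Observed
segment CN is 2(1 − purity) + purity·cn + noise, the same mixture the
pipeline inverts. DNA read counts are binomial at Poisson depth with
purity-diluted allele fractions for somatic variants.

### What it does not emulate

- No subclonal structure, phasing, or multi-allelic sites; one alternate
  allele per site.
- No GC/length biases, batch effects, mappability, or positional coverage
  structure; depth is exchangeable across sites.
- Gene coordinates, chromosome layout, and the gene universe are synthetic;
  only a small set of marker genes carry meaningful names.
- Copy number is segment-level truth with Gaussian observation noise — no
  probe-level modeling or segmentation errors.
- RNA allele fractions equal DNA allele fractions (no allele-specific
  expression or RNA editing).

## Numerical choices

- Type-7 (linear-interpolation) quantiles everywhere a quartile is needed,
  matching `numpy` defaults; the classifier accepts type 6 for comparison.
- Fisher p-values are computed in the log domain via the hypergeometric
  survival function and clipped to (0, 1].
- Pearson correlations use a shared helper that returns (NaN, NaN) with a
  `RuntimeWarning` on constant input instead of raising.
- All simulation randomness flows through a single `numpy.random.Generator`
  seeded from `SimConfig.seed`; output is bit-for-bit reproducible and
  column/row orders are sorted wherever iteration order is not already
  deterministic.
- Bundle TSVs are read back with `float_precision="round_trip"` so
  write/read round-trips are exact.

## Limitations

- The moderated t-test is a fixed-prior approximation (d₀ chosen, not
  estimated from the data as an empirical-Bayes fit would do).
- The enrichment Fisher test treats reads as independent draws; duplicate
  reads or strand artifacts are not modeled, and the test is conservative
  at low depth.
- The blacklist requires ≥ 3 normals to be meaningful; smaller cohorts get
  no artifact protection (a warning is emitted). Common germline SNPs shared
  by ≥ 3 sequenced normals can also enter the blacklist; for tumor-only
  cases this removes real germline variants (harmless here) but it is a
  behavior to keep in mind when re-using the blacklist across cohorts.
- Exact recovery of the planted ESR1-depleted case set holds in ≥ 95% of
  seeds, not all: occasionally a borderline ESR1 delta in a non-depleted
  case lands just outside a fence (a genuine tail event of the null
  distribution, not a pipeline error).
- Purity adjustment assumes a diploid contaminating population and known
  purity; errors in the purity estimate propagate linearly into adjusted AF
  and CN.
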