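# recurseq

Paired-tumor genomics of locoregional breast-cancer recurrence, at desk scale.

`recurseq` implements the full analysis pipeline used to compare primary
ER-positive breast tumors with their matched locoregional recurrences on a
targeted RNA/DNA panel, together with a calibrated synthetic-cohort generator
so every stage can be exercised and validated without patient data:

- **Synthetic cohort generator** — 12 virtual patients with paired
  primary/recurrence tumors (6 with a matched normal), negative-binomial
  panel RNA counts, DNA variant read counts, copy-number segments, and RNA
  pileups, with all planted signal recorded as ground truth.
- **Expression preparation** — TMM normalization (matching
  `edgeR::calcNormFactors` to within rounding), log2 CPM, most-variable-gene
  selection by IQR, 1−Pearson average-linkage clustering, pair-similarity
  statistics.
- **Variant enrichment** — the recurrence-enriched variant cascade: coverage
  and allele-frequency candidacy, germline exclusion, a cohort blacklist
  built from normals, tumor-purity AF adjustment, a one-sided Fisher
  enrichment test, and five pathogenic-candidate criteria.
- **RNA concordance** — RNA-level support of DNA variant calls and DNA–RNA
  allele-frequency correlation.
- **Outlier classifier** — five-category Tukey-fence classification of
  per-case expression log-fold-changes (Stable / OutlierGain / OutlierLoss /
  ExtremeGain / ExtremeLoss) and detection of receptor-depleted cases.
- **Subtype differential expression** — paired moderated t-test,
  Benjamini–Hochberg FDR, and a reporting filter.
- **Copy number** — probe-weighted gene-level CN from segments, purity
  adjustment, pair concordance with a discordance flag, and CN–expression
  correlation.

## Worked example

```python
import recurseq as rq

# 1. Simulate a paired primary/recurrence cohort (12 cases, 1385-gene panel)
bundle = rq.generate_cohort(rq.SimConfig(seed=0))
cases = bundle.case_table

# 2. TMM-normalize counts and cluster samples on the most variable genes
mat = rq.ExpressionMatrix(bundle.counts).normalize()
genes = rq.variable_genes(mat.lognorm)          # top 10% by IQR
_, newick, pairs = rq.cluster_pairs(mat.lognorm, genes, cases)
print("pairs whose nearest neighbor is the matched primary:",
      int(pairs.nearest_neighbor_is_partner.sum()), "/", len(pairs))

# 3. Call recurrence-enriched variants through the full cascade
enriched, blacklist = rq.enrich_variants(bundle.variants, cases)
print("enriched variants called:", len(enriched),
      "| blacklisted sites:", len(blacklist.to_frame()))

# 4. Check RNA support of the enriched calls
support = rq.support_table(enriched, bundle.rna_pileups)
print("RNA-supported fraction: %.2f" % support.supported.mean())

# 5. Classify per-case expression outliers and find receptor-depleted cases
deltas, zero_mask = rq.pair_deltas(mat.lognorm, cases, bundle.counts)
calls, fences = rq.classify_cohort(deltas, zero_mask)
depleted = rq.select_depleted_cases(calls)
print("ESR1-depleted recurrences:", depleted)

# 6. Paired differential expression within the depleted subset
sub = cases[cases.case_id.isin(depleted)]
de = rq.report_filter(rq.paired_de(mat.lognorm, sub))
print("reportable DE genes:", len(de))
print(de.head(6)[["gene", "log2fc", "p_nominal", "p_fdr"]].to_string(index=False))
```

Output (exactly reproducible — all randomness flows from `seed=0`):

```text
pairs whose nearest neighbor is the matched primary: 12 / 12
enriched variants called: 61 | blacklisted sites: 45
RNA-supported fraction: 0.97
ESR1-depleted recurrences: ['LR_04', 'LR_06', 'LR_07', 'LR_09', 'LR_10']
reportable DE genes: 9
 gene    log2fc    p_nominal    p_fdr
 ESR1 -4.177928 2.479839e-09 0.000003
 IDH2  2.376810 5.232016e-07 0.000362
FGFR4  2.529738 8.571730e-07 0.000396
NDRG1  2.606150 2.601836e-06 0.000901
 TP63  2.323098 3.280916e-06 0.000909
 EPOR  2.623098 7.120627e-06 0.001644
```

The generator planted five ESR1-depleted recurrences with a coordinated
basal-like program; the pipeline recovers exactly those five cases, the
receptor loss (ESR1 log2FC ≈ −4.2), and the planted program genes.

A `recurseq` command-line interface wraps the main stages
(`recurseq simulate`, `recurseq normalize`, `recurseq enrich-variants`,
`recurseq outliers`, `recurseq subtype-de`); run `recurseq --help`.

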