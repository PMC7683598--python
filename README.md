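# coregscan

Family-wide alteration testing of transcription factors (TF) and
transcriptional coregulators — coactivators (COA), corepressors (COR) and
mixed-function coregulators (MIXED) — in tumor cohorts, together with a
fully synthetic, truth-tracked cohort generator so that every stage of the
pipeline can be exercised and validated without access to patient data.

The package is aimed at computational cancer biologists who want to ask:
*is a whole class of regulators altered in tumors more than chance would
allow, and do the most altered members matter clinically?*

## What it computes

**Alteration scores.** Expression is standardized per gene either against
matched adjacent-normal samples, Z = (x_tumor − mean_normal)/SD_normal
(genes detectable in ≥ 80% of samples), or against the per-gene median for
cohorts without normals. Copy number uses GISTIC codes {−2…+2} (deep
events ±2). Mutation burden per gene is sqrt(m_g / L_g), the square root
of the count of mutations normalized by the genomic union of the gene's
exon lengths, damping the growth of summed counts with cohort size.

**Family test.** For a gene class C of size k in a detected-gene universe
of size n with per-gene score vector s, a class statistic T(C) — the
proportion of class genes altered beyond a Z threshold in a given
direction, the class mean, or the class mean rank — is compared with the
same statistic on B random k-subsets of the universe (B = 100,000 by
convention). The empirical p-value is

    p = (1 + #{draws at least as extreme as T(C)}) / (B + 1),

one-sided in the stated direction, with floor 1/(B+1) (≈ 1e-05 at
B = 100,000). Benjamini–Hochberg FDR is applied across the whole panel of
class × cohort × data-type × direction tests. Class over-representation in
reference gene sets uses the one-sided hypergeometric test.

**Clinical follow-through.** Genes altered by > t Z-scores in ≥ f of
tumors (presets t = 2 or 2.5, f = 0.35) are kept; tumors are clustered on
them (complete linkage, Euclidean) and cluster membership is tested
against clinical categories with an uncorrected chi-squared. Per-gene
survival screening compares lower- vs upper-quartile expression groups by
Kaplan–Meier/log-rank with BH FDR across the screened genes.

**Cis-regulation cascade.** Binding peaks overlapping a chromatin-state
segment by ≥ 1 bp are annotated to every gene whose TSS lies within
100 kb; linked genes significant in both a knockdown contrast and a
cohort upper-vs-lower-quartile contrast (default FDR < 0.05,
|logFC| > 1.5) form the bound-and-regulated network. Correlation profiles
compare a gene set's Spearman correlations with an index gene against a
background set via a two-sample KS test.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (6,000 genes, 200 tumors, 40 normals, corepressor down-shifts and
one expression-linked hazard gene planted; see `docs/methods.md`).
Running `python analysis/02_family_alteration_tests.py` prints:

```
2/24 class tests significant at q < 0.1:
class             data_type direction  observed  empirical_p      q
  COR            expression      down -0.334836      0.00005 0.0006
  COR cna_deletion_fraction        up  0.035922      0.00005 0.0006
```

Both planted signals — the corepressor expression down-shift and the
corepressor deep-deletion excess — reach the empirical-p floor of the
B = 20,000 resampling null (p = 1/(B+1) ≈ 5e-05) and survive FDR, while
the other 22 class tests stay null. `analysis/03_filter_cluster_outcome.py`
then reports 16 frequently altered genes whose clustering separates
higher-grade tumors (`X-squared = 10.7644, p-value = 0.00103`), with 14 of
the filtered genes shared between the two cohorts;
`analysis/04_survival_screen.py` ranks the planted hazard gene first
(q = 4.2e-06 among 100 screened genes); and
`analysis/05_cis_regulation_cascade.py` reduces 60 peaks to 50 in
chromatin states to 184 peak:gene links to exactly the 20 planted
bound-and-regulated genes.

The same steps are available as a CLI (`coregscan catalog | simulate |
score | family-test | filter | intersect | survival | cis | pipeline`).

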