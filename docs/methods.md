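# Methods

## The model in brief

The package treats a tumor cohort as a matrix of per-gene alteration
scores and asks two families of questions: (1) is a predefined gene class
shifted as a group relative to equal-size random gene sets drawn from the
same detected-gene universe (a competitive resampling test), and (2) do
the most altered individual genes associate with clinical structure
(clusters, grade, time to biochemical progression)? A separate cascade
links binding peaks to genes and intersects them with two differential-
expression contrasts to define a bound-and-regulated network for an index
coactivator.

## Gene-class catalog

Classes are built from two evidence sources: canonical TF lists, and term
annotations whose labels match configurable phrase lists for positive /
negative control of transcription and co-activator / co-repressor
function (case-insensitive substring match). Precedence is TF first: a
gene on any canonical TF list is TF even if it also carries coregulator
terms (the override is recorded in its provenance as
`coregulator_evidence_superseded`). Among the rest, genes with only
positive evidence are COA, only negative COR, both MIXED. This yields
disjoint classes by construction; the order of input records never
matters. Symbols are upper-cased; synonym resolution is deliberately out
of scope — callers must supply harmonized symbols. Reference class sizes
for a genome-wide catalog are on the order of 2,662 TFs, 766 COA, 599 COR
and 511 MIXED genes; the synthetic generator's class fractions (0.133,
0.038, 0.030, 0.026) mirror those proportions over a ~20k-gene genome.

## Empirical family test

Given per-gene scores s over a universe of n detected genes and a class
of size k, the null is built from B subsets of size k sampled uniformly
without replacement (partial selection on iid uniform keys, vectorized in
blocks capped at 4×10⁷ cells). Statistics:

* `proportion_beyond_threshold` (default, t = 2 Z-scores): fraction of
  class genes with s < −t (down), s > t (up), or |s| > t (two-sided).
  Direction is encoded in the indicator, so larger is always more extreme.
* `mean`: class mean of s; the direction picks the tail.
* `mean_rank`: class mean of the ranks of s within the universe.

p = (1 + r)/(B + 1) where r counts null draws at least as extreme; ties
count toward r (conservative), with a 1e-9 relative tolerance so that a
draw that reproduces the class set itself still ties after floating-point
summation in a different order. The floor is exactly 1/(B+1) and the
maximum exactly 1. BH FDR is applied across the full panel; classes that
are empty or singleton in a cohort's universe are flagged `skipped`
rather than dropped. B defaults to 100,000; the analysis scripts use
20,000 and the pipeline 5,000, trading the attainable p floor for
runtime — panel conclusions at q < 0.1 are unchanged at these depths.

The proportion statistic operates naturally on per-gene-per-tumor Z
matrices summarized per gene; when the per-gene score is itself a tumor
average (as in the shipped pipeline), essentially no gene exceeds |Z| = 2
and the proportion statistic degenerates, so the pipeline and the
calibration/power experiments use the `mean` statistic. Both remain
first-class options.

## Alteration scores

* Tumor-vs-normal Z: per gene, (tumor value − normal mean)/normal SD
  (ddof = 1), requiring ≥ 2 normals; genes "detectible" (non-missing and
  above an expression floor, default > 0) in < 80% of samples are
  dropped, as are zero-variance genes (with a warning). The 80% threshold
  is applied over all samples; this and the floor are configurable.
* Median Z: (value − row median)/row SD, for cohorts without normals.
* CNA calls: deep (±2 only) or any (|code| ≥ 1) amplification/deletion
  indicators from GISTIC codes.
* Mutation burden: score_g = sqrt(Σ_samples m_gs / L_g) with L_g the
  genomic union of all (alternative) exon intervals, so shared bases count
  once. The square root damps the linear growth of summed counts with
  cohort size; the pre-sqrt rate is always reported and a per-tumor-rate
  reading is selectable (`mode="per_tumor_rate"`), since length-plus-
  cohort normalization admits more than one sensible formula.

All genomic coordinates are 0-based half-open throughout.

## Filtering, clustering, intersection

The frequent-alteration filter keeps genes with |Z| (or signed Z) > t in
at least a fraction f of tumors — strict on Z, non-strict on f. Two
presets are shipped (t = 2 and t = 2.5, both with f = 0.35) because both
thresholds are in common use for this screen; the default direction is
`either` since both tails are of interest in clustered heatmaps. Tumor
clustering is agglomerative with complete linkage on Euclidean distance
(the common clustered-heatmap default), cut at k = 2 by default.
Cluster-vs-outcome association is a Pearson chi-squared without
continuity correction; continuous clinical variables are dichotomized at
the median first. Cross-cohort intersection reports exclusive
UpSet-style combination sizes, which sum to the union size by
construction.

## Survival screen

Per gene, tumors at or below Q1 of expression form the lower group and at
or above Q3 the upper group (linear-interpolation quantiles; boundary
ties included by default, strict comparison selectable); the middle half
is excluded. Groups are compared by the standard two-group log-rank test
with hypergeometric variance, and the Kaplan–Meier product-limit
estimator provides the curves; both are computed with lifelines. BH FDR
is applied per cohort across exactly the screened genes; genes whose
quartile split is undefined (constant expression) are reported as NA and
excluded from both sides of the correction. Quartiles are taken on raw
expression values — any monotone transform (Z-scoring included) yields
the same groups.

## Cis-regulation cascade

Peaks are first required to overlap a chromatin-state segment by
≥ 1 bp (half-open intervals, so touching segments share 0 bp), then
annotated to every gene whose anchor lies within W = 100,000 bp; the
anchor is the TSS by default, with gene-body-edge anchoring available.
Distance is the gap in bases from the nearest peak edge to the anchor,
strand-ignorant: an anchor inside the peak is at distance 0, one exactly
100,000 bp away is linked, 100,001 bp is not. Interval queries use
interval trees; brute-force all-pairs oracles verify them in the tests.

Cohort quartile DE splits tumors on the index gene's expression and tests
every other gene with a two-sided Wilcoxon rank-sum test (logFC = upper −
lower group mean, BH FDR). This rank-based test is a deliberate,
documented substitution for a count-model DE fit: the cohort input here
is continuous (log/Z-scale) expression, for which a location-shift rank
test is the natural choice. DEG significance defaults to FDR < 0.05 and
|logFC| > 1.5, with a looser FDR-only rule shipped as a second preset,
because published gene counts for such screens vary with the rule. The
bound-and-regulated network is the exact three-set intersection of linked
genes with the significant genes of both contrasts, ranked by |cohort
logFC| — this ranking is also the documented (otherwise arbitrary)
criterion for truncations such as "top 63". Correlation profiles use
Spearman correlation by default (robust to outliers; Pearson selectable)
and a two-sample KS test of the gene set's correlations against the
background's, reporting D, p and the sign of the shift.

## Synthetic data generator

The generator defines the study conditions rather than fitting any real
cohort. One config seeds everything; the same config written twice is
byte-identical.

* **Cohort**: 10,000 genes, 498 tumors, 52 normals by default (a
  local-tumor cohort scale); the analysis scripts use 6,000 × 200 + 40 to
  keep runtimes in seconds. Expression for gene g is N(μ_g, σ_g) with
  μ_g ~ N(8, 2), σ_g ~ U(0.5, 2); only location and scale matter
  downstream because the pipeline consumes Z-scores. A planted expression
  effect adds `effect_size × σ_g` to the affected cells, so affected
  cells have true tumor-vs-normal Z shift equal to `effect_size`;
  effects select a fraction of a class's genes and a fraction of tumors.
  CNA codes are iid from (0.01, 0.09, 0.80, 0.09, 0.01) over {−2…+2};
  a planted CNA effect is the probability an affected cell is set to the
  deep code (sign chooses deletion vs amplification). Mutations are
  Poisson with per-cell rate `rate_per_bp × L_g` (default 1e-6/bp ≈ one
  exonic mutation per Mb per tumor); a planted mutation effect multiplies
  the rate. Gene models are laid on one synthetic chromosome with 1–20
  exons of 80–300 bp.
* **Structure seed**: class labels, gene models and the identity of
  affected genes can be pinned to a separate `structure_seed`, so two
  seeds emulate independent cohorts of the same disease in which the same
  genes are altered — this is what makes cross-cohort intersection
  meaningful.
* **Survival**: exponential proportional hazards, hazard
  λ0·exp(Σ coef_g Z_g) with λ0 = 1/1500 per day and Z the generative
  (true) standardization; censoring is an independent exponential whose
  rate is chosen to give the configured null censoring fraction (default
  0.6). Exponential baselines are the simplest proportional-hazards
  generator; recovery is tested by log-rank ranking, not by model
  fitting. Tumor grade (Gleason-like, 6–9) is drawn with higher-grade
  probabilities for tumors carrying a planted expression effect, so
  cluster-grade association is recoverable in principle — the planted
  tumor sets of different effects overlap, so the association strength
  varies across seeds.
* **Cistrome**: one synthetic chromosome holding a gene region (20 kb
  spacing), followed by a gene-free tail. Chromatin states tile the
  chromosome as 2 kb labeled segments separated by 1 kb gaps. Each truth
  gene gets a peak placed inside a state segment within the 100 kb window
  of its TSS; decoys are placed either in the tail beyond the window of
  every gene (removed by the distance filter) or inside gaps (removed by
  the state filter). Multi-chromosome layouts are a config away but not
  the default.
* **Knockdown DE**: 15,000 genes with 1,993 down- and 1,607 up-regulated
  (gamma-distributed |logFC| with means 1.11 and 0.83, shape 2 — the
  skew of a coactivator knockdown), DEG p-values log-uniform in
  [1e-8, 1e-2], null p uniform, BH over all.

What the generator does **not** emulate: correlated co-expression
modules beyond shared planted effects, CNA segment geometry (calls are
iid per gene), mutational signatures and hotspots, batch effects, or
count-level RNA-seq noise. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the
planted-effect model, not robustness to every failure mode of real
cohort data.

## Numerical choices and degenerate inputs

* Empirical p never returns 0 (add-one estimator); ties count toward the
  null (see above).
* Zero-variance genes: dropped with a warning in Z-scoring; constant
  expression in the survival screen yields NA outside the FDR family;
  constant rows in correlation profiles are excluded with a count.
* Chi-squared requires ≥ 2 × 2 non-degenerate margins; quartile grouping
  requires ≥ 8 samples and Q1 ≠ Q3.
* Clustering ties are resolved by scipy's deterministic merge order; all
  sorts in the package use stable mergesort so outputs are order-stable.
* Sub-seeds passed between stages stay below 2³¹.

## Problem sizes

The shipped experiments run on one CPU in seconds to a couple of
minutes: null calibration uses 500 random classes at B = 2,000 over a
2,000-gene universe; power/recovery uses 20 seeds at 10,000 genes × 100
tumors; the end-to-end pipeline uses 6,000 genes × 200 tumors at
B = 5,000. These sizes were chosen so the full suite and the
reproduction script each complete comfortably on a laptop while leaving
every statistical conclusion (calibration bands, recovery rates)
unchanged relative to larger runs.

## Known limitations

* The resampling test is competitive (random gene sets), not
  self-contained; correlated gene classes inflate significance on real
  data in ways the iid generator cannot reveal.
* The rank-sum quartile DE is not a count-model DE; applying it to raw
  counts rather than log/Z expression would be inappropriate.
* Catalog construction assumes harmonized gene symbols; no synonym or
  cross-species mapping.
* The survival module implements exactly the two-group quartile log-rank
  screen; no Cox modeling or multivariable adjustment.
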