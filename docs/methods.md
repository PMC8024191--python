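# Methods

`aluedit` implements an A-to-I RNA-editing analysis for cohorts with
matched DNA and RNA sequencing, of the kind used to characterise editing
in chronic lymphocytic leukemia (CLL) against normal B cells.  This note
describes the models, the thresholds that matter, the synthetic-cohort
generator, and the numerical choices made where the design was open.

## The measurement model

The pipeline starts from per-position base-count pileups (sample,
modality DNA/RNA, contig, position, reference base, counts of A/C/G/T
reads).  Alignment, duplicate marking and quality filtering are upstream
commodity steps; everything this package contributes operates on
per-position RNA/DNA comparisons, so pileups are the natural input
contract.  All coordinates are 0-based half-open internally; pileup TSV
and VCF positions are 1-based on disk and converted at the I/O boundary.

### RNA–DNA difference (RDD) calling

A site yields at most one call per sample.  The site must look
genomically homozygous-reference in DNA (depth ≥ `min_dna_cov` = 10 and
reference-allele fraction ≥ `homozygosity_frac` = 0.95 — this is the SNP
exclusion step), and the dominant non-reference RNA base must be
supported by ≥ `min_var_reads` = 2 reads at frequency ≥ `min_var_freq` =
0.05 with RNA depth ≥ `min_rna_cov` = 10.  Ties between variant bases
break in the fixed order A < C < G < T so the caller is deterministic.
The thresholds are not dictated by any published table; they are standard
RDD-calling practice balancing the sequencing error rate (~10⁻³ per base)
against sensitivity, and every one of them is a config field.

The reference-strand change class is one of the 12 ordered base pairs
("A>G", "T>C", …).  When the covering feature's strand is known, the
substitution is mapped onto the coding strand: A>G on '+' and T>C on '−'
both resolve to A>I, the molecular signature of ADAR deamination (inosine
is read as guanosine).  This strand resolution is exercised by a
reverse-complement invariance test: flipping the whole dataset (genome,
intervals, pileups) leaves the strand-resolved A>I call set unchanged.

### Alu editing metrics

Two per-sample global-activity statistics are computed over Alu
intervals, restricted to strand-adjusted adenosines (reference A in
plus-strand Alus, reference T in minus-strand Alus, where edited reads
appear as C):

* **AEI (Alu editing index)**, in percent: `100 · Σ edited / Σ (edited +
  unedited)` pooled over all covered Alu adenosines.  Pooling raw read
  counts — rather than averaging per-site frequencies — weights each
  position by its expression, so highly expressed Alu elements dominate,
  matching the published construction of the index.  Published CLL values
  (1.22–2.45 "arbitrary units") are consistent with this percent scale.
* **Unique Alu editing sites**: Alu adenosines with ≥ 2 edited reads at
  ≥ 1% frequency.  No published threshold exists for a site to count; the
  defaults are this package's decision and are configurable.

Positions with fewer than 5 A+G-equivalent reads are excluded from both
statistics (configurable).  The AEI uses A+G depth rather than total
depth for this cut because only those reads enter the index.

### Recoding annotation

Feature classification uses the precedence CDS > UTR > intron >
intergenic.  For CDS hits the codon is reconstructed on the coding
strand, the A→G substitution applied, and both amino acids derived from
the standard genetic code; consequences are synonymous, nonsynonymous or
stop-affecting.  For binary "amino-acid changing" summaries,
stop-affecting is pooled with nonsynonymous.  "Exonic" in consequence
percentages means CDS-overlapping; UTR is reported separately (published
reports do not state whether their "exonic" includes UTRs — keeping the
classes separate loses nothing).  When two genes' CDS contain a site, the
lexicographically first gene supplies the reported consequence and the
others are listed alongside.

Sequence context is profiled at the −1/+1 neighbours of the edited
adenosine on the coding strand and compared with a background of covered
adenosines: per-base enrichment ratios plus two-sided binomial tests.
ADAR's deamination motif — G depleted at −1, G enriched at +1 — is the
expected signature of a genuine catalog.

### Recurrence catalog

The editing matrix (sites × samples) is extracted directly from pileup
counts at a fixed panel, so a covered-but-unedited cell is 0, not
missing; a cell is missing exactly when its A+G depth is below
`matrix_min_cov` = 10.  A site is "edited in a patient" at frequency
≥ 0.01 with ≥ 2 edited reads (again the published rule names only
"k of N"), and the recurrence filter keeps sites edited in ≥ k = 5
samples.  Coverage exclusion then drops sites missing in more than
`max_missing_frac` = 50% of samples — the rule that, in the published
validation cohort, removed one low-coverage gene's four sites from a
19-site panel leaving 15.

### Clustering and survival

Samples are clustered on their site-frequency vectors by agglomerative
hierarchical clustering with Ward linkage on Euclidean distance, after
imputing missing cells with the site's cross-sample mean; the dendrogram
is cut into exactly k groups.  None of these choices are stated in the
source study; Ward/Euclidean/mean-imputation is the standard,
deterministic combination at this scale, and silhouette scores for
k = 2…8 are reported to aid choosing k.  Cluster labels are renumbered by
decreasing size so the partition is invariant to sample order.

Survival endpoints (time to first treatment, from sampling or from
diagnosis) are compared between one cluster and the rest with
Kaplan–Meier curves, the log-rank test, and a univariate Cox
proportional-hazards fit for the hazard ratio with Wald 95% CI;
multivariate Cox fits take cytogenetics and IGHV status as covariates.
The survival machinery is standard and is delegated to lifelines (Efron
tie handling); with continuous simulated times, ties are measure-zero, so
this is numerically indistinguishable from Breslow handling, and the
package's tests verify the log-rank statistic and Kaplan–Meier medians
against brute-force enumeration and the univariate Cox HR against the
two-group route.  The F-test of equal AEI variances (CLL vs normal B)
puts the larger variance in the numerator with a two-sided p on
(n₁−1, n₂−1) degrees of freedom.  Benjamini–Hochberg adjustment is used
for cofactor differential-expression screens.

## The synthetic cohort

Access-controlled patient data cannot ship with an analysis package, so a
generator emulates the statistical structure the pipeline must handle.
Its defaults are the study conditions:

| aspect | default | basis |
| --- | --- | --- |
| cohort | 45 CLL (19 IGHV-mutated / 21 unmutated / 5 unknown) + 9 normal B | published cohort table |
| genome | 3 contigs × 26 kb; 56 inverted Alu pairs × 300 bp; 14 genes with 3 CDS exons | ≥ 10,000 Alu adenosines; Alu pairs are the ADAR substrate |
| global Alu editing rate | Uniform(0.012, 0.0245) per CLL sample | printed AEI range 1.22–2.45 |
| normal-B rate | Normal(0.022, 0.001) | naive B cells: high, homogeneous editing |
| recoding panel | 19 sites in 14 genes, one gene carrying 4 | published panel shape |
| cluster profiles | 4 clusters; cluster 1 = one dominant site + one intermediate, rest ≈ 0 | described poor-prognosis pattern |
| sequencing error | 0.001/base, uniform across substitutions | realistic false-candidate pressure |
| coverage | DNA 30×, RNA 50× (Poisson) | exome/transcriptome scale |
| survival | exponential; baseline hazard 0.0059/month (median ≈ 117 mo), cluster-1 HR 2.0, exponential censoring 0.004/month | printed medians and univariate HR |
| ADAR–editing correlation | r = 0.8 in IGHV-mutated, 0 in unmutated | the study's central IGHV asymmetry |

DNA counts are homozygous reference plus error (with a configurable set
of planted heterozygous SNPs that the caller must reject); RNA counts
draw edited reads Binomial(coverage, true level) onto G (plus strand) or
C (minus strand).  Editing is planted only at adenosines; every other
change class arises from error alone.  Non-Alu background sites are sized
so that exactly the configured fraction (default 99%) of planted A>I
events falls inside Alu intervals.  Note the distinction the real data
also shows: the *called* Alu fraction is lower (~0.95 under defaults)
because most Alu adenosines sit at ~1.5% editing and fall under the
variant-read thresholds, while the recoding panel is called reliably.

All randomness derives from one seed through `numpy.random.SeedSequence`
spawning in a fixed order (genome, truth, one stream per sample's
pileups, clinical table), so any stage can be reproduced independently
and `simulate --seed N` is byte-deterministic.

What the generator does **not** emulate: alignment artefacts and mapping
ambiguity (the published study resolved these manually with BLAST/IGV),
exome capture bias (simulated DNA covers Alu regions uniformly, which
real WES does not), overdispersed per-site editing-level distributions
within Alu, hyper-edited reads, indels, copy-number and subclonal DNA
variation, and correlation between editing and gene expression beyond
the planted ADAR relationship.  Passing tests therefore demonstrate that
the algorithms recover planted signal under binomial read sampling and
realistic error — not that the thresholds are optimal for any particular
real dataset.

## Numerical choices and degenerate inputs

* Variant-base ties and cluster-label assignment break deterministically
  (base order; cluster size then smallest sample id).
* Sites with reference N are skipped and tallied, not errors.
* An empty AEI denominator (no covered Alu adenosine), a fully excluded
  site panel, zero-variance correlation input, groups with n < 2, and
  survival data without events all raise informative errors rather than
  returning NaN.
* Cox fits reject constant or collinear covariates before fitting and
  surface separation (diverging coefficients) as errors; unreached
  Kaplan–Meier medians are reported as infinity (null in JSON output).
* VCF round-tripping stores frequencies as full-precision strings so a
  written call set reads back bit-identically.

## Problem sizes

Default problem sizes (45 + 9 samples, ~78 kb genome, ~45,000 pileup
positions per sample and modality, 100-replicate survival calibrations)
were chosen so a full run completes in well under a minute on a single
core while every statistical check retains comfortable power; all sizes
scale through `SimParams`.

## Known limitations

* Percentages in consequence tables are rounded to one decimal; sums can
  differ from 100 by rounding.
* The two TTFT endpoints share one event time plus a uniform
  diagnosis-to-sampling lag, so they are perfectly dependent — adequate
  for exercising the dual-endpoint interface, not a model of real
  diagnosis-to-sampling dynamics.
* The multivariate Cox covariate coding (binary aberration flags,
  IGHV-unmutated indicator, unknown-status samples dropped per analysis)
  is this package's own documented convention.
* `cox_multivariate` uses Efron tie handling (see above); with heavily
  tied real-world times the Breslow/Efron distinction could matter.
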