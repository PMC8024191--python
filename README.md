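# aluedit

A-to-I RNA-editing analysis for cohorts with matched DNA and RNA
sequencing — built around the questions asked of editing in chronic
lymphocytic leukemia (CLL): how much global Alu editing does each sample
show, which coding sites are recurrently recoded, do editing patterns
define patient subgroups, and do those subgroups differ in time to first
treatment?

It is aimed at computational biologists who have per-position base
counts (pileups) from matched RNA-seq and DNA sequencing and want a
tested, deterministic implementation of the full analysis chain, plus a
synthetic-cohort generator with known ground truth standing in for
access-controlled patient data.

## What it computes

* **RDD calling** — RNA–DNA single-nucleotide differences per sample: a
  site genomically homozygous reference (DNA depth ≥ 10, reference
  fraction ≥ 0.95) whose dominant non-reference RNA base has ≥ 2 reads at
  frequency ≥ 5%. A>G on the feature's coding strand (T>C on the
  reference strand for minus-strand features) resolves to A>I, the ADAR
  signature.
* **Alu editing index (AEI)** — the pooled edited-read fraction over all
  covered Alu adenosines, in percent:

      AEI = 100 · Σ_i G_i / Σ_i (A_i + G_i)

  summed over strand-adjusted Alu adenosines i; pooling read counts
  weights each position by its expression. Also the count of **unique
  Alu editing sites** (≥ 2 edited reads, ≥ 1% frequency).
* **Recoding annotation** — feature class (CDS > UTR > intron >
  intergenic), codon consequence of the A→G change via the standard
  genetic code, and the −1/+1 sequence-context profile against a
  covered-adenosine background (ADAR motif: G depleted at −1, enriched
  at +1).
* **Recurrence catalog** — a site × sample editing-frequency matrix
  extracted straight from pileup counts (0 when covered-but-unedited,
  missing below 10× depth), a k-of-N recurrence filter (default: edited
  in ≥ 5 samples), and exclusion of sites missing in > 50% of samples.
* **Cohort analytics** — Pearson/Spearman correlation, Welch t-test,
  two-sided variance F-test, Benjamini–Hochberg FDR, Ward hierarchical
  clustering of editing profiles, Kaplan–Meier medians, log-rank tests
  and uni-/multivariate Cox proportional-hazards models.
* **Synthetic cohort** — 45 CLL + 9 normal B-cell samples by default,
  with inverted Alu pairs, a 19-site recoding panel over 14 genes,
  cluster-specific editing profiles, ADAR expression correlated with
  editing only in IGHV-mutated samples, and exponential survival with a
  configurable cluster hazard ratio. Fully seeded and byte-deterministic.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate the default cohort and run every stage:

```python
from aluedit import SimParams
from aluedit.pipeline import run_pipeline, summarize_results

results = run_pipeline(params=SimParams(seed=1))
print(summarize_results(results))
```

Selected output (seed 1):

```
n_rdd_calls                        51165
n_a2i_calls                        50220
aei_percent_min_cll                1.256
aei_percent_max_cll                2.484
aei_slope_vs_true_rate             1.012
n_recurrent_sites                  19
n_sites_after_coverage_exclusion   19
cluster_ari_vs_truth               1.0
ttft_hazard_ratio_cluster1         1.937
ttft_logrank_p                     0.145
aei_variance_f                     12.97
adar_p110_aei_r_mutated            0.468
adar_p110_aei_r_unmutated          0.103
```

Reading this: per-sample AEI spans 1.26–2.48%, tracking the planted
global editing rates with regression slope ≈ 1; all 19 planted recoding
sites pass the 5-of-45 recurrence filter and none is lost to the
coverage rule; clustering recovers the planted 4-group structure
perfectly (adjusted Rand index 1.0); the cluster-1 hazard ratio estimate
(1.94) sits near the simulated truth of 2.0 (a single 45-patient cohort
gives limited log-rank power, hence p ≈ 0.14); AEI variance is ~13-fold
higher in CLL than in the homogeneous normal B cells; and ADAR p110
expression correlates with AEI in IGHV-mutated but not unmutated
samples — the planted asymmetry.

The same run is available from a shell:

```sh
aluedit all --seed 1 --outdir out/
aluedit simulate --seed 7 --outdir sim/        # inputs + ground truth
aluedit call-rdd --pileups sim/pileups --alu-bed sim/alu.bed \
        --genome sim/genome.fa --outdir calls/
```

Stages (`simulate`, `call-rdd`, `aei`, `annotate`, `recur`, `cluster`,
`survive`, `all`) are rerunnable from their on-disk inputs; rerunning
with the same seed and config reproduces outputs byte for byte.

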