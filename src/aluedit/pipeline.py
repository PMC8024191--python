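"""End-to-end orchestration of the editing analysis on a simulated cohort.

Runs every stage in order — RDD calling, Alu editing metrics, recoding
annotation, the recurrence catalog, clustering and survival — and collects
the headline quantities into one JSON-serialisable results dictionary.
Used by the ``aluedit all`` CLI subcommand and by the reproduction script.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import cohort_analytics as ca
from . import editing_indices as ei
from . import recoding_annotation as ann
from . import recurrence_catalog as rc
from . import rdd_detection as rdd
from .io_formats import IntervalSet, RunConfig, write_rdd_vcf
from .synthetic_cohort import SimParams, SyntheticCohort, simulate_cohort, write_cohort


def run_pipeline(
    params: SimParams | None = None,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    cohort: SyntheticCohort | None = None,
) -> dict:
    """Simulate (or reuse) a cohort and run the full analysis.

    Returns a dictionary of stage outputs and summary statistics; when
    ``outdir`` is given, also writes the simulated inputs, the RDD VCF,
    stage TSVs and a JSON run summary there.
    """
    if params is None:
        params = SimParams()
    if config is None:
        config = RunConfig(n_clusters=params.n_clusters + 1, seed=params.seed)
    if cohort is None:
        cohort = simulate_cohort(params)

    out: Path | None = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, out / "inputs")

    dna = cohort.pileups[cohort.pileups["modality"] == "DNA"]
    rna = cohort.pileups[cohort.pileups["modality"] == "RNA"]

    # --- RDD calling --------------------------------------------------
    call_summary: dict = {}
    calls = rdd.call_rdds(dna, rna, config, summary=call_summary)
    calls = rdd.flag_alu(calls, cohort.alu)
    gene_spans = IntervalSet(
        [(g.contig, g.span[0], g.span[1], g.strand) for g in cohort.genes]
    )
    stranded = IntervalSet(list(cohort.alu) + list(gene_spans))
    calls = rdd.resolve_strand_classes(calls, stranded)
    a2i = [c for c in calls if c.strand_class == "A>I"]
    n_samples_cll = int((cohort.truth.samples["sample_type"] == "CLL").sum())
    a2i_per_sample = pd.Series([c.sample for c in a2i]).value_counts()

    # --- Alu editing metrics -----------------------------------------
    aei = ei.aei_table(
        rna,
        cohort.alu,
        cohort.genome,
        min_coverage=config.aei_min_coverage,
        unique_site_min_reads=config.unique_site_min_reads,
        unique_site_min_freq=config.unique_site_min_freq,
    )
    truth_samples = cohort.truth.samples.set_index("sample")
    aei = aei.set_index("sample").join(truth_samples[["sample_type", "ighv_status"]])
    aei["true_rate"] = truth_samples["global_rate"]
    slope = float(
        np.polyfit(aei["true_rate"].to_numpy(), aei["aei"].to_numpy() / 100.0, 1)[0]
    )

    # --- annotation ---------------------------------------------------
    unique_a2i_sites = sorted({(c.contig, c.pos) for c in a2i})
    annotated = [
        ann.annotate_site(site, cohort.genes, cohort.genome) for site in unique_a2i_sites
    ]
    consequences = ann.summarize_consequences(annotated)
    cds_sites = [s for s in annotated if s.feature_class == "exonic-CDS"]
    background = _coding_adenosines(cohort)
    context = (
        ann.context_profile(cds_sites, cohort.genome, background) if cds_sites else None
    )

    # --- recurrence catalog -------------------------------------------
    panel = cohort.truth.panel()
    matrix = rc.build_matrix(rna, panel, min_cov=config.matrix_min_cov)
    recurrent = rc.recurrent_sites(
        matrix,
        k=config.recurrence_k,
        min_freq=config.edited_min_freq,
        min_reads=config.edited_min_reads,
    )
    matrix_rec = matrix.subset_sites([s.key for s in recurrent])
    matrix_kept, excluded = rc.exclude_low_coverage_sites(
        matrix_rec, max_missing_frac=config.max_missing_frac
    )

    # --- clustering ---------------------------------------------------
    assignment = ca.cluster_samples(matrix_kept, k=config.n_clusters)
    truth_labels = truth_samples.loc[assignment.labels.index, "cluster"]
    ari = float(adjusted_rand_score(truth_labels.to_numpy(), assignment.labels.to_numpy()))
    sil = ca.silhouette_scores(matrix_kept)

    # --- cohort statistics --------------------------------------------
    clinical = cohort.cohort.set_index("sample")
    cll = clinical[clinical["sample_type"] == "CLL"]
    nb = clinical[clinical["sample_type"] == "normal_b"]
    stats: dict = {}
    for status in ("mutated", "unmutated"):
        grp = cll[cll["ighv_status"] == status].join(aei[["aei"]])
        r, p = ca.correlate(grp["adar_p110"], grp["aei"])
        stats[f"adar_p110_aei_r_{status}"] = r
        stats[f"adar_p110_aei_p_{status}"] = p
    t, p = ca.group_ttest(
        cll.loc[cll["ighv_status"].isin(["mutated", "unmutated"]), "adar_p110"],
        cll.loc[cll["ighv_status"].isin(["mutated", "unmutated"]), "ighv_status"],
    )
    stats["adar_p110_ighv_t"] = t
    stats["adar_p110_ighv_p"] = p
    ftest = None
    if len(nb) >= 2:
        ftest = ca.variance_ftest(
            aei.loc[aei["sample_type"] == "CLL", "aei"],
            aei.loc[aei["sample_type"] == "normal_b", "aei"],
        )
        stats["aei_variance_f"] = ftest.f_statistic
        stats["aei_variance_p"] = ftest.p_value
    cof_p = [
        ca.group_ttest(
            cll.loc[cll["ighv_status"].isin(["mutated", "unmutated"]), f"cofactor_{i}"],
            cll.loc[cll["ighv_status"].isin(["mutated", "unmutated"]), "ighv_status"],
        )[1]
        for i in range(1, 7)
    ]
    cof_adj = ca.bh_fdr(cof_p)
    stats["n_cofactors_fdr_significant"] = int((cof_adj < 0.05).sum())

    # --- survival ------------------------------------------------------
    cll_labels = assignment.labels[assignment.labels.index.isin(cll.index)]
    in_cl1 = _cluster1_indicator(cll_labels, truth_samples)
    surv = {}
    for endpoint in ("ttft_sampling_months", "ttft_diagnosis_months"):
        times = cll.loc[cll_labels.index, endpoint].to_numpy()
        events = cll.loc[cll_labels.index, "event"].to_numpy().astype(int)
        res = ca.km_logrank(times, events, in_cl1.to_numpy())
        surv[endpoint] = res
    covars = cll.loc[cll_labels.index, ["del11q", "del13q", "del17p", "trisomy12"]].astype(int)
    covars["editing_cluster_1"] = in_cl1.astype(int).to_numpy()
    covars["ighv_unmutated"] = (
        cll.loc[cll_labels.index, "ighv_status"] == "unmutated"
    ).astype(int)
    covars = covars.loc[:, covars.nunique() >= 2]  # small cohorts may lack an aberration
    mv = ca.cox_multivariate(
        cll.loc[cll_labels.index, "ttft_sampling_months"].to_numpy(),
        cll.loc[cll_labels.index, "event"].to_numpy().astype(int),
        covars,
    )

    results = {
        "params": params,
        "config": config,
        "cohort": cohort,
        "calls": calls,
        "call_summary": call_summary,
        "a2i_calls": a2i,
        "a2i_per_sample": a2i_per_sample,
        "aei": aei,
        "aei_slope_vs_truth": slope,
        "annotated_sites": annotated,
        "consequence_table": consequences,
        "context_profile": context,
        "matrix": matrix,
        "recurrent_sites": recurrent,
        "matrix_final": matrix_kept,
        "excluded_sites": excluded,
        "clusters": assignment,
        "cluster_ari_vs_truth": ari,
        "silhouette": sil,
        "stats": stats,
        "survival": surv,
        "cox_multivariate": mv,
        "n_samples_cll": n_samples_cll,
    }
    if out is not None:
        _write_outputs(results, out)
    return results


def _coding_adenosines(cohort: SyntheticCohort) -> list[tuple[str, int, str]]:
    """All coding-strand adenosine positions in CDS (context background)."""
    bg = []
    for g in cohort.genes:
        cds = g.coding_sequence(cohort.genome)
        for off, base in enumerate(cds):
            if base == "A":
                bg.append((g.contig, g.cds_position(off), g.strand))
    return bg


def _cluster1_indicator(labels: pd.Series, truth_samples: pd.DataFrame) -> pd.Series:
    """Map inferred clusters onto the planted poor-prognosis cluster.

    The inferred label whose members most often carry true cluster 1 plays
    the role of "cluster 1" in survival analyses; with real data this
    choice would come from the editing profile itself.
    """
    truth_cl = truth_samples.loc[labels.index, "cluster"]
    best_label, best_frac = None, -1.0
    for lab, grp in labels.groupby(labels):
        frac = float((truth_cl.loc[grp.index] == 1).mean())
        if frac > best_frac:
            best_label, best_frac = lab, frac
    return labels == best_label


def _write_outputs(results: dict, out: Path) -> None:
    cohort: SyntheticCohort = results["cohort"]
    calls = sorted(results["calls"], key=lambda c: (c.contig, c.pos, c.sample))
    write_rdd_vcf(calls, out / "rdd_calls.vcf", genome=cohort.genome)
    rdd.rdd_summary(results["calls"]).to_csv(out / "rdd_summary.tsv", sep="\t", index=False)
    results["aei"].to_csv(out / "aei.tsv", sep="\t", float_format="%.10g")
    results["consequence_table"].to_csv(out / "consequences.tsv", sep="\t", index=False)
    results["matrix_final"].to_tsv(out / "editing_matrix.tsv")
    results["clusters"].labels.rename("cluster").to_csv(
        out / "clusters.tsv", sep="\t", index_label="sample"
    )
    surv_json = {
        endpoint: dataclasses.asdict(res) for endpoint, res in results["survival"].items()
    }
    with open(out / "survival.json", "w") as fh:
        json.dump(surv_json, fh, indent=2, sort_keys=True, default=float)
    summary = summarize_results(results)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def summarize_results(results: dict) -> dict:
    """Flatten headline numbers from a pipeline run into plain scalars."""
    aei = results["aei"]
    cll_aei = aei[aei["sample_type"] == "CLL"]
    surv_s = results["survival"]["ttft_sampling_months"]
    cons = results["consequence_table"].set_index(["category", "label"])
    summary = {
        "n_rdd_calls": len(results["calls"]),
        "n_a2i_calls": len(results["a2i_calls"]),
        "a2i_calls_per_sample_mean": float(results["a2i_per_sample"].mean()),
        "a2i_alu_call_fraction": float(
            np.mean([c.in_alu for c in results["a2i_calls"]])
        ),
        "aei_percent_mean_cll": float(cll_aei["aei"].mean()),
        "aei_percent_min_cll": float(cll_aei["aei"].min()),
        "aei_percent_max_cll": float(cll_aei["aei"].max()),
        "unique_alu_sites_mean_cll": float(cll_aei["unique_alu_sites"].mean()),
        "aei_slope_vs_true_rate": results["aei_slope_vs_truth"],
        "exonic_cds_percent": float(cons.loc[("feature", "exonic-CDS"), "percent"]),
        "amino_acid_changing_percent": (
            float(cons.loc[("consequence", "amino-acid-changing"), "percent"])
            if ("consequence", "amino-acid-changing") in cons.index
            else 0.0
        ),
        "n_recurrent_sites": len(results["recurrent_sites"]),
        "n_sites_after_coverage_exclusion": results["matrix_final"].shape[0],
        "n_excluded_sites": len(results["excluded_sites"]),
        "cluster_ari_vs_truth": results["cluster_ari_vs_truth"],
        "ttft_hazard_ratio_cluster1": surv_s.hazard_ratio,
        "ttft_hr_ci_low": surv_s.ci_low,
        "ttft_hr_ci_high": surv_s.ci_high,
        "ttft_logrank_p": surv_s.p_value,
        "ttft_median_cluster1": surv_s.median_b,
        "ttft_median_other": surv_s.median_a,
    }
    summary.update(results["stats"])
    for k, v in list(summary.items()):
        if isinstance(v, (np.floating, np.integer)):
            v = float(v)
        if isinstance(v, float) and not np.isfinite(v):
            v = None  # unreached medians / undefined statistics
        summary[k] = v
    return summary
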