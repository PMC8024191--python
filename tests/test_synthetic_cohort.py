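"""Generator invariants: determinism, planted structure, parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from aluedit import SimParams, simulate_cohort, simulate_genome_and_annotations
from aluedit.cohort_analytics import correlate
from aluedit.synthetic_cohort import (
    default_site_profiles,
    simulate_survival,
    _site_counts_per_gene,
)


class TestGenome:
    def test_ten_pairs_give_twenty_intervals(self, tiny_params):
        params = dataclasses.replace(tiny_params, n_alu_pairs=10)
        _, alu, _ = simulate_genome_and_annotations(params)
        assert len(alu) == 20
        strands = [s for *_iv, s in alu]
        assert strands.count("+") == 10 and strands.count("-") == 10

    def test_cds_lengths_divisible_by_three(self, tiny_cohort):
        for g in tiny_cohort.genes:
            assert g.cds_length % 3 == 0

    def test_same_seed_identical_genome(self, tiny_params):
        g1, _, _ = simulate_genome_and_annotations(tiny_params)
        g2, _, _ = simulate_genome_and_annotations(tiny_params)
        assert g1.contigs == g2.contigs

    def test_too_small_genome_is_error(self, tiny_params):
        params = dataclasses.replace(tiny_params, contig_length=900)
        with pytest.raises(ValueError, match="too short"):
            simulate_genome_and_annotations(params)

    def test_features_do_not_overlap(self, tiny_cohort):
        spans = [(c, s, e) for c, s, e, _ in tiny_cohort.alu]
        spans += [(g.contig, *g.span) for g in tiny_cohort.genes]
        by_contig: dict = {}
        for c, s, e in spans:
            by_contig.setdefault(c, []).append((s, e))
        for ivs in by_contig.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2


class TestTruth:
    def test_site_distribution_over_genes(self):
        assert _site_counts_per_gene(19, 14) == [4, 2, 2] + [1] * 11
        assert sum(_site_counts_per_gene(19, 14)) == 19

    def test_recoding_sites_inside_cds_and_nonsynonymous(self, tiny_cohort):
        from aluedit import annotate_site

        for r in tiny_cohort.truth.recoding_sites.itertuples():
            site = annotate_site((r.contig, int(r.pos)), tiny_cohort.genes, tiny_cohort.genome)
            assert site.feature_class == "exonic-CDS"
            assert site.gene_id == r.gene_id
            assert site.consequence == "nonsynonymous"

    def test_alu_sites_inside_alu_intervals(self, tiny_cohort):
        truth = tiny_cohort.truth
        sampled = truth.alu_sites.sample(n=200, random_state=0)
        for r in sampled.itertuples():
            assert tiny_cohort.alu.contains(r.contig, int(r.pos))

    def test_sample_group_sizes(self, tiny_cohort):
        s = tiny_cohort.truth.samples
        cll = s[s["sample_type"] == "CLL"]
        assert len(cll) == 12
        assert (cll["ighv_status"] == "mutated").sum() == 5
        assert (cll["ighv_status"] == "unmutated").sum() == 5
        assert (s["sample_type"] == "normal_b").sum() == 4
        assert set(cll["cluster"]) <= {1, 2, 3, 4}

    def test_default_profiles_shape_and_range(self):
        p = default_site_profiles()
        assert p.shape == (4, 19)
        assert (p >= 0).all() and (p <= 1).all()
        assert p[0, 0] == pytest.approx(0.60)  # dominant site of cluster 1


class TestPileups:
    def test_fully_edited_site_shows_only_edited_base(self, tiny_params):
        """True level 1 with no sequencing error leaves no reference reads."""
        profiles = np.full((4, 19), 1.0)
        params = dataclasses.replace(
            tiny_params, error_rate=0.0, site_profiles=profiles, profile_sd=0.0
        )
        cohort = simulate_cohort(params)
        rna = cohort.pileups[cohort.pileups["modality"] == "RNA"]
        merged = cohort.truth.recoding_sites.merge(rna, on=["contig", "pos"])
        cll = set(
            cohort.truth.samples.loc[
                cohort.truth.samples["sample_type"] == "CLL", "sample"
            ]
        )
        merged = merged[merged["sample"].isin(cll)]
        plus = merged[merged["strand"] == "+"]
        minus = merged[merged["strand"] == "-"]
        assert (plus["nA"] == 0).all() and (plus["nG"] == plus[["nA", "nC", "nG", "nT"]].sum(axis=1)).all()
        assert (minus["nT"] == 0).all() and (minus["nC"] == minus[["nA", "nC", "nG", "nT"]].sum(axis=1)).all()

    def test_unedited_site_error_reads_only(self, tiny_cohort):
        """DNA pileups are homozygous reference apart from error-rate noise."""
        dna = tiny_cohort.pileups[tiny_cohort.pileups["modality"] == "DNA"]
        het = set(zip(tiny_cohort.truth.het_sites["contig"], tiny_cohort.truth.het_sites["pos"]))
        dna = dna[~dna.apply(lambda r: (r["contig"], r["pos"]) in het, axis=1)]
        counts = dna[["nA", "nC", "nG", "nT"]].to_numpy()
        ref_idx = np.searchsorted(np.array(list("ACGT")), dna["ref"].to_numpy())
        total = counts.sum(axis=1)
        nonref = total - counts[np.arange(len(dna)), ref_idx]
        # observed error fraction close to the configured rate
        assert nonref.sum() / total.sum() == pytest.approx(
            tiny_cohort.params.error_rate, rel=0.5
        )

    def test_planted_site_frequency_within_three_binomial_sd(self, tiny_params):
        """A 30% site observed at high coverage lands within 3 binomial SDs."""
        profiles = np.full((4, 19), 0.30)
        params = dataclasses.replace(
            tiny_params, rna_coverage=1000.0, site_profiles=profiles, profile_sd=0.0,
            n_samples=4, n_ighv_mutated=2, n_ighv_unmutated=2, n_normal_b=0,
        )
        cohort = simulate_cohort(params)
        rna = cohort.pileups[cohort.pileups["modality"] == "RNA"]
        merged = cohort.truth.recoding_sites.merge(rna, on=["contig", "pos"])
        plus = merged["strand"] == "+"
        edited = np.where(plus, merged["nG"], merged["nC"])
        unedited = np.where(plus, merged["nA"], merged["nT"])
        freq = edited / (edited + unedited)
        sd = np.sqrt(0.3 * 0.7 / (edited + unedited))
        assert (np.abs(freq - 0.30) < 3.5 * sd).mean() > 0.98

    def test_determinism_same_seed(self, tiny_params):
        c1 = simulate_cohort(tiny_params)
        c2 = simulate_cohort(tiny_params)
        pd.testing.assert_frame_equal(c1.pileups, c2.pileups)
        pd.testing.assert_frame_equal(c1.cohort, c2.cohort)


class TestCohortTable:
    def test_adar_correlates_with_editing_only_in_mutated(self, default_cohort):
        truth = default_cohort.truth.samples.set_index("sample")
        tbl = default_cohort.cohort.set_index("sample").join(truth[["global_rate", "cluster"]],
                                                             rsuffix="_t")
        mut = tbl[(tbl["ighv_status"] == "mutated") & (tbl["sample_type"] == "CLL")]
        unm = tbl[(tbl["ighv_status"] == "unmutated") & (tbl["sample_type"] == "CLL")]
        r_mut, _ = correlate(mut["adar_total"], mut["global_rate"])
        r_unm, _ = correlate(unm["adar_total"], unm["global_rate"])
        assert r_mut > 0.55
        assert abs(r_unm) < 0.45

    def test_null_correlation_parameter_centers_on_zero(self, tiny_params):
        rs = []
        for seed in range(12):
            params = dataclasses.replace(
                tiny_params, seed=seed, adar_corr_mutated=0.0, n_samples=20,
                n_ighv_mutated=10, n_ighv_unmutated=10, n_normal_b=0,
            )
            cohort = simulate_cohort(params)
            truth = cohort.truth.samples.set_index("sample")
            tbl = cohort.cohort.set_index("sample").join(truth[["global_rate"]])
            mut = tbl[tbl["ighv_status"] == "mutated"]
            rs.append(correlate(mut["adar_total"], mut["global_rate"])[0])
        assert abs(np.mean(rs)) < 0.25

    def test_survival_null_hr_one_gives_similar_groups(self):
        rng = np.random.default_rng(0)
        times, events, groups = simulate_survival(500, 500, 0.01, 1.0, 0.004, rng)
        from aluedit import km_logrank

        res = km_logrank(times, events, groups)
        assert 0.8 < res.hazard_ratio < 1.25

    def test_survival_hr_recovery_median_over_replicates(self):
        """HR 2 with 200/arm: the median Cox estimate over 30 replicates sits
        in [1.7, 2.4]."""
        from aluedit import km_logrank

        rng = np.random.default_rng(123)
        hrs = []
        for _ in range(30):
            times, events, groups = simulate_survival(200, 200, 0.0059, 2.0, 0.004, rng)
            hrs.append(km_logrank(times, events, groups).hazard_ratio)
        assert 1.7 < np.median(hrs) < 2.4

    def test_normal_b_have_no_survival_data(self, tiny_cohort):
        nb = tiny_cohort.cohort[tiny_cohort.cohort["sample_type"] == "normal_b"]
        assert nb["ttft_sampling_months"].isna().all()
        assert (nb["event"] == 0).all()
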