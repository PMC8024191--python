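"""Synthetic matched RNA/DNA cohort generator with known ground truth.

Emulates the statistical structure of a CLL editing study: a small genome
carrying inverted Alu repeat pairs and multi-exon genes; per-sample global
Alu editing rates on the scale of published Alu editing indices (~1.2-2.5%);
a panel of recurrently edited recoding sites whose per-cluster depth
profiles define planted patient clusters; ADAR expression correlated with
global editing in the IGHV-mutated subgroup only; homogeneous, high-editing
normal B-cell samples; and exponential time-to-first-treatment with a
configurable hazard ratio for cluster 1.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning: child streams are created in a fixed order (genome, truth, one per
sample's pileups, cohort table), so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import (
    GenomeRef,
    GeneModel,
    IntervalSet,
    write_bed,
    write_cohort_table,
    write_fasta,
    write_gtf,
    write_pileup_table,
)
from .recurrence_catalog import Site

_BASES = np.array(["A", "C", "G", "T"])
_STOPS = {"TAA", "TAG", "TGA"}


def default_site_profiles(n_sites: int = 19, n_clusters: int = 4) -> np.ndarray:
    """Per-cluster mean editing levels for the recoding panel.

    Cluster 1 mimics the poor-prognosis pattern: one dominant high site,
    one intermediate site, everything else near zero.  Cluster 2 is
    uniformly intermediate, cluster 3 edits the first half of the panel,
    cluster 4 the second half at low-moderate levels.
    """
    if n_clusters != 4:
        raise ValueError("default profiles are defined for 4 clusters")
    p = np.zeros((4, n_sites))
    p[0, :] = 0.02
    p[0, 0] = 0.60
    if n_sites > 1:
        p[0, 1] = 0.30
    p[1, :] = 0.35
    p[2, :] = 0.05
    p[2, 2 : min(10, n_sites)] = 0.50
    p[3, :] = 0.10
    p[3, min(10, n_sites) :] = 0.30
    return p


def normal_b_profile(n_sites: int = 19) -> np.ndarray:
    """Homogeneous alternating high/low profile for normal B-cell samples."""
    p = np.where(np.arange(n_sites) % 2 == 0, 0.55, 0.15)
    return p.astype(float)


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic cohort.

    Defaults mirror the published cohort structure: 45 CLL patients
    (19 IGHV-mutated, 21 unmutated, 5 unknown), 9 normal B-cell samples,
    a 19-site recoding panel over 14 genes with one 4-site gene, global
    Alu editing rates spanning the printed AEI range, and an exponential
    TTFT model with hazard ratio 2 for cluster 1.
    """

    n_samples: int = 45
    n_ighv_mutated: int = 19
    n_ighv_unmutated: int = 21
    n_normal_b: int = 9
    n_contigs: int = 3
    contig_length: int = 26_000
    n_alu_pairs: int = 56
    alu_length: int = 300
    alu_rate_low: float = 0.012  # per-sample global editing rate ~ AEI/100
    alu_rate_high: float = 0.0245
    normal_rate_mean: float = 0.022
    normal_rate_sd: float = 0.001
    alu_fraction: float = 0.99  # fraction of planted A>I events inside Alu
    n_genes: int = 14
    n_recoding_sites: int = 19
    cds_exons: int = 3
    cds_exon_length: int = 150
    utr_length: int = 60
    intron_length: int = 120
    n_clusters: int = 4
    cluster_proportions: tuple[float, ...] = (0.2, 0.3, 0.25, 0.25)
    site_profiles: np.ndarray | None = field(default=None, compare=False)
    profile_sd: float = 0.05
    normal_profile_sd: float = 0.01
    adar_corr_mutated: float = 0.8
    adar_corr_unmutated: float = 0.0
    dna_coverage: float = 30.0
    rna_coverage: float = 50.0
    error_rate: float = 0.001  # per-base sequencing error, uniform substitutions
    n_het_sites: int = 25
    background_level_low: float = 0.005
    background_level_high: float = 0.05
    baseline_hazard: float = 0.0059  # per month; median TTFT ~ 117 months
    cluster_hazard_ratio: float = 2.0
    censoring_rate: float = 0.004  # exponential censoring, per month
    sampling_lag_max: float = 60.0  # months between diagnosis and sampling
    motif_bias: float = 2.0  # preference for +1 G / against -1 G at planted sites
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alu_rate_low", "alu_rate_high", "alu_fraction", "error_rate",
                     "background_level_low", "background_level_high"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dna_coverage < 1 or self.rna_coverage < 1:
            raise ValueError("coverages must be >= 1")
        if self.cluster_hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.n_ighv_mutated + self.n_ighv_unmutated > self.n_samples:
            raise ValueError("IGHV group counts exceed n_samples")
        if abs(sum(self.cluster_proportions) - 1) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        if (self.cds_exons * self.cds_exon_length) % 3 != 0:
            raise ValueError("total CDS length must be divisible by 3")

    def profiles(self) -> np.ndarray:
        if self.site_profiles is not None:
            p = np.asarray(self.site_profiles, dtype=float)
            if p.shape != (self.n_clusters, self.n_recoding_sites):
                raise ValueError("site_profiles shape mismatch")
            return p
        return default_site_profiles(self.n_recoding_sites, self.n_clusters)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    alu_sites: pd.DataFrame  # contig, pos, strand — every Alu adenosine
    recoding_sites: pd.DataFrame  # contig, pos, strand, gene_id, label
    background_sites: pd.DataFrame  # contig, pos, strand, level
    het_sites: pd.DataFrame  # contig, pos, ref, alt
    samples: pd.DataFrame  # sample, sample_type, ighv_status, cluster, global_rate
    site_levels: pd.DataFrame  # index: recoding site keys; columns: samples

    def panel(self) -> list[Site]:
        return [
            Site(contig=r.contig, pos=int(r.pos), strand=r.strand, label=r.label)
            for r in self.recoding_sites.itertuples()
        ]


@dataclass
class SyntheticCohort:
    params: SimParams
    genome: GenomeRef
    alu: IntervalSet
    genes: list[GeneModel]
    truth: GroundTruth
    pileups: pd.DataFrame  # all samples, DNA+RNA, 0-based
    cohort: pd.DataFrame


# ---------------------------------------------------------------------------
# Genome and annotations


def _random_seq(rng, length: int, probs=(0.25, 0.25, 0.25, 0.25)) -> np.ndarray:
    return rng.choice(_BASES, size=length, p=list(probs))


def _random_cds(rng, length: int) -> np.ndarray:
    """Random coding sequence without internal stop codons."""
    assert length % 3 == 0
    codons = []
    while len(codons) * 3 < length:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return np.array(list("".join(codons)), dtype="<U1")


def simulate_genome_and_annotations(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[GenomeRef, IntervalSet, list[GeneModel]]:
    """Simulate a genome with inverted Alu pairs and multi-exon genes.

    Alu pairs and genes are distributed round-robin over contigs and placed
    left to right with random gaps.  Raises when a contig cannot hold its
    share of features.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    spacer = 30
    pair_len = 2 * params.alu_length + spacer
    gene_len = (
        2 * params.utr_length
        + params.cds_exons * params.cds_exon_length
        + (params.cds_exons - 1) * params.intron_length
    )

    # round-robin feature assignment to contigs
    per_contig: list[list[str]] = [[] for _ in range(params.n_contigs)]
    for i in range(params.n_alu_pairs):
        per_contig[i % params.n_contigs].append("alu_pair")
    for i in range(params.n_genes):
        per_contig[i % params.n_contigs].append("gene")

    contigs: dict[str, str] = {}
    alu_intervals: list[tuple[str, int, int, str]] = []
    genes: list[GeneModel] = []
    gene_idx = 0
    for ci, features in enumerate(per_contig):
        name = f"chr{ci + 1}"
        seq = _random_seq(rng, params.contig_length)
        lengths = [pair_len if f == "alu_pair" else gene_len for f in features]
        slack = params.contig_length - sum(lengths)
        min_gap = 2
        n_gaps = len(features) + 1
        if slack < n_gaps * min_gap:
            raise ValueError(
                f"genome too short: contig {name} needs {sum(lengths) + n_gaps * min_gap} bp, "
                f"has {params.contig_length}"
            )
        extra = slack - n_gaps * min_gap
        w = rng.random(n_gaps)
        gaps = min_gap + np.floor(extra * w / w.sum()).astype(int)
        cursor = 0
        for feat, flen, gap in zip(features, lengths, gaps):
            cursor += int(gap)
            if feat == "alu_pair":
                body = _random_seq(rng, params.alu_length, probs=(0.32, 0.20, 0.20, 0.28))
                s1 = cursor
                seq[s1 : s1 + params.alu_length] = body
                rc = np.array(list(str(Seq("".join(body)).reverse_complement())))
                mut = rng.random(params.alu_length) < 0.05  # diverged second copy
                rc[mut] = rng.choice(_BASES, size=int(mut.sum()))
                s2 = s1 + params.alu_length + spacer
                seq[s2 : s2 + params.alu_length] = rc
                alu_intervals.append((name, s1, s1 + params.alu_length, "+"))
                alu_intervals.append((name, s2, s2 + params.alu_length, "-"))
            else:
                strand = str(rng.choice(["+", "-"]))
                cds_total = params.cds_exons * params.cds_exon_length
                coding = _random_cds(rng, cds_total)
                genomic_cds = coding if strand == "+" else np.array(
                    list(str(Seq("".join(coding)).reverse_complement()))
                )
                cds_ivs, utr_ivs = [], []
                pos = cursor
                utr_ivs.append((pos, pos + params.utr_length))
                pos += params.utr_length
                off = 0
                for e in range(params.cds_exons):
                    seq[pos : pos + params.cds_exon_length] = genomic_cds[
                        off : off + params.cds_exon_length
                    ]
                    cds_ivs.append((pos, pos + params.cds_exon_length))
                    off += params.cds_exon_length
                    pos += params.cds_exon_length
                    if e < params.cds_exons - 1:
                        pos += params.intron_length
                utr_ivs.append((pos, pos + params.utr_length))
                gene_idx += 1
                genes.append(
                    GeneModel(
                        gene_id=f"GENE{gene_idx:03d}",
                        contig=name,
                        strand=strand,
                        cds=tuple(cds_ivs),
                        utrs=tuple(utr_ivs),
                    )
                )
            cursor += flen
        contigs[name] = "".join(seq)
    return GenomeRef(contigs), IntervalSet(alu_intervals), genes


# ---------------------------------------------------------------------------
# Ground truth


def _site_counts_per_gene(n_sites: int, n_genes: int) -> list[int]:
    """Distribute panel sites over genes; one multi-site (4x) gene first."""
    if n_sites < n_genes:
        raise ValueError("need at least one site per gene")
    counts = [1] * n_genes
    extras = n_sites - n_genes
    take = min(3, extras)
    counts[0] += take
    extras -= take
    g = 1
    while extras > 0:
        counts[g % n_genes] += 1
        extras -= 1
        g += 1
    return counts


def _choose_recoding_sites(
    params: SimParams, genome: GenomeRef, genes: list[GeneModel], rng
) -> pd.DataFrame:
    counts = _site_counts_per_gene(params.n_recoding_sites, len(genes))
    rows = []
    for gene, want in zip(genes, counts):
        cds = gene.coding_sequence(genome)
        cand, weights = [], []
        for off in range(1, len(cds) - 1):
            if cds[off] != "A":
                continue
            start = off - off % 3
            codon = cds[start : start + 3]
            edited = codon[: off % 3] + "G" + codon[off % 3 + 1 :]
            aa0, aa1 = str(Seq(codon).translate()), str(Seq(edited).translate())
            if aa0 == aa1 or "*" in (aa0, aa1):
                continue  # plant strictly nonsynonymous recoding sites
            w = 1.0
            if cds[off + 1] == "G":
                w *= params.motif_bias
            if cds[off - 1] == "G":
                w /= params.motif_bias
            cand.append(off)
            weights.append(w)
        if len(cand) < want:
            raise ValueError(f"gene {gene.gene_id}: too few recoding candidates")
        w = np.array(weights) / sum(weights)
        chosen = rng.choice(len(cand), size=want, replace=False, p=w)
        for j, ci in enumerate(sorted(int(c) for c in chosen)):
            off = cand[ci]
            rows.append(
                {
                    "contig": gene.contig,
                    "pos": gene.cds_position(off),
                    "strand": gene.strand,
                    "gene_id": gene.gene_id,
                    "label": f"{gene.gene_id}_s{j + 1}",
                }
            )
    return pd.DataFrame(rows)


def _alu_adenosines(alu: IntervalSet, genome: GenomeRef) -> pd.DataFrame:
    frames = []
    for contig, s, e, strand in alu:
        arr = np.frombuffer(genome.slice(contig, s, e).encode(), dtype="S1")
        target = b"A" if strand == "+" else b"T"
        pos = s + np.flatnonzero(arr == target)
        if len(pos):
            frames.append(pd.DataFrame({"contig": contig, "pos": pos, "strand": strand}))
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(["contig", "pos"]).reset_index(drop=True)


def simulate_truth(
    params: SimParams,
    genome: GenomeRef,
    alu: IntervalSet,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> GroundTruth:
    """Plant editing sites, assign samples to groups, and draw true levels."""
    alu_sites = _alu_adenosines(alu, genome)
    recoding = _choose_recoding_sites(params, genome, genes, rng)
    taken = set(zip(recoding["contig"], recoding["pos"]))
    for c, p in zip(alu_sites["contig"], alu_sites["pos"]):
        taken.add((c, p))

    # non-Alu background A>I sites sized so the planted-event Alu fraction
    # matches params.alu_fraction
    n_target_nonalu = int(round(len(alu_sites) * (1 - params.alu_fraction) / params.alu_fraction))
    n_bg = max(0, n_target_nonalu - len(recoding))
    bg_rows = []
    contig_names = list(genome.contigs)
    guard = 0
    while len(bg_rows) < n_bg:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("failed to place background sites")
        contig = contig_names[int(rng.integers(len(contig_names)))]
        pos = int(rng.integers(genome.length(contig)))
        ref = genome.base(contig, pos)
        if ref not in ("A", "T") or (contig, pos) in taken or alu.contains(contig, pos):
            continue
        taken.add((contig, pos))
        bg_rows.append(
            {
                "contig": contig,
                "pos": pos,
                "strand": "+" if ref == "A" else "-",
                "level": float(
                    rng.uniform(params.background_level_low, params.background_level_high)
                ),
            }
        )
    background = pd.DataFrame(bg_rows, columns=["contig", "pos", "strand", "level"])

    # heterozygous DNA SNP sites inside gene spans (always covered by pileups)
    het_rows = []
    spans = [(g.contig, *g.span) for g in genes]
    guard = 0
    while len(het_rows) < params.n_het_sites:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("failed to place heterozygous sites")
        contig, s, e = spans[int(rng.integers(len(spans)))]
        pos = int(rng.integers(s, e))
        ref = genome.base(contig, pos)
        if ref == "N" or (contig, pos) in taken:
            continue
        taken.add((contig, pos))
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        het_rows.append({"contig": contig, "pos": pos, "ref": ref, "alt": alt})
    het = pd.DataFrame(het_rows, columns=["contig", "pos", "ref", "alt"])

    # samples: CLL with IGHV status and cluster labels, plus normal B cells
    n = params.n_samples
    ighv = np.array(
        ["mutated"] * params.n_ighv_mutated
        + ["unmutated"] * params.n_ighv_unmutated
        + ["unknown"] * (n - params.n_ighv_mutated - params.n_ighv_unmutated)
    )
    rng.shuffle(ighv)
    props = np.asarray(params.cluster_proportions)
    counts = np.floor(props * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(props * n - counts))] += 1
    clusters = np.repeat(np.arange(1, params.n_clusters + 1), counts)
    rng.shuffle(clusters)
    cll_ids = [f"S{i + 1:03d}" for i in range(n)]
    nb_ids = [f"NB{i + 1:02d}" for i in range(params.n_normal_b)]
    samples = pd.DataFrame(
        {
            "sample": cll_ids + nb_ids,
            "sample_type": ["CLL"] * n + ["normal_b"] * params.n_normal_b,
            "ighv_status": list(ighv) + ["unknown"] * params.n_normal_b,
            "cluster": list(clusters) + [0] * params.n_normal_b,
            "global_rate": list(rng.uniform(params.alu_rate_low, params.alu_rate_high, size=n))
            + list(
                np.clip(
                    rng.normal(params.normal_rate_mean, params.normal_rate_sd, params.n_normal_b),
                    0.0,
                    1.0,
                )
            ),
        }
    )

    profiles = params.profiles()
    nb_prof = normal_b_profile(params.n_recoding_sites)
    levels = np.zeros((params.n_recoding_sites, len(samples)))
    for j, row in enumerate(samples.itertuples()):
        if row.sample_type == "CLL":
            mean = profiles[row.cluster - 1]
            sd = params.profile_sd
        else:
            mean = nb_prof
            sd = params.normal_profile_sd
        levels[:, j] = np.clip(mean + rng.normal(0, sd, params.n_recoding_sites), 0.0, 1.0)
    keys = [f"{r.contig}:{r.pos + 1}" for r in recoding.itertuples()]
    site_levels = pd.DataFrame(levels, index=keys, columns=samples["sample"].tolist())

    return GroundTruth(
        alu_sites=alu_sites,
        recoding_sites=recoding,
        background_sites=background,
        het_sites=het,
        samples=samples,
        site_levels=site_levels,
    )


# ---------------------------------------------------------------------------
# Pileups


def _position_universe(
    params: SimParams,
    genome: GenomeRef,
    alu: IntervalSet,
    genes: list[GeneModel],
    truth: GroundTruth,
) -> pd.DataFrame:
    """All pileup positions with ref base, editable-strand and site class."""
    frames = []
    for contig, s, e, strand in alu:
        frames.append(pd.DataFrame({"contig": contig, "pos": np.arange(s, e)}))
    for g in genes:
        s, e = g.span
        frames.append(pd.DataFrame({"contig": g.contig, "pos": np.arange(s, e)}))
    frames.append(truth.background_sites[["contig", "pos"]])
    frames.append(truth.het_sites[["contig", "pos"]])
    univ = (
        pd.concat([f for f in frames if len(f)], ignore_index=True)
        .astype({"pos": int})
        .drop_duplicates(["contig", "pos"])
        .sort_values(["contig", "pos"])
        .reset_index(drop=True)
    )
    refs = []
    for contig, grp in univ.groupby("contig", sort=False):
        arr = np.frombuffer(genome.contigs[contig].encode(), dtype="S1")
        refs.append(
            pd.Series(arr[grp["pos"].to_numpy()].astype("U1"), index=grp.index)
        )
    univ["ref"] = pd.concat(refs).sort_index()

    univ["site_kind"] = "none"  # none | alu | recoding | background | het
    univ["strand"] = "+"
    univ["site_idx"] = -1

    def _mark(df: pd.DataFrame, kind: str) -> None:
        key = univ.set_index(["contig", "pos"]).index
        target = pd.MultiIndex.from_frame(df[["contig", "pos"]])
        loc = key.get_indexer(target)
        univ.loc[univ.index[loc], "site_kind"] = kind
        if "strand" in df.columns:
            univ.loc[univ.index[loc], "strand"] = df["strand"].to_numpy()
        univ.loc[univ.index[loc], "site_idx"] = np.arange(len(df))

    _mark(truth.alu_sites, "alu")
    _mark(truth.recoding_sites, "recoding")
    _mark(truth.background_sites, "background")
    _mark(truth.het_sites, "het")
    return univ


def _split_errors(rng, n_err: np.ndarray, ref: np.ndarray, counts: np.ndarray) -> None:
    """Distribute error reads uniformly over the three non-reference bases."""
    for b_idx, base in enumerate(_BASES):
        mask = ref == base
        if not mask.any():
            continue
        other = [i for i in range(4) if i != b_idx]
        split = rng.multinomial(n_err[mask], [1 / 3] * 3)
        for k, col in enumerate(other):
            counts[mask, col] += split[:, k]


def simulate_pileups(
    params: SimParams,
    genome: GenomeRef,
    alu: IntervalSet,
    genes: list[GeneModel],
    truth: GroundTruth,
    seed_seq: np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Draw DNA and RNA base counts for every sample over the target regions.

    DNA is homozygous reference apart from sequencing error (and the planted
    heterozygous SNPs); RNA draws edited reads Binomial(coverage, true level)
    onto G (plus-strand sites) or C (minus-strand sites).
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(params.seed)
    univ = _position_universe(params, genome, alu, genes, truth)
    n_pos = len(univ)
    ref = univ["ref"].to_numpy()
    strand = univ["strand"].to_numpy()
    kind = univ["site_kind"].to_numpy()
    site_idx = univ["site_idx"].to_numpy()
    ref_idx = np.searchsorted(_BASES, ref)
    edited_col = np.where(strand == "+", 2, 1)  # G for '+', C for '-'
    het_mask = kind == "het"
    het_alt_idx = np.zeros(n_pos, dtype=int)
    if het_mask.any():
        alts = truth.het_sites["alt"].to_numpy()
        het_alt_idx[het_mask] = np.searchsorted(_BASES, alts[site_idx[het_mask]])
    bg_levels = truth.background_sites["level"].to_numpy()
    key_order = list(truth.site_levels.index)
    rec_keys = [f"{r.contig}:{r.pos + 1}" for r in truth.recoding_sites.itertuples()]
    rec_row = np.array([key_order.index(k) for k in rec_keys])

    sample_seeds = seed_seq.spawn(len(truth.samples))
    out_frames = []
    for (row, child) in zip(truth.samples.itertuples(), sample_seeds):
        rng = np.random.default_rng(child)
        level = np.zeros(n_pos)
        level[kind == "alu"] = row.global_rate
        rmask = kind == "recoding"
        if rmask.any():
            per_site = truth.site_levels[row.sample].to_numpy()
            level[rmask] = per_site[rec_row[site_idx[rmask]]]
        bmask = kind == "background"
        level[bmask] = bg_levels[site_idx[bmask]]

        for modality, mean_cov in (("DNA", params.dna_coverage), ("RNA", params.rna_coverage)):
            cov = rng.poisson(mean_cov, n_pos)
            counts = np.zeros((n_pos, 4), dtype=np.int64)
            rows = np.arange(n_pos)
            if modality == "DNA":
                ref_reads = np.where(
                    het_mask, rng.binomial(cov, 0.5), cov
                )
                alt_reads = cov - ref_reads
                n_err = rng.binomial(ref_reads, params.error_rate)
                counts[rows, ref_idx] = ref_reads - n_err
                counts[rows, np.where(het_mask, het_alt_idx, ref_idx)] += alt_reads
                _split_errors(rng, n_err, ref, counts)
            else:
                edited = rng.binomial(cov, np.where(het_mask, 0.0, level))
                het_alt_reads = np.where(het_mask, rng.binomial(cov, 0.5), 0)
                base_reads = cov - edited - het_alt_reads
                n_err = rng.binomial(base_reads, params.error_rate)
                counts[rows, ref_idx] = base_reads - n_err
                counts[rows, edited_col] += edited
                counts[rows, het_alt_idx] += het_alt_reads
                _split_errors(rng, n_err, ref, counts)
            out_frames.append(
                pd.DataFrame(
                    {
                        "sample": row.sample,
                        "modality": modality,
                        "contig": univ["contig"].to_numpy(),
                        "pos": univ["pos"].to_numpy(),
                        "ref": ref,
                        "nA": counts[:, 0],
                        "nC": counts[:, 1],
                        "nG": counts[:, 2],
                        "nT": counts[:, 3],
                    }
                )
            )
    return pd.concat(out_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Clinical table


def simulate_survival(
    n_control: int,
    n_exposed: int,
    baseline_hazard: float,
    hazard_ratio: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponential event times with a hazard ratio for the exposed arm.

    Returns (times, events, groups) with groups 0/1; censoring is an
    independent exponential clock at ``censoring_rate``.
    """
    groups = np.r_[np.zeros(n_control, dtype=int), np.ones(n_exposed, dtype=int)]
    hazard = baseline_hazard * hazard_ratio**groups
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        t_cens = rng.exponential(1.0 / censoring_rate, size=len(groups))
    else:
        t_cens = np.full(len(groups), np.inf)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events, groups


def simulate_cohort_table(
    params: SimParams, truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical covariates, ADAR expression and survival for every sample.

    ADAR expression is constructed to correlate with the true global
    editing rate at the configured coefficient within each IGHV group of
    the CLL samples; TTFT-from-sampling is exponential with the cluster-1
    hazard multiplier, and TTFT-from-diagnosis adds a uniform
    diagnosis-to-sampling lag.  Normal B-cell samples carry no survival data.
    """
    df = truth.samples.copy()
    n = len(df)
    is_cll = (df["sample_type"] == "CLL").to_numpy()

    # ADAR expression correlated with editing within IGHV groups
    expr = np.zeros(n)
    for status, r in (
        ("mutated", params.adar_corr_mutated),
        ("unmutated", params.adar_corr_unmutated),
        ("unknown", 0.0),
    ):
        mask = (df["ighv_status"] == status).to_numpy() & is_cll
        if mask.sum() == 0:
            continue
        rate = df.loc[mask, "global_rate"].to_numpy()
        z = (rate - rate.mean()) / (rate.std() if rate.std() > 0 else 1.0)
        expr[mask] = r * z + np.sqrt(max(0.0, 1 - r**2)) * rng.normal(0, 1, mask.sum())
    expr[~is_cll] = rng.normal(0.8, 0.3, (~is_cll).sum())  # naive B: high editing machinery
    df["adar_total"] = 50 + 10 * expr
    df["adar_p110"] = 0.6 * df["adar_total"] + rng.normal(0, 1.5, n)
    df["adar_p150"] = 0.4 * df["adar_total"] + rng.normal(0, 1.5, n)
    unmut = (df["ighv_status"] == "unmutated").to_numpy()
    for i in range(1, 7):
        shift = 1.2 if i <= 3 else 0.0  # three cofactors differ by IGHV status
        df[f"cofactor_{i}"] = rng.normal(0, 1, n) + shift * unmut

    # FISH cytogenetics; del11q enriched in cluster 1
    cl1 = (df["cluster"] == 1).to_numpy()
    df["del11q"] = (rng.random(n) < np.where(cl1, 0.45, 0.12)) & is_cll
    df["del13q"] = (rng.random(n) < 0.55) & is_cll
    df["del17p"] = (rng.random(n) < 0.08) & is_cll
    df["trisomy12"] = (rng.random(n) < 0.13) & is_cll
    df["normal_karyotype"] = is_cll & ~(
        df["del11q"] | df["del13q"] | df["del17p"] | df["trisomy12"]
    )

    hazard = params.baseline_hazard * np.where(cl1, params.cluster_hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = (
        rng.exponential(1.0 / params.censoring_rate, n)
        if params.censoring_rate > 0
        else np.full(n, np.inf)
    )
    ttft = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    lag = rng.uniform(0, params.sampling_lag_max, n)
    df["ttft_sampling_months"] = np.where(is_cll, ttft, np.nan)
    df["ttft_diagnosis_months"] = np.where(is_cll, ttft + lag, np.nan)
    df["event"] = np.where(is_cll, event, 0)
    return df.drop(columns=["cluster", "global_rate"])


# ---------------------------------------------------------------------------
# Orchestration


def simulate_cohort(params: SimParams | None = None) -> SyntheticCohort:
    """Run the full generator: genome, truth, pileups and clinical table."""
    if params is None:
        params = SimParams()
    genome_seed, truth_seed, pileup_seed, cohort_seed = np.random.SeedSequence(
        params.seed
    ).spawn(4)
    genome, alu, genes = simulate_genome_and_annotations(
        params, np.random.default_rng(genome_seed)
    )
    truth = simulate_truth(params, genome, alu, genes, np.random.default_rng(truth_seed))
    pileups = simulate_pileups(params, genome, alu, genes, truth, seed_seq=pileup_seed)
    cohort = simulate_cohort_table(params, truth, np.random.default_rng(cohort_seed))
    return SyntheticCohort(
        params=params, genome=genome, alu=alu, genes=genes, truth=truth,
        pileups=pileups, cohort=cohort,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write every on-disk artefact the pipeline reads, plus ground truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": str(out / "genome.fa"),
        "alu_bed": str(out / "alu.bed"),
        "genes_gtf": str(out / "genes.gtf"),
        "cohort": str(out / "cohort.tsv"),
        "truth": str(out / "truth.json"),
        "pileup_dir": str(out / "pileups"),
    }
    write_fasta(cohort.genome, paths["genome"])
    write_bed(cohort.alu, paths["alu_bed"], name_prefix="alu")
    write_gtf(cohort.genes, paths["genes_gtf"])
    write_cohort_table(cohort.cohort, paths["cohort"])
    pdir = Path(paths["pileup_dir"])
    pdir.mkdir(exist_ok=True)
    for sample, grp in cohort.pileups.groupby("sample", sort=True):
        write_pileup_table(grp, pdir / f"{sample}.tsv")
    truth = cohort.truth
    blob = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cohort.params).items()
            if k != "site_profiles"
        },
        "alu_sites": truth.alu_sites.to_dict(orient="list"),
        "recoding_sites": truth.recoding_sites.to_dict(orient="list"),
        "background_sites": truth.background_sites.to_dict(orient="list"),
        "het_sites": truth.het_sites.to_dict(orient="list"),
        "samples": truth.samples.to_dict(orient="list"),
        "site_levels": {
            "index": list(truth.site_levels.index),
            "columns": list(truth.site_levels.columns),
            "values": truth.site_levels.to_numpy().tolist(),
        },
    }
    with open(paths["truth"], "w") as fh:
        json.dump(blob, fh, sort_keys=True)
    return paths
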