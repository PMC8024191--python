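"""Per-sample global editing metrics over Alu intervals.

Two statistics summarise a sample's global A-to-I activity:

* the number of *unique Alu editing sites* — Alu adenosines with evidence
  of editing above small read/frequency thresholds; and
* the *Alu editing index* (AEI) — the pooled fraction (in percent) of
  edited reads over all covered Alu adenosines.  Pooling raw read counts
  weights each position by its expression, so highly expressed Alu
  elements dominate the index.

On minus-strand Alu elements the edited adenosine sits on the transcribed
strand, so on the reference strand it appears as a T position whose edited
reads are C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .rdd_detection import pileup_frame

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import GenomeRef, IntervalSet


@dataclass(frozen=True)
class AEIResult:
    sample: str
    aei: float  # percent
    numerator: int  # total edited (G-equivalent) reads at Alu adenosines
    denominator: int  # total edited + unedited reads at Alu adenosines
    unique_alu_sites: int

    def __post_init__(self) -> None:
        if not 0 <= self.aei <= 100:
            raise ValueError("AEI must lie in [0, 100]")
        if self.numerator > self.denominator:
            raise ValueError("numerator exceeds denominator")


def alu_adenosine_positions(alu: "IntervalSet", genome: "GenomeRef") -> pd.DataFrame:
    """All strand-adjusted adenosine positions inside Alu intervals.

    Plus-strand intervals contribute reference-A positions, minus-strand
    intervals reference-T positions.  Returns columns contig/pos/strand,
    deduplicated on (contig, pos) keeping the first strand seen.
    """
    frames = []
    for contig, start, end, strand in alu:
        seq = np.frombuffer(genome.slice(contig, start, end).encode(), dtype="S1")
        target = b"A" if strand == "+" else b"T"
        pos = start + np.flatnonzero(seq == target)
        if len(pos):
            frames.append(pd.DataFrame({"contig": contig, "pos": pos, "strand": strand}))
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "strand"])
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(["contig", "pos"]).reset_index(drop=True)


def _strand_adjusted_counts(rna: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Join RNA pileup rows onto site positions; add edited/unedited counts."""
    merged = sites.merge(rna, on=["contig", "pos"], how="inner")
    plus = merged["strand"].to_numpy() == "+"
    merged["edited"] = np.where(plus, merged["nG"], merged["nC"])
    merged["unedited"] = np.where(plus, merged["nA"], merged["nT"])
    return merged


def compute_aei(
    rna,
    alu: "IntervalSet",
    genome: "GenomeRef",
    min_coverage: int = 5,
    unique_site_min_reads: int = 2,
    unique_site_min_freq: float = 0.01,
) -> AEIResult:
    """Compute the AEI and unique-site count for a single sample.

    Positions with fewer than ``min_coverage`` A+G-equivalent reads are
    excluded from both statistics.  Raises ValueError when no covered Alu
    adenosine remains (empty denominator).
    """
    rna_df = pileup_frame(rna)
    rna_df = rna_df[rna_df["modality"] == "RNA"]
    samples = rna_df["sample"].unique()
    if len(samples) != 1:
        raise ValueError(f"compute_aei expects exactly one sample, got {len(samples)}")
    sites = alu_adenosine_positions(alu, genome)
    merged = _strand_adjusted_counts(rna_df, sites)
    cov = merged["edited"] + merged["unedited"]
    merged = merged[cov >= min_coverage]
    if len(merged) == 0:
        raise ValueError("empty denominator: no covered Alu adenosine")
    num = int(merged["edited"].sum())
    den = int((merged["edited"] + merged["unedited"]).sum())
    freq = merged["edited"] / (merged["edited"] + merged["unedited"])
    unique = int(
        (
            (merged["edited"] >= unique_site_min_reads)
            & (freq >= unique_site_min_freq)
        ).sum()
    )
    return AEIResult(
        sample=str(samples[0]),
        aei=100.0 * num / den,
        numerator=num,
        denominator=den,
        unique_alu_sites=unique,
    )


def count_unique_sites(
    rna,
    alu: "IntervalSet",
    genome: "GenomeRef",
    min_coverage: int = 5,
    unique_site_min_reads: int = 2,
    unique_site_min_freq: float = 0.01,
) -> int:
    """Number of Alu adenosines with evidence of editing (single sample)."""
    return compute_aei(
        rna,
        alu,
        genome,
        min_coverage=min_coverage,
        unique_site_min_reads=unique_site_min_reads,
        unique_site_min_freq=unique_site_min_freq,
    ).unique_alu_sites


def aei_table(
    rna,
    alu: "IntervalSet",
    genome: "GenomeRef",
    min_coverage: int = 5,
    unique_site_min_reads: int = 2,
    unique_site_min_freq: float = 0.01,
) -> pd.DataFrame:
    """AEI results for every sample present in a multi-sample RNA pileup."""
    rna_df = pileup_frame(rna)
    rna_df = rna_df[rna_df["modality"] == "RNA"]
    rows = []
    for sample, grp in rna_df.groupby("sample", sort=True):
        res = compute_aei(
            grp,
            alu,
            genome,
            min_coverage=min_coverage,
            unique_site_min_reads=unique_site_min_reads,
            unique_site_min_freq=unique_site_min_freq,
        )
        rows.append(
            {
                "sample": res.sample,
                "aei": res.aei,
                "numerator": res.numerator,
                "denominator": res.denominator,
                "unique_alu_sites": res.unique_alu_sites,
            }
        )
    return pd.DataFrame(rows)
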