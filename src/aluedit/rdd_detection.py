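"""Calling RNA-DNA single-nucleotide differences (RDDs) from matched pileups.

An RDD is a position where the RNA-seq base composition differs from the
matched genomic DNA of the same sample.  After excluding genomically
non-homozygous sites, the dominant RNA variant base defines the call; A>G
changes on the transcribed strand are the signature of ADAR-mediated A-to-I
editing (inosine is read as guanosine by the sequencer).
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import IntervalSet, RunConfig

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_COUNT_COLS = ["nA", "nC", "nG", "nT"]


@dataclass(frozen=True)
class PileupRecord:
    """Base counts for one sample at one position in one modality."""

    sample: str
    modality: str  # "DNA" or "RNA"
    contig: str
    pos: int  # 0-based
    ref: str
    nA: int
    nC: int
    nG: int
    nT: int

    def __post_init__(self) -> None:
        if self.modality not in ("DNA", "RNA"):
            raise ValueError(f"invalid modality {self.modality!r}")
        if self.ref not in ("A", "C", "G", "T", "N"):
            raise ValueError(f"invalid reference base {self.ref!r}")
        if min(self.nA, self.nC, self.nG, self.nT) < 0:
            raise ValueError("negative base count")
        if self.pos < 0:
            raise ValueError("negative position")

    @property
    def depth(self) -> int:
        return self.nA + self.nC + self.nG + self.nT

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.nA, self.nC, self.nG, self.nT)


@dataclass
class RDDCall:
    """One called RNA-DNA difference for one sample."""

    sample: str
    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    change: str  # e.g. "A>G" on the reference strand
    dna_ref_frac: float
    rna_var_freq: float
    rna_depth: int
    dna_depth: int
    in_alu: bool | None = None
    strand_class: str | None = None  # "A>I" or "other" once a strand is known

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError("variant base equals reference base")
        if not (0 <= self.rna_var_freq <= 1 and 0 <= self.dna_ref_frac <= 1):
            raise ValueError("frequencies must lie in [0, 1]")


def pileup_frame(records: Iterable[PileupRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalise pileup input (record stream or DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        (r.sample, r.modality, r.contig, r.pos, r.ref, r.nA, r.nC, r.nG, r.nT)
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["sample", "modality", "contig", "pos", "ref", *_COUNT_COLS]
    )


def classify_change(ref: str, alt: str, strand: str | None = None) -> tuple[str, str | None]:
    """Return (reference-strand change class, strand-resolved class).

    The change class is one of the 12 ordered base pairs, e.g. ``"A>G"``.
    When a feature strand is given, the substitution is mapped onto the
    coding strand: A>G on '+' and T>C on '-' both resolve to ``"A>I"``,
    everything else to ``"other"``.
    """
    if ref not in BASES or alt not in BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref!r}>{alt!r}")
    change = f"{ref}>{alt}"
    if strand is None:
        return change, None
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    if strand == "+":
        coding = change
    else:
        coding = f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
    return change, "A>I" if coding == "A>G" else "other"


def call_rdds(
    dna: Iterable[PileupRecord] | pd.DataFrame,
    rna: Iterable[PileupRecord] | pd.DataFrame,
    config: "RunConfig | None" = None,
    summary: dict | None = None,
) -> list[RDDCall]:
    """Call RDDs from matched DNA/RNA pileups.

    A call is emitted at a site iff all of:

    * DNA depth >= ``min_dna_cov`` and DNA reference fraction >=
      ``homozygosity_frac`` (the site is genomically homozygous reference);
    * RNA depth >= ``min_rna_cov``;
    * the most frequent non-reference RNA base has >= ``min_var_reads``
      reads and frequency (variant reads / RNA depth) >= ``min_var_freq``.

    At most one call per site per sample; ties between variant bases are
    broken in the fixed order A < C < G < T.  Sites with reference base N
    are skipped silently and tallied in ``summary``.
    """
    if config is None:
        from .io_formats import RunConfig

        config = RunConfig()
    dna_df = pileup_frame(dna)
    rna_df = pileup_frame(rna)
    key = ["sample", "contig", "pos"]
    merged = dna_df.merge(rna_df, on=key, suffixes=("_d", "_r"))
    if summary is not None:
        summary["n_joined_sites"] = len(merged)
    if len(merged) == 0:
        if summary is not None:
            summary.update(n_skipped_ref_n=0, n_ref_mismatch=0, n_calls=0)
        return []

    mismatch = merged["ref_d"].to_numpy() != merged["ref_r"].to_numpy()
    if mismatch.any():
        row = merged.iloc[int(np.flatnonzero(mismatch)[0])]
        raise ValueError(
            "DNA/RNA reference mismatch at "
            f"{row['sample']} {row['contig']}:{row['pos']} "
            f"({row['ref_d']!r} vs {row['ref_r']!r})"
        )

    ref_n = merged["ref_d"].to_numpy() == "N"
    if summary is not None:
        summary["n_skipped_ref_n"] = int(ref_n.sum())
        summary["n_ref_mismatch"] = 0
    merged = merged[~ref_n]

    ref = merged["ref_d"].to_numpy()
    ref_idx = np.searchsorted(np.array(BASES), ref)
    dcounts = merged[[c + "_d" for c in _COUNT_COLS]].to_numpy(dtype=np.int64)
    rcounts = merged[[c + "_r" for c in _COUNT_COLS]].to_numpy(dtype=np.int64)
    n = len(merged)
    rows = np.arange(n)

    dna_depth = dcounts.sum(axis=1)
    rna_depth = rcounts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dna_ref_frac = np.where(dna_depth > 0, dcounts[rows, ref_idx] / dna_depth, 0.0)

    var_counts = rcounts.copy()
    var_counts[rows, ref_idx] = -1  # exclude the reference column from argmax
    alt_idx = var_counts.argmax(axis=1)  # ties -> lowest index -> A<C<G<T order
    var_reads = rcounts[rows, alt_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        var_freq = np.where(rna_depth > 0, var_reads / rna_depth, 0.0)

    keep = (
        (dna_depth >= config.min_dna_cov)
        & (dna_ref_frac >= config.homozygosity_frac)
        & (rna_depth >= config.min_rna_cov)
        & (var_reads >= config.min_var_reads)
        & (var_freq >= config.min_var_freq)
    )
    idx = np.flatnonzero(keep)
    base_arr = np.array(BASES)
    calls = [
        RDDCall(
            sample=merged["sample"].iat[i],
            contig=merged["contig"].iat[i],
            pos=int(merged["pos"].iat[i]),
            ref=ref[i],
            alt=str(base_arr[alt_idx[i]]),
            change=f"{ref[i]}>{base_arr[alt_idx[i]]}",
            dna_ref_frac=float(dna_ref_frac[i]),
            rna_var_freq=float(var_freq[i]),
            rna_depth=int(rna_depth[i]),
            dna_depth=int(dna_depth[i]),
        )
        for i in idx
    ]
    calls.sort(key=lambda c: (c.sample, c.contig, c.pos))
    if summary is not None:
        summary["n_calls"] = len(calls)
    return calls


def resolve_strand_classes(calls: list[RDDCall], features: "IntervalSet") -> list[RDDCall]:
    """Attach strand-resolved classes using the strand of the covering feature.

    A call inside a stranded feature (Alu element or gene span) gets
    ``strand_class`` "A>I" or "other"; calls outside any feature keep None.
    Sites covered by features on both strands resolve to "A>I" if either
    orientation yields A>G.
    """
    out = []
    for c in calls:
        strands = {s for *_se, s in features.overlapping(c.contig, c.pos)}
        if not strands:
            out.append(replace(c))
            continue
        resolved = [classify_change(c.ref, c.alt, s)[1] for s in sorted(strands)]
        sc = "A>I" if "A>I" in resolved else "other"
        out.append(replace(c, strand_class=sc))
    return out


def flag_alu(calls: list[RDDCall], alu: "IntervalSet") -> list[RDDCall]:
    """Set ``in_alu`` on each call (half-open interval semantics)."""
    return [replace(c, in_alu=alu.contains(c.contig, c.pos)) for c in calls]


def rdd_summary(calls: list[RDDCall]) -> pd.DataFrame:
    """Per-sample counts of calls by change class, split Alu vs non-Alu."""
    if not calls:
        return pd.DataFrame(columns=["sample", "change", "in_alu", "n"])
    df = pd.DataFrame(
        {
            "sample": [c.sample for c in calls],
            "change": [c.change for c in calls],
            "in_alu": [bool(c.in_alu) for c in calls],
        }
    )
    out = df.value_counts(["sample", "change", "in_alu"]).rename("n").reset_index()
    return out.sort_values(["sample", "change", "in_alu"]).reset_index(drop=True)
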