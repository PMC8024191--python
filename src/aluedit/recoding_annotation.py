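"""Feature and codon-level annotation of A-to-I editing sites.

Classifies each site by genomic feature (CDS > UTR > intron > intergenic
precedence), reconstructs the affected codon on the coding strand to decide
the amino-acid consequence of the A-to-G change, and profiles the sequence
context at the -1/+1 neighbours of the edited adenosine.  ADAR prefers a
depleted G immediately 5' of the target adenosine and an enriched G
immediately 3' of it, so the context profile is the standard sanity check
that a site catalog looks like genuine deaminase activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .rdd_detection import _COMPLEMENT, RDDCall

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import GeneModel, GenomeRef

FEATURE_CLASSES = ("exonic-CDS", "UTR", "intronic", "intergenic")
CONSEQUENCES = ("synonymous", "nonsynonymous", "stop-affecting", "not-applicable")


@dataclass(frozen=True)
class AnnotatedSite:
    contig: str
    pos: int  # 0-based
    gene_id: str | None
    feature_class: str  # exonic-CDS | UTR | intronic | intergenic
    consequence: str  # synonymous | nonsynonymous | stop-affecting | not-applicable
    ref_aa: str | None = None
    alt_aa: str | None = None
    context_m1: str | None = None  # base at -1 on the coding strand
    context_p1: str | None = None  # base at +1 on the coding strand
    strand: str | None = None  # coding strand used for context
    additional_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"invalid feature class {self.feature_class!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"invalid consequence {self.consequence!r}")
        if self.feature_class != "exonic-CDS" and self.consequence != "not-applicable":
            raise ValueError("codon consequence only applies to exonic-CDS sites")


@dataclass(frozen=True)
class ContextProfile:
    """Base composition at -1/+1 around edited adenosines vs background."""

    edited_freq: pd.DataFrame  # index (-1, +1), columns A/C/G/T, rows sum to 1
    background_freq: pd.DataFrame
    enrichment: pd.DataFrame  # edited / background frequency ratio
    p_values: pd.DataFrame  # two-sided binomial test per (position, base)
    n_edited: int
    n_background: int
    n_excluded_boundary: int


def _codon_consequence(
    gene: "GeneModel", genome: "GenomeRef", pos: int
) -> tuple[str, str, str]:
    """(consequence, ref_aa, alt_aa) for an A-to-I edit at CDS position `pos`."""
    offset = gene.cds_offset(pos)
    if offset is None:
        raise ValueError(f"position {pos} not in CDS of {gene.gene_id}")
    cds = gene.coding_sequence(genome)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS frame inconsistency in gene {gene.gene_id}")
    codon_start = offset - offset % 3
    codon = cds[codon_start : codon_start + 3]
    within = offset % 3
    ref_base = codon[within]
    # coding-strand substitution implied by A>I: A->G; other reference bases
    # get their literal coding-strand substitution (defensive, non-A>I calls)
    alt_base = "G" if ref_base == "A" else ref_base
    edited = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(edited).translate())
    if ref_aa == alt_aa:
        cons = "synonymous"
    elif "*" in (ref_aa, alt_aa):
        cons = "stop-affecting"
    else:
        cons = "nonsynonymous"
    return cons, ref_aa, alt_aa


def _context(genome: "GenomeRef", contig: str, pos: int, strand: str) -> tuple[str | None, str | None]:
    """(-1, +1) neighbour bases on the coding strand; None at contig edges."""
    length = genome.length(contig)
    left = genome.base(contig, pos - 1) if pos - 1 >= 0 else None
    right = genome.base(contig, pos + 1) if pos + 1 < length else None
    if strand == "+":
        return left, right
    m1 = _COMPLEMENT.get(right) if right else None
    p1 = _COMPLEMENT.get(left) if left else None
    return m1, p1


def annotate_site(
    call: "RDDCall | tuple[str, int]",
    genes: list["GeneModel"],
    genome: "GenomeRef",
) -> AnnotatedSite:
    """Annotate one site by feature class and codon-level consequence.

    Overlapping features resolve by precedence CDS > UTR > intron >
    intergenic.  When several genes' CDS contain the site, the
    lexicographically first gene provides the reported consequence and the
    rest are listed in ``additional_gene_ids``.  Intergenic sites use the
    reference strand for context extraction.
    """
    if isinstance(call, RDDCall):
        contig, pos = call.contig, call.pos
    else:
        contig, pos = call
    if contig not in genome.contigs:
        raise KeyError(f"unknown contig {contig!r}")

    cds_hits, utr_hits, intron_hits = [], [], []
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.contig != contig:
            continue
        if any(s <= pos < e for s, e in g.cds):
            cds_hits.append(g)
        elif any(s <= pos < e for s, e in g.utrs):
            utr_hits.append(g)
        else:
            span = g.span
            if span[0] <= pos < span[1]:
                intron_hits.append(g)

    if cds_hits:
        gene = cds_hits[0]
        cons, ref_aa, alt_aa = _codon_consequence(gene, genome, pos)
        m1, p1 = _context(genome, contig, pos, gene.strand)
        return AnnotatedSite(
            contig=contig,
            pos=pos,
            gene_id=gene.gene_id,
            feature_class="exonic-CDS",
            consequence=cons,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            context_m1=m1,
            context_p1=p1,
            strand=gene.strand,
            additional_gene_ids=tuple(g.gene_id for g in cds_hits[1:]),
        )
    for hits, fclass in ((utr_hits, "UTR"), (intron_hits, "intronic")):
        if hits:
            gene = hits[0]
            m1, p1 = _context(genome, contig, pos, gene.strand)
            return AnnotatedSite(
                contig=contig,
                pos=pos,
                gene_id=gene.gene_id,
                feature_class=fclass,
                consequence="not-applicable",
                context_m1=m1,
                context_p1=p1,
                strand=gene.strand,
                additional_gene_ids=tuple(g.gene_id for g in hits[1:]),
            )
    m1, p1 = _context(genome, contig, pos, "+")
    return AnnotatedSite(
        contig=contig,
        pos=pos,
        gene_id=None,
        feature_class="intergenic",
        consequence="not-applicable",
        context_m1=m1,
        context_p1=p1,
        strand="+",
    )


def summarize_consequences(sites: list[AnnotatedSite]) -> pd.DataFrame:
    """Counts and percentages per feature class and, within CDS, per consequence.

    Percentages are count/total x 100 to one decimal.  Feature-class rows
    are percentages of all sites; consequence rows are percentages of
    exonic-CDS sites ("amino-acid changing" pools nonsynonymous with
    stop-affecting).  Empty input yields an empty table.
    """
    cols = ["category", "label", "count", "percent"]
    if not sites:
        return pd.DataFrame(columns=cols)
    total = len(sites)
    fc = pd.Series([s.feature_class for s in sites])
    rows = []
    for label in FEATURE_CLASSES:
        n = int((fc == label).sum())
        rows.append(("feature", label, n, round(100.0 * n / total, 1)))
    exonic = [s for s in sites if s.feature_class == "exonic-CDS"]
    n_ex = len(exonic)
    if n_ex:
        cons = pd.Series([s.consequence for s in exonic])
        for label in ("synonymous", "nonsynonymous", "stop-affecting"):
            n = int((cons == label).sum())
            rows.append(("consequence", label, n, round(100.0 * n / n_ex, 1)))
        n_change = int(cons.isin(["nonsynonymous", "stop-affecting"]).sum())
        rows.append(
            ("consequence", "amino-acid-changing", n_change, round(100.0 * n_change / n_ex, 1))
        )
    return pd.DataFrame(rows, columns=cols)


def context_profile(
    sites: list[AnnotatedSite],
    genome: "GenomeRef",
    background: list[tuple[str, int, str]],
) -> ContextProfile:
    """Profile -1/+1 base composition of edited sites against a background.

    ``background`` lists (contig, pos, strand) of covered adenosine
    positions (coding strand).  Sites or background positions lacking a
    -1 or +1 neighbour (contig boundary) are excluded and counted.
    """
    if not sites:
        raise ValueError("context_profile requires at least one edited site")
    if not background:
        raise ValueError("context_profile requires a non-empty background")

    def _collect(entries) -> tuple[pd.DataFrame, int]:
        m1s, p1s, skipped = [], [], 0
        for contig, pos, strand in entries:
            m1, p1 = _context(genome, contig, pos, strand)
            if m1 is None or p1 is None:
                skipped += 1
                continue
            m1s.append(m1)
            p1s.append(p1)
        counts = pd.DataFrame(
            {
                "-1": pd.Series(m1s).value_counts().reindex(list("ACGT"), fill_value=0),
                "+1": pd.Series(p1s).value_counts().reindex(list("ACGT"), fill_value=0),
            }
        ).T
        return counts, skipped

    edited_counts, n_skip = _collect(
        [(s.contig, s.pos, s.strand or "+") for s in sites]
    )
    bg_counts, bg_skip = _collect(background)
    n_e = int(edited_counts.iloc[0].sum())
    n_b = int(bg_counts.iloc[0].sum())
    if n_e == 0 or n_b == 0:
        raise ValueError("all sites or background positions fell on contig boundaries")
    edited_freq = edited_counts / n_e
    bg_freq = bg_counts / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = edited_freq / bg_freq
    pvals = pd.DataFrame(index=edited_freq.index, columns=edited_freq.columns, dtype=float)
    for posn in edited_freq.index:
        for base in "ACGT":
            p0 = float(bg_freq.loc[posn, base])
            k = int(edited_counts.loc[posn, base])
            if 0 < p0 < 1:
                pvals.loc[posn, base] = stats.binomtest(k, n_e, p0).pvalue
            else:
                pvals.loc[posn, base] = 1.0 if (p0 == 1) == (k == n_e) else 0.0
    return ContextProfile(
        edited_freq=edited_freq,
        background_freq=bg_freq,
        enrichment=enrichment,
        p_values=pvals,
        n_edited=n_e,
        n_background=n_b,
        n_excluded_boundary=n_skip + bg_skip,
    )
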