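"""Reverse-complement transforms used by strand-invariance tests.

Maps a whole dataset (genome, intervals, gene models, pileups, positions)
through genome-wide reverse complementation with strand swap; the set of
strand-resolved A>I calls must be invariant under this transformation.
"""

import pandas as pd
from Bio.Seq import Seq

from aluedit import GeneModel, GenomeRef, IntervalSet


def rc_genome(genome: GenomeRef) -> GenomeRef:
    return GenomeRef(
        {name: str(Seq(seq).reverse_complement()) for name, seq in genome.contigs.items()}
    )


def rc_pos(genome: GenomeRef, contig: str, pos: int) -> int:
    return genome.length(contig) - 1 - pos


def rc_intervals(ivs: IntervalSet, genome: GenomeRef) -> IntervalSet:
    out = []
    for contig, s, e, strand in ivs:
        L = genome.length(contig)
        out.append((contig, L - e, L - s, "-" if strand == "+" else "+"))
    return IntervalSet(out)


def rc_genes(genes: list[GeneModel], genome: GenomeRef) -> list[GeneModel]:
    out = []
    for g in genes:
        L = genome.length(g.contig)
        out.append(
            GeneModel(
                gene_id=g.gene_id,
                contig=g.contig,
                strand="-" if g.strand == "+" else "+",
                cds=tuple(sorted((L - e, L - s) for s, e in g.cds)),
                utrs=tuple(sorted((L - e, L - s) for s, e in g.utrs)),
            )
        )
    return out


def rc_pileups(df: pd.DataFrame, genome: GenomeRef) -> pd.DataFrame:
    out = df.copy()
    lengths = out["contig"].map({c: genome.length(c) for c in genome.contigs})
    out["pos"] = lengths - 1 - out["pos"]
    out["ref"] = out["ref"].map({"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"})
    out[["nA", "nC", "nG", "nT"]] = out[["nT", "nG", "nC", "nA"]].to_numpy()
    return out
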