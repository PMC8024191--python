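"""Readers and writers for the on-disk formats the pipeline touches.

Formats: FASTA genomes, BED Alu/repeat intervals, a GTF subset for gene
models (gene/CDS/UTR features), base-count pileup TSVs, VCF 4.2 for RDD
calls, TSV cohort tables and YAML run configuration.

Coordinate conventions: everything is 0-based half-open internally.  BED is
native 0-based; pileup TSV and VCF positions are 1-based on disk and
converted at this boundary.
"""

from __future__ import annotations

import csv
import dataclasses
import io
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .rdd_detection import PileupRecord, RDDCall

_VALID_BASES = frozenset("ACGTN")
PILEUP_COLUMNS = ["sample", "modality", "contig", "pos", "ref", "nA", "nC", "nG", "nT"]


# ---------------------------------------------------------------------------
# Genome


@dataclass(frozen=True)
class GenomeRef:
    """Reference genome: contig name -> uppercase DNA sequence (A/C/G/T/N)."""

    contigs: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("GenomeRef requires at least one contig")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            if not set(seq) <= _VALID_BASES:
                bad = sorted(set(seq) - _VALID_BASES)
                raise ValueError(f"contig {name!r} contains invalid bases {bad}")

    def length(self, contig: str) -> int:
        return len(self._seq(contig))

    def base(self, contig: str, pos: int) -> str:
        seq = self._seq(contig)
        if not 0 <= pos < len(seq):
            raise IndexError(f"position {pos} outside contig {contig!r} (length {len(seq)})")
        return seq[pos]

    def slice(self, contig: str, start: int, end: int) -> str:
        seq = self._seq(contig)
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"slice [{start}, {end}) outside contig {contig!r} (length {len(seq)})"
            )
        return seq[start:end]

    def _seq(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None


def read_fasta(path) -> GenomeRef:
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return GenomeRef(contigs)


def write_fasta(genome: GenomeRef, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Intervals


@dataclass
class IntervalSet:
    """A set of stranded genomic intervals, 0-based half-open.

    Overlap queries run in O(log n) per lookup via an interval tree built
    lazily per contig.
    """

    intervals: list[tuple[str, int, int, str]]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for contig, start, end, strand in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {contig}:{start}-{end}")
            if strand not in ("+", "-"):
                raise ValueError(f"invalid strand {strand!r}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[str, int, int, str]]:
        return iter(self.intervals)

    def _tree(self, contig: str) -> IntervalTree:
        if contig not in self._trees:
            tree = IntervalTree()
            for c, s, e, strand in self.intervals:
                if c == contig:
                    tree.addi(s, e, strand)
            self._trees[contig] = tree
        return self._trees[contig]

    def overlapping(self, contig: str, pos: int) -> list[tuple[int, int, str]]:
        """Intervals containing `pos` (half-open: start <= pos < end)."""
        return sorted((iv.begin, iv.end, iv.data) for iv in self._tree(contig).at(pos))

    def contains(self, contig: str, pos: int) -> bool:
        return bool(self._tree(contig).at(pos))

    def contains_many(self, contigs: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership for parallel arrays of contigs/positions."""
        out = np.zeros(len(positions), dtype=bool)
        for contig in pd.unique(contigs):
            tree = self._tree(contig)
            mask = contigs == contig
            out[mask] = [bool(tree.at(int(p))) for p in positions[mask]]
        return out


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6; missing strand defaults to '+'."""
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            strand = fields[5] if len(fields) >= 6 else "+"
            rows.append((fields[0], int(fields[1]), int(fields[2]), strand))
    return IntervalSet(rows)


def write_bed(intervals: IntervalSet, path, name_prefix: str = "iv") -> None:
    with open(path, "w") as fh:
        for i, (contig, start, end, strand) in enumerate(intervals):
            fh.write(f"{contig}\t{start}\t{end}\t{name_prefix}{i}\t0\t{strand}\n")


# ---------------------------------------------------------------------------
# Gene models


@dataclass(frozen=True)
class GeneModel:
    """A gene with ordered, non-overlapping CDS intervals and UTRs.

    Intervals are 0-based half-open in genomic order regardless of strand;
    total CDS length must be divisible by 3.
    """

    gene_id: str
    contig: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    utrs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not self.cds:
            raise ValueError(f"{self.gene_id}: no CDS intervals")
        prev_end = -1
        for s, e in self.cds:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty CDS interval {s}-{e}")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or are unsorted")
            prev_end = e
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.cds] + [s for s, _ in self.utrs]
        ends = [e for _, e in self.cds] + [e for _, e in self.utrs]
        return min(starts), max(ends)

    def coding_sequence(self, genome: GenomeRef) -> str:
        """Spliced CDS on the coding strand (reverse-complemented for '-')."""
        s = "".join(genome.slice(self.contig, a, b) for a, b in self.cds)
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def cds_offset(self, pos: int) -> int | None:
        """Coding-strand offset of genomic position `pos`, or None if not in CDS."""
        off = 0
        for s, e in self.cds:
            if s <= pos < e:
                genomic = off + (pos - s)
                if self.strand == "+":
                    return genomic
                return self.cds_length - 1 - genomic
            off += e - s
        return None

    def cds_position(self, offset: int) -> int:
        """Genomic position of coding-strand offset `offset` (inverse of cds_offset)."""
        if not 0 <= offset < self.cds_length:
            raise IndexError(f"{self.gene_id}: CDS offset {offset} out of range")
        genomic = offset if self.strand == "+" else self.cds_length - 1 - offset
        for s, e in self.cds:
            if genomic < e - s:
                return s + genomic
            genomic -= e - s
        raise AssertionError("unreachable")


def read_gtf(path) -> list[GeneModel]:
    """Read the gene/CDS/UTR GTF subset into GeneModel objects."""
    cds: dict[str, list[tuple[int, int]]] = {}
    utr: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            contig, _src, feature, start1, end1, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "CDS", "UTR", "five_prime_utr", "three_prime_utr"):
                continue
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            iv = (int(start1) - 1, int(end1))  # GTF is 1-based closed
            if gid not in meta:
                meta[gid] = (contig, strand)
                order.append(gid)
            if feature == "CDS":
                cds.setdefault(gid, []).append(iv)
            elif feature != "gene":
                utr.setdefault(gid, []).append(iv)
    genes = []
    for gid in order:
        contig, strand = meta[gid]
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=contig,
                strand=strand,
                cds=tuple(sorted(cds.get(gid, []))),
                utrs=tuple(sorted(utr.get(gid, []))),
            )
        )
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    return None


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.contig}\taluedit\tgene\t{span[0] + 1}\t{span[1]}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.cds:
                fh.write(f"{g.contig}\taluedit\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{attrs}\n")
            for s, e in g.utrs:
                fh.write(f"{g.contig}\taluedit\tUTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# Pileups


def read_pileup(path) -> Iterator[PileupRecord]:
    """Stream pileup records from TSV; positions converted to 0-based.

    Expected header: sample, modality, contig, pos, ref, nA, nC, nG, nT.
    Malformed rows raise ValueError naming the line number.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != PILEUP_COLUMNS:
            raise ValueError(f"{path}: bad pileup header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                sample, modality, contig, pos, ref = row[0], row[1], row[2], int(row[3]), row[4]
                counts = tuple(int(x) for x in row[5:9])
                if len(row) != 9:
                    raise ValueError("wrong column count")
                yield PileupRecord(
                    sample=sample,
                    modality=modality,
                    contig=contig,
                    pos=pos - 1,
                    ref=ref,
                    nA=counts[0],
                    nC=counts[1],
                    nG=counts[2],
                    nT=counts[3],
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed pileup row: {exc}") from None


def read_pileup_table(path) -> pd.DataFrame:
    """Vectorised pileup reader; same validation, returns a 0-based DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "modality": str, "contig": str})
    if list(df.columns) != PILEUP_COLUMNS:
        raise ValueError(f"{path}: bad pileup header {list(df.columns)!r}")
    bad = ~df["modality"].isin(["DNA", "RNA"])
    if bad.any():
        raise ValueError(f"{path}: invalid modality at data row {int(np.flatnonzero(bad)[0]) + 1}")
    counts = df[["nA", "nC", "nG", "nT"]].to_numpy()
    if (counts < 0).any():
        raise ValueError(f"{path}: negative base count")
    if not df["ref"].isin(list("ACGTN")).all():
        raise ValueError(f"{path}: invalid reference base")
    df = df.copy()
    df["pos"] = df["pos"].astype(int) - 1
    if (df["pos"] < 0).any():
        raise ValueError(f"{path}: non-positive 1-based position")
    return df


def write_pileup_table(df: pd.DataFrame, path) -> None:
    """Write a 0-based in-memory pileup frame as the 1-based on-disk TSV."""
    out = df[PILEUP_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


_VCF_INFO = [
    ("SAMPLE", 1, "String", "Sample identifier"),
    ("CLASS", 1, "String", "RNA-DNA change class on the reference strand (e.g. A>G)"),
    ("STRANDCLASS", 1, "String", "Strand-resolved class: A>I or other (NA if strand unknown)"),
    ("RNAVF", 1, "String", "RNA variant frequency (variant reads / RNA depth)"),
    ("DNARF", 1, "String", "DNA reference-allele fraction"),
    ("DPRNA", 1, "Integer", "RNA depth at site"),
    ("DPDNA", 1, "Integer", "DNA depth at site"),
    ("ALU", 0, "Flag", "Site overlaps an Alu interval"),
]


def write_rdd_vcf(calls: list[RDDCall], path, genome: GenomeRef | None = None) -> None:
    """Write RDD calls as VCF 4.2; input must be sorted by (contig, position).

    Frequencies are stored as full-precision strings so the file round-trips
    losslessly through :func:`read_rdd_vcf`.
    """
    keys = [(c.contig, c.pos) for c in calls]
    if keys != sorted(keys):
        raise ValueError("calls must be sorted by (contig, position)")
    header = pysam.VariantHeader()
    contigs: list[str] = []
    if genome is not None:
        contigs = list(genome.contigs)
    else:
        for c in calls:
            if c.contig not in contigs:
                contigs.append(c.contig)
        contigs.sort()
    for name in contigs:
        if genome is not None:
            header.contigs.add(name, length=genome.length(name))
        else:
            header.contigs.add(name)
    for key, number, vtype, desc in _VCF_INFO:
        header.info.add(key, number, vtype, desc)
    vf = pysam.VariantFile(str(path), "w", header=header)
    try:
        for c in calls:
            rec = vf.new_record(
                contig=c.contig, start=c.pos, stop=c.pos + 1, alleles=(c.ref, c.alt)
            )
            rec.info["SAMPLE"] = c.sample
            rec.info["CLASS"] = c.change.replace(">", "_")
            rec.info["STRANDCLASS"] = (
                "NA" if c.strand_class is None else c.strand_class.replace(">", "_")
            )
            rec.info["RNAVF"] = repr(float(c.rna_var_freq))
            rec.info["DNARF"] = repr(float(c.dna_ref_frac))
            rec.info["DPRNA"] = int(c.rna_depth)
            rec.info["DPDNA"] = int(c.dna_depth)
            if c.in_alu:
                rec.info["ALU"] = True
            vf.write(rec)
    finally:
        vf.close()


def read_rdd_vcf(path) -> list[RDDCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = dict(rec.info)
            strand_class = info["STRANDCLASS"]
            calls.append(
                RDDCall(
                    sample=info["SAMPLE"],
                    contig=rec.contig,
                    pos=rec.start,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    change=info["CLASS"].replace("_", ">"),
                    dna_ref_frac=float(info["DNARF"]),
                    rna_var_freq=float(info["RNAVF"]),
                    rna_depth=int(info["DPRNA"]),
                    dna_depth=int(info["DPDNA"]),
                    in_alu=bool(info.get("ALU", False)),
                    strand_class=None if strand_class == "NA" else strand_class.replace("_", ">"),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Cohort table

COHORT_REQUIRED = [
    "sample",
    "sample_type",
    "ighv_status",
    "del11q",
    "del13q",
    "del17p",
    "trisomy12",
    "adar_total",
    "adar_p110",
    "adar_p150",
    "ttft_sampling_months",
    "ttft_diagnosis_months",
    "event",
]


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {missing}")
    if not df["ighv_status"].isin(["mutated", "unmutated", "unknown"]).all():
        raise ValueError(f"{path}: invalid ighv_status value")
    for col in ("ttft_sampling_months", "ttft_diagnosis_months"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"{path}: negative survival time in {col}")
    if not df["event"].dropna().isin([0, 1]).all():
        raise ValueError(f"{path}: event indicator outside {{0,1}}")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """All analysis thresholds in one place; every field is overridable.

    Defaults follow common RDD-calling practice; the pileup-level caller
    thresholds trade the simulated sequencing error rate against sensitivity.
    """

    min_dna_cov: int = 10
    homozygosity_frac: float = 0.95
    min_rna_cov: int = 10
    min_var_reads: int = 2
    min_var_freq: float = 0.05
    aei_min_coverage: int = 5
    unique_site_min_reads: int = 2
    unique_site_min_freq: float = 0.01
    matrix_min_cov: int = 10
    edited_min_freq: float = 0.01
    edited_min_reads: int = 2
    recurrence_k: int = 5
    max_missing_frac: float = 0.5
    n_clusters: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_dna_cov",
            "min_rna_cov",
            "min_var_reads",
            "aei_min_coverage",
            "unique_site_min_reads",
            "matrix_min_cov",
            "edited_min_reads",
            "recurrence_k",
            "n_clusters",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("homozygosity_frac", "min_var_freq", "unique_site_min_freq",
                     "edited_min_freq", "max_missing_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("call", data))

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        buf = io.StringIO()
        yaml.safe_dump({"call": dataclasses.asdict(self)}, buf, sort_keys=True)
        return buf.getvalue()
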