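"""Domain types and file I/O for sORF classification.

Sequence records pair a candidate open reading frame (start codon through
stop codon) with its upstream flanking sequence, which carries the
translation-initiation-site context.  Genomic coordinates are handled
0-based half-open internally; converters sit at the GFF3 boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_START_CODONS = frozenset({"ATG"})
VALID_BASES = frozenset("ACGT")

#: Annotation classes used by sORF repositories to describe the host
#: genomic region of a candidate (exon of an mRNA, intron, intergenic, ...).
ANNOTATION_CLASSES = (
    "exonic",
    "intronic",
    "intergenic",
    "lncRNA",
    "3UTR",
    "5UTR",
    "ensembl_sORF",
    "NMD",
    "TEC",
    "NSD",
    "pseudogene",
)

#: External coding-potential metrics consumed as pre-computed columns.
METRIC_NAMES = ("FLOSS", "ORFscore", "PhyloP", "PhastCon")


class ParseError(ValueError):
    """Malformed line in an annotation/interval file (carries line number)."""


class SchemaError(ValueError):
    """Tabular input violates the expected schema."""


@dataclass(frozen=True)
class SorfRecord:
    """One candidate sORF: upstream flank plus the ORF itself.

    ``flank`` is stored 5'->3' so its last character sits at position -1
    relative to the start codon; ``orf`` begins with the start codon and,
    for training records, ends with a stop codon.
    """

    id: str
    flank: str
    orf: str
    label: Optional[str] = None  # "coding" | "noncoding"
    annotation_class: Optional[str] = None

    @property
    def aa_length(self) -> int:
        """Peptide length in amino acids (stop codon not counted)."""
        n = len(self.orf) // 3 - 1
        return max(n, 0)

    @property
    def sequence(self) -> str:
        return self.flank + self.orf


@dataclass(frozen=True)
class GeneInterval:
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Genome sequences plus gene intervals (0-based half-open)."""

    sequences: dict[str, str]
    genes: list[GeneInterval] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if g.contig in self.sequences and g.end > len(self.sequences[g.contig]):
                raise ValueError(
                    f"gene interval {g} exceeds contig {g.contig} "
                    f"length {len(self.sequences[g.contig])}"
                )


@dataclass(frozen=True)
class Rejection:
    """One excluded input record with a machine-readable reason."""

    id: str
    reason: str


def _validate_record(
    rec_id: str,
    flank: str,
    orf: str,
    start_codons: frozenset[str],
    require_stop: bool,
    max_aa: Optional[int],
) -> Optional[str]:
    """Return a rejection reason, or None if the record is valid."""
    if not set(flank) <= VALID_BASES or not set(orf) <= VALID_BASES:
        return "ambiguous base"
    if len(orf) < 6:
        return "orf shorter than 6 nt"
    if len(orf) % 3 != 0:
        return "orf length not a multiple of 3"
    if orf[:3] not in start_codons:
        return f"orf does not begin with a start codon ({orf[:3]})"
    if require_stop and orf[-3:] not in STOP_CODONS:
        return f"orf does not end with a stop codon ({orf[-3:]})"
    if max_aa is not None and len(orf) // 3 - 1 > max_aa:
        return f"orf longer than {max_aa} aa"
    return None


def read_sorf_fasta(
    path,
    flank_length: int = 100,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    require_stop: bool = True,
    max_aa: Optional[int] = None,
    label: Optional[str] = None,
) -> tuple[list[SorfRecord], list[Rejection]]:
    """Read flank+ORF FASTA entries, validating each record.

    Each entry is the upstream flank (``flank_length`` nt) immediately
    followed by the ORF.  Records failing quality control (ambiguous
    bases, bad frame, missing start/stop codon, or — when ``max_aa`` is
    set — exceeding the sORF length cut-off) are excluded and reported,
    never silently fixed.  Lowercase (soft-masked) bases are uppercased.
    """
    start_codons = frozenset(s.upper() for s in start_codons)
    records: list[SorfRecord] = []
    rejections: list[Rejection] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if len(seq) < flank_length + 6:
            rejections.append(
                Rejection(entry.id, f"entry shorter than flank ({flank_length}) + 6 nt")
            )
            continue
        flank, orf = seq[:flank_length], seq[flank_length:]
        reason = _validate_record(
            entry.id, flank, orf, start_codons, require_stop, max_aa
        )
        if reason is not None:
            rejections.append(Rejection(entry.id, reason))
        else:
            records.append(SorfRecord(entry.id, flank, orf, label=label))
    return records, rejections


def write_sorf_fasta(records: Iterable[SorfRecord], path) -> None:
    """Write records as flank+ORF FASTA (inverse of :func:`read_sorf_fasta`)."""
    seqs = [
        SeqRecord(Seq(r.flank + r.orf), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_genome_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(sequences: dict[str, str], path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_gene_intervals(path, format: str = "BED") -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based
    closed, ``gene`` features only), normalized to the internal 0-based
    half-open convention."""
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown interval format {format!r}")
    intervals: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    contig, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = fields[5] if len(fields) > 5 else "+"
                else:
                    if len(fields) < 8:
                        raise ValueError("fewer than 8 GFF3 columns")
                    if fields[2] != "gene":
                        continue
                    contig = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if fields[6] in ("+", "-") else "+"
                intervals.append(GeneInterval(contig, start, end, strand))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_gene_intervals(intervals: Iterable[GeneInterval], path, format: str = "BED"):
    """Write intervals back out; GFF3 output restores 1-based closed
    coordinates (involutive with :func:`read_gene_intervals`)."""
    fmt = format.upper()
    with open(path, "w") as fh:
        for iv in intervals:
            if fmt == "BED":
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t.\t.\t{iv.strand}\n")
            elif fmt == "GFF3":
                fh.write(
                    f"{iv.contig}\t.\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\tID=gene\n"
                )
            else:
                raise ValueError(f"unknown interval format {format!r}")


@dataclass
class SorfTable:
    """Tabular sORF benchmark set: sequences, annotation classes and
    pre-computed external coding-potential metric scores.

    Missing metric values are NaN/None, never zero — absence of evidence
    is not a score of zero.
    """

    frame: pd.DataFrame  # columns: id, sequence, upstream, annotation_class, metrics...

    @property
    def metrics(self) -> list[str]:
        return [m for m in METRIC_NAMES if m in self.frame.columns]

    def __len__(self) -> int:
        return len(self.frame)

    def records(self, require_stop: bool = False) -> tuple[list[SorfRecord], list[Rejection]]:
        """Materialize rows as validated :class:`SorfRecord` objects."""
        records, rejections = [], []
        for row in self.frame.itertuples(index=False):
            flank = str(row.upstream).upper()
            orf = str(row.sequence).upper()
            reason = _validate_record(
                str(row.id), flank, orf, DEFAULT_START_CODONS, require_stop, None
            )
            if reason is not None:
                rejections.append(Rejection(str(row.id), reason))
            else:
                records.append(
                    SorfRecord(
                        str(row.id), flank, orf,
                        annotation_class=row.annotation_class,
                    )
                )
        return records, rejections


REQUIRED_TABLE_COLUMNS = ("id", "sequence", "upstream", "annotation_class")


def read_sorf_table(path) -> SorfTable:
    """Read a tab-delimited sORF benchmark table.

    Required columns: id, sequence, upstream, annotation_class.  Optional
    metric columns (FLOSS, ORFscore, PhyloP, PhastCon) are parsed as
    floats; unparsable or empty cells become NaN for that metric only.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    bad = set(df["annotation_class"].dropna()) - set(ANNOTATION_CLASSES)
    if bad:
        raise SchemaError(
            f"unknown annotation_class value(s): {', '.join(sorted(bad))}"
        )
    for metric in METRIC_NAMES:
        if metric in df.columns:
            df[metric] = pd.to_numeric(df[metric], errors="coerce")
    return SorfTable(df)


def write_sorf_table(table: SorfTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
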