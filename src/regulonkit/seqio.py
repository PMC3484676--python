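"""FASTA and annotation I/O helpers.

Genomes are held in memory as plain ``{chrom: sequence}`` dicts of uppercase
strings; the genomes this package works with (a handful of chromosome arms)
fit comfortably. FASTA reading/writing goes through Biopython.

Coordinates are 0-based half-open everywhere inside the package. BED output
uses the same convention; GFF3 output converts to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Genome = Dict[str, str]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a ``{name: uppercase sequence}`` dict."""
    genome: Genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(path: str | Path, records: Iterable[Tuple[str, str]]) -> None:
    seqrecs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    SeqIO.write(seqrecs, str(path), "fasta")


@dataclass(frozen=True)
class TSSRecord:
    """A gene's transcription start site: the strand-aware 5' end."""

    gene_id: str
    chrom: str
    tss: int  # 0-based
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"TSS coordinate must be >= 0, got {self.tss}")


TSSAnnotation = List[TSSRecord]


def _check_unique_gene_ids(records: Sequence[TSSRecord]) -> None:
    seen = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r} in annotation")
        seen.add(rec.gene_id)


def read_tss_bed(path: str | Path) -> TSSAnnotation:
    """Read a 6-column BED of TSS positions.

    The TSS is the strand-aware 5' end of the interval: ``start`` for '+'
    records, ``end - 1`` for '-' records. Single-base intervals therefore
    denote the TSS directly on either strand.
    """
    records: TSSAnnotation = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            start_i, end_i = int(start), int(end)
            tss = start_i if strand == "+" else end_i - 1
            records.append(TSSRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand))
    _check_unique_gene_ids(records)
    return records


def write_tss_bed(path: str | Path, annotation: Sequence[TSSRecord]) -> None:
    with open(path, "w") as fh:
        for rec in annotation:
            fh.write(f"{rec.chrom}\t{rec.tss}\t{rec.tss + 1}\t{rec.gene_id}\t0\t{rec.strand}\n")


def read_tss_gff3(path: str | Path, feature: str = "gene") -> TSSAnnotation:
    """Extract TSSs from ``gene`` features of a GFF3 file.

    GFF3 is 1-based inclusive: the TSS is ``start - 1`` (0-based) for '+'
    genes and ``end - 1`` for '-' genes. The gene id is taken from the
    ``ID=`` attribute.
    """
    records: TSSAnnotation = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != feature:
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: {feature} record lacks an ID attribute")
            tss = int(start) - 1 if strand == "+" else int(end) - 1
            records.append(TSSRecord(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
    _check_unique_gene_ids(records)
    return records


def write_tss_gff3(path: str | Path, annotation: Sequence[TSSRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in annotation:
            fh.write(
                f"{rec.chrom}\tregulonkit\tgene\t{rec.tss + 1}\t{rec.tss + 1}\t.\t"
                f"{rec.strand}\t.\tID={rec.gene_id}\n"
            )
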