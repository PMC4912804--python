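"""File format helpers: FASTA/FASTQ via Biopython, BED/GFF3/TSV writers.

Internal coordinates are 0-based half-open; BED and GFF3 follow their
own conventions (BED 0-based half-open, GFF3 1-based inclusive), and
human-readable TSV reports use 1-based inclusive coordinates.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .inserts import PrimerPair


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


def read_fastq(path):
    """Return (reads, read_len) where reads is [(id, seq, qual)]."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append((rec.id, str(rec.seq).upper(), qual))
    if not reads:
        raise FormatError(f"no reads in {path}")
    return reads, len(reads[0][1])


def write_fastq(readset, path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in readset.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_bed(intervals, path, chrom: str = "assembly") -> None:
    """intervals: iterable of (start, end, name)."""
    with open(path, "w") as fh:
        for start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_gff3(features, path, seqid: str = "assembly") -> None:
    """features: iterable of (start, end, type, name); 0-based half-open
    in, GFF3 1-based inclusive out."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for start, end, ftype, name in features:
            fh.write(
                f"{seqid}\tpfinish\t{ftype}\t{start + 1}\t{end}\t.\t+\t.\tName={name}\n"
            )


def write_tsv(rows: list[dict], path) -> None:
    if not rows:
        Path(path).write_text("")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_primers_tsv(path) -> list[PrimerPair]:
    """Primer table: name, forward, reverse columns (TSV with header)."""
    pairs = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "forward", "reverse"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError("primer TSV needs columns: name, forward, reverse")
        for row in reader:
            pairs.append(
                PrimerPair(
                    name=row["name"],
                    forward=row["forward"].upper(),
                    reverse=row["reverse"].upper(),
                )
            )
    return pairs
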