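"""Thin IO helpers around Biopython for the formats the toolkit speaks."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "read_reads",
    "write_fasta",
    "write_fastq",
    "write_tsv",
    "write_json",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return records


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA or FASTQ read set (format sniffed from the first byte)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), fmt)]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def write_fastq(path: str | Path, records: Iterable[tuple[str, str]],
                quality: int = 40) -> None:
    """Write reads as FASTQ with a uniform quality score."""
    recs = []
    for name, seq in records:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def write_tsv(path: str | Path, header: Sequence[str],
              rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
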