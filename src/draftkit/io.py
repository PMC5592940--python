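"""FASTA/FASTQ reading and writing (plain or gzip) via Biopython."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered mapping record id -> uppercase sequence."""
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    if isinstance(records, dict):
        records = records.items()
    with _open(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
            fh,
            "fasta",
        )


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercase) from a FASTQ file."""
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[str, str]]:
    r1 = list(iter_fastq(path1))
    r2 = list(iter_fastq(path2))
    if len(r1) != len(r2):
        raise ValueError(f"paired FASTQ length mismatch: {len(r1)} vs {len(r2)}")
    return list(zip(r1, r2))


def write_fastq_pairs(
    pairs: Iterable[tuple[str, str]],
    path1: str | Path,
    path2: str | Path,
    prefix: str = "pair",
    quality_char: str = "I",
) -> None:
    """Write mates to two FASTQ files with constant quality."""
    with _open(path1, "wt") as fh1, _open(path2, "wt") as fh2:
        for i, (r1, r2) in enumerate(pairs):
            fh1.write(f"@{prefix}_{i}/1\n{r1}\n+\n{quality_char * len(r1)}\n")
            fh2.write(f"@{prefix}_{i}/2\n{r2}\n+\n{quality_char * len(r2)}\n")
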