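"""Thin FASTA/FASTQ I/O helpers (plain or gzipped) built on Biopython."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(source) -> dict[str, str]:
    """Read a FASTA file (optionally .gz) or pass through a contig dict."""
    if isinstance(source, dict):
        return {k: str(v).upper() for k, v in source.items()}
    with _open_text(source) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"no sequences found in {source}")
    return records


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) triples from a FASTQ(.gz) file."""
    with _open_text(path) as fh:
        n = 0
        try:
            for rec in FastqGeneralIterator(fh):
                n += 1
                yield rec
        except ValueError as e:
            raise ValueError(f"malformed FASTQ near record {n + 1} in {path}: {e}") from e


class FastqWriter:
    """Append-style FASTQ(.gz) writer usable as a context manager."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fh = _open_text(self.path, "wt")
        self.count = 0

    def write(self, title: str, seq: str, qual: str) -> None:
        self._fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
        self.count += 1

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
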