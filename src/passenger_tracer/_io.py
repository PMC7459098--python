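"""File helpers: gzip-transparent text IO and deterministic gzip output.

Gzip output is written with a zeroed mtime header so that identical inputs
produce byte-identical ``.gz`` files across runs — the pipeline's
determinism contract extends to compressed outputs.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open plain or ``.gz`` text transparently (read side)."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="ascii")  # type: ignore[return-value]
    return open(path, mode, encoding="ascii")


def write_gzip_text(path: str | Path, text: str) -> None:
    """Write ``text`` gzip-compressed with mtime=0 (reproducible bytes)."""
    Path(path).write_bytes(gzip.compress(text.encode("ascii"), mtime=0))


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs from a FASTQ file (gzip OK).

    The read id is the title up to the first whitespace.
    """
    with open_text(path) as handle:
        for title, seq, _qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (record_id, uppercase sequence) tuples."""
    with open_text(path) as handle:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    lines: list[str] = []
    for name, seq in records:
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")
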