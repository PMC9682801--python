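"""Reading and writing of FASTA/FASTQ, with transparent gzip support.

Gzip is recognised by magic bytes rather than file extension, so ``.fastq``
and ``.fastq.gz`` inputs behave identically. Quality strings are read but
never interpreted: the algorithms use base calls only.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


class FastqParseError(ValueError):
    """Malformed FASTQ record; the message names the 1-based record index."""


def xopen(path: str | Path, mode: str = "rt") -> IO:
    """Open *path* as text, decompressing when the gzip magic bytes match."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences (upper-case) from a FASTQ file.

    Raises :class:`FastqParseError` naming the index of the offending record
    when the 4-line structure is violated.
    """
    n = 0
    with xopen(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"malformed FASTQ record {n + 1} in {path}: {exc}"
                ) from exc
            n += 1
            yield seq.upper()


def parse_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped, line-wrapped) multi-FASTA into an ordered dict."""
    with xopen(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def fasta_names(path: str | Path) -> list[str]:
    with xopen(path) as handle:
        return [rec.id for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(path: str | Path, contigs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as out:
        for name, seq in contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_fastq(path: str | Path, reads: Iterable[str], prefix: str = "read") -> None:
    """Write plain sequences as a minimal FASTQ (constant quality)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as out:
        for i, seq in enumerate(reads):
            out.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
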