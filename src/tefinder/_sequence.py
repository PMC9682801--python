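"""Low-level DNA string helpers shared across the package.

All sequences are plain upper-case ``str`` over the alphabet {A, C, G, T}.
Windows containing any other character (N and other ambiguity codes) are
skipped wherever k-mers are sliced, both from reads and from the reference.
"""

from __future__ import annotations

import re
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_RE = re.compile(r"^[ACGT]*$")
_CLEAN_RE = re.compile(r"[ACGT]+")


def is_valid_dna(seq: str) -> bool:
    """True if *seq* contains only A, C, G, T."""
    return _VALID_RE.match(seq) is not None


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string.

    Raises ``ValueError`` on any character outside {A, C, G, T}; ambiguity
    codes never reach this function because k-mer slicing drops them.
    """
    if not is_valid_dna(seq):
        raise ValueError(f"non-ACGT character in sequence {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def clean_segments(seq: str) -> Iterator[str]:
    """Yield the maximal runs of ACGT characters in *seq*.

    Slicing k-mers per segment is equivalent to sliding a window over the
    full sequence while skipping every window that touches an invalid base.
    """
    for m in _CLEAN_RE.finditer(seq):
        yield m.group(0)


def clean_segments_with_pos(seq: str) -> Iterator[tuple[int, str]]:
    """Like :func:`clean_segments` but yields (0-based start, segment)."""
    for m in _CLEAN_RE.finditer(seq):
        yield m.start(), m.group(0)


def iter_kmers(seq: str, k: int) -> Iterator[str]:
    """All k-length windows of *seq* (1-base step), skipping non-ACGT windows."""
    for segment in clean_segments(seq):
        for i in range(len(segment) - k + 1):
            yield segment[i : i + k]
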