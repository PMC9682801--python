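"""Disk-backable k-mer catalogs sliced from short reads.

Both algorithms start from the same primitive: every k-length window of
every read (1-base step), deduplicated, sorted lexicographically and
counted. Sample-specific k-mers — present in one sample's catalog and
absent from the other's — are enriched for sequences created by new TE
insertions, because a junction between genomic flank and TE end is novel
sequence that the other genome cannot contain.

Catalogs are strand-naive: reads are cataloged exactly as sequenced, and
reverse-complement collapsing happens only at reporting/verification time.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from bisect import bisect_left
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from ._sequence import iter_kmers

logger = logging.getLogger(__name__)

#: default number of distinct k-mers buffered in memory before spilling a
#: sorted run to disk; bounds peak memory independently of input size.
DEFAULT_CHUNK_SIZE = 4_000_000


class KmerCatalog:
    """Sorted, deduplicated fixed-length k-mers with per-sample counts.

    Internally a dict (k-mer -> count); the sorted view is materialised
    lazily and cached so that exact and prefix count queries are O(log n).
    Contents are independent of the order in which reads were supplied.
    """

    def __init__(self, k: int, counts: dict[str, int] | None = None,
                 source_sample: str | None = None):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.counts: dict[str, int] = counts if counts is not None else {}
        self.source_sample = source_sample
        self._sorted: list[str] | None = None
        for seq in self.counts:
            if len(seq) != self.k:
                raise ValueError(f"k-mer {seq!r} does not match k={self.k}")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.counts)

    def __contains__(self, seq: str) -> bool:
        return seq in self.counts

    def count(self, seq: str) -> int:
        """Exact-match occurrence count (0 when absent)."""
        return self.counts.get(seq, 0)

    @property
    def sorted_seqs(self) -> list[str]:
        if self._sorted is None:
            self._sorted = sorted(self.counts)
        return self._sorted

    @property
    def records(self) -> list[tuple[str, int]]:
        """Records sorted lexicographically by sequence, unique by sequence."""
        return [(s, self.counts[s]) for s in self.sorted_seqs]

    def count_prefix(self, prefix: str) -> int:
        """Summed count of all catalog k-mers starting with *prefix*.

        Used to count probes shorter than k (the non-insertion probe is
        40 - tsd_len bases long) against a k=40 catalog: each catalog entry
        beginning with the probe corresponds to a read window containing it.
        """
        if len(prefix) > self.k:
            return 0
        seqs = self.sorted_seqs
        lo = bisect_left(seqs, prefix)
        hi = bisect_left(seqs, prefix + "Z")  # 'Z' > 'T': closes the range
        return sum(self.counts[s] for s in seqs[lo:hi])

    # -- persistence ---------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Plain-text serialisation: "SEQ\\tCOUNT" per line, LF, sorted."""
        with open(path, "w", newline="\n") as out:
            for seq, n in self.records:
                out.write(f"{seq}\t{n}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int | None = None,
                 source_sample: str | None = None) -> "KmerCatalog":
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                seq, n = line.rstrip("\n").split("\t")
                counts[seq] = int(n)
        if k is None:
            k = len(next(iter(counts))) if counts else 1
        return cls(k, counts, source_sample)


def slice_kmers(reads: Iterable[str], k: int,
                source_sample: str | None = None,
                max_duplicate_reads: int | None = None) -> KmerCatalog:
    """Build a :class:`KmerCatalog` from an iterable of read sequences.

    Windows containing non-ACGT characters are skipped; reads shorter than
    *k* contribute nothing. ``max_duplicate_reads`` optionally caps how many
    identical whole-read copies are counted (a crude guard against PCR
    duplicates; disabled by default).
    """
    counts: Counter[str] = Counter()
    seen_reads: Counter[str] | None = Counter() if max_duplicate_reads else None
    n_reads = 0
    for read in reads:
        n_reads += 1
        if seen_reads is not None:
            seen_reads[read] += 1
            if seen_reads[read] > max_duplicate_reads:
                continue
        counts.update(iter_kmers(read, k))
    if n_reads and not counts:
        warnings.warn(f"no read yielded a {k}-mer; catalog is empty")
    return KmerCatalog(k, dict(counts), source_sample)


def specific_kmers(a: KmerCatalog, b: KmerCatalog) -> tuple[list[str], list[str]]:
    """Sample-specific sequences: (in a only, in b only), each sorted.

    Membership is decided by sequence alone; counts do not matter here.
    """
    if a.k != b.k:
        raise ValueError(f"catalog k mismatch: {a.k} != {b.k}")
    a_keys = a.counts.keys()
    b_keys = b.counts.keys()
    return sorted(a_keys - b_keys), sorted(b_keys - a_keys)


# -- external (disk-backed) sorting -----------------------------------------

def write_sorted_chunk(counter: Counter, scratch_dir: Path, index: int) -> Path:
    path = Path(scratch_dir) / f"chunk_{index:06d}.tsv"
    with open(path, "w", newline="\n") as out:
        for seq in sorted(counter):
            out.write(f"{seq}\t{counter[seq]}\n")
    return path


def _iter_chunk(path: Path) -> Iterator[tuple[str, int]]:
    with open(path) as fh:
        for line in fh:
            seq, n = line.rstrip("\n").split("\t")
            yield seq, int(n)


def merge_sorted_chunks(paths: Sequence[Path], k: int,
                        source_sample: str | None = None) -> KmerCatalog:
    """Merge sorted "SEQ\\tCOUNT" chunk files, summing counts across runs."""
    counts: dict[str, int] = {}
    merged = heapq.merge(*[_iter_chunk(p) for p in paths])
    last_seq: str | None = None
    last_count = 0
    for seq, n in merged:
        if seq == last_seq:
            last_count += n
        else:
            if last_seq is not None:
                counts[last_seq] = last_count
            last_seq, last_count = seq, n
    if last_seq is not None:
        counts[last_seq] = last_count
    return KmerCatalog(k, counts, source_sample)


def external_sort_merge(runs: Iterable[Iterable[str]], scratch_dir: str | Path,
                        chunk_size: int = DEFAULT_CHUNK_SIZE,
                        source_sample: str | None = None,
                        keep_chunks: bool = False) -> KmerCatalog:
    """Sort + count k-mer runs with memory bounded by *chunk_size*.

    Result is identical to an in-memory sort of the concatenated runs.
    Sorted chunk files are written under *scratch_dir*; they are removed on
    success unless *keep_chunks* (they are reusable inputs to
    :func:`merge_sorted_chunks`), and always removed on failure.
    """
    scratch_dir = Path(scratch_dir)
    scratch_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    buf: Counter[str] = Counter()
    k: int | None = None
    try:
        for run in runs:
            for kmer in run:
                if k is None:
                    k = len(kmer)
                buf[kmer] += 1
                if len(buf) >= chunk_size:
                    paths.append(write_sorted_chunk(buf, scratch_dir, len(paths)))
                    buf.clear()
        if buf or not paths:
            paths.append(write_sorted_chunk(buf, scratch_dir, len(paths)))
        catalog = merge_sorted_chunks(paths, k if k is not None else 1,
                                      source_sample)
    except BaseException:
        for p in paths:
            p.unlink(missing_ok=True)
        raise
    if not keep_chunks:
        for p in paths:
            p.unlink(missing_ok=True)
    logger.debug("external sort: %d chunks -> %d unique k-mers",
                 len(paths), len(catalog))
    return catalog
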