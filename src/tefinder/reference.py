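"""Exact-match 20-mer index of a reference genome, both strands.

The junction method needs a single primitive from the reference: given a
20-mer, where does it occur? A position is reported only when the match is
unique over both strands of all unmasked contigs; a 20-mer seen at two or
more sites (counting a forward and a reverse hit as two) is *ambiguous* and
excluded from junction pairing, and a 20-mer seen nowhere is *absent*.

Contig masking follows the config-file convention: the config lists one
contig name per line, in FASTA order; renaming a line to the literal "NOP"
drops that contig from the index.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from ._sequence import clean_segments_with_pos, is_valid_dna, reverse_complement

logger = logging.getLogger(__name__)

END_K = 20  # fixed flank / TE-end length used throughout
MASK_NAME = "NOP"

FORWARD = "+"
REVERSE = "-"

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
ABSENT = "absent"

_INDEX_VERSION = 1


@dataclass(frozen=True)
class GenomePosition:
    """1-based, fully-closed coordinate of a 20-mer's first base."""

    contig: str
    pos: int
    strand: str


@dataclass(frozen=True)
class LookupResult:
    status: str  # unique | ambiguous | absent
    position: Optional[GenomePosition] = None


@dataclass
class ReferenceConfig:
    """Pairs each FASTA record (in file order) with its effective name."""

    entries: list[tuple[str, str]]  # (original name, effective name)

    @property
    def active(self) -> list[str]:
        return [orig for orig, eff in self.entries if eff != MASK_NAME]

    def is_masked(self, original: str) -> bool:
        for orig, eff in self.entries:
            if orig == original:
                return eff == MASK_NAME
        raise KeyError(original)


def write_config(fasta_names: list[str], path: str | Path) -> Path:
    """Create the editable contig-list config; never overwrites."""
    path = Path(path)
    if path.exists():
        raise FileExistsError(f"config {path} already exists; not overwriting")
    path.write_text("".join(f"{name}\n" for name in fasta_names))
    return path


def read_config(path: str | Path, fasta_names: list[str]) -> ReferenceConfig:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) != len(fasta_names):
        raise ValueError(
            f"config {path} lists {len(lines)} contigs but the FASTA has "
            f"{len(fasta_names)}"
        )
    return ReferenceConfig(list(zip(fasta_names, lines)))


def full_config(fasta_names: list[str]) -> ReferenceConfig:
    """Config that keeps every contig (used when no file is supplied)."""
    return ReferenceConfig([(n, n) for n in fasta_names])


class ReferenceIndex:
    """Maps every 20-mer of the unmasked reference to its genomic sites.

    Reverse-strand occurrences are stored under the reverse complement of
    the forward 20-mer, so a single dict lookup answers both strands; the
    reported coordinate is always the forward-strand start of the site.
    """

    def __init__(self, contigs: dict[str, str], config: ReferenceConfig | None = None,
                 k: int = END_K, checksum: str | None = None):
        if config is None:
            config = full_config(list(contigs))
        names = [orig for orig, _ in config.entries]
        if list(contigs) != names:
            raise ValueError("config entries do not match FASTA records by order")
        self.k = k
        self.config = config
        self.contigs = contigs  # unmasked substring access for TSD checks
        self.checksum = checksum
        self._sites: dict[str, tuple[GenomePosition, ...]] = {}
        self._build()

    def _build(self) -> None:
        k = self.k
        sites: dict[str, list[GenomePosition]] = {}
        for orig, eff in self.config.entries:
            if eff == MASK_NAME:
                logger.info("contig %s masked (NOP); skipped", orig)
                continue
            seq = self.contigs[orig]
            if len(seq) < k:
                warnings.warn(f"contig {orig} shorter than {k}; skipped")
                continue
            for start, segment in clean_segments_with_pos(seq):
                for i in range(len(segment) - k + 1):
                    kmer = segment[i : i + k]
                    pos = start + i + 1  # 1-based
                    sites.setdefault(kmer, []).append(
                        GenomePosition(orig, pos, FORWARD))
                    sites.setdefault(reverse_complement(kmer), []).append(
                        GenomePosition(orig, pos, REVERSE))
        self._sites = {s: tuple(v) for s, v in sites.items()}
        logger.info("reference index: %d distinct %d-mers", len(self._sites), k)

    # -- queries -------------------------------------------------------------
    def matches(self, seq: str) -> tuple[GenomePosition, ...]:
        """All genomic sites of *seq* (both strands, forward coordinates)."""
        if len(seq) != self.k:
            raise ValueError(f"query length {len(seq)} != k={self.k}")
        if not is_valid_dna(seq):
            return ()
        return self._sites.get(seq, ())

    def lookup(self, seq: str) -> LookupResult:
        hits = self.matches(seq)
        if not hits:
            return LookupResult(ABSENT)
        if len(hits) > 1:
            return LookupResult(AMBIGUOUS)
        return LookupResult(UNIQUE, hits[0])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Reference substring, 1-based closed interval [start, end]."""
        return self.contigs[contig][start - 1 : end]

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with open(path, "wb") as out:
            pickle.dump(
                {"version": _INDEX_VERSION, "k": self.k, "checksum": self.checksum,
                 "contigs": self.contigs, "config": self.config,
                 "sites": self._sites},
                out, protocol=pickle.HIGHEST_PROTOCOL)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceIndex":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != _INDEX_VERSION:
            raise ValueError("incompatible index version")
        obj = cls.__new__(cls)
        obj.k = payload["k"]
        obj.checksum = payload["checksum"]
        obj.contigs = payload["contigs"]
        obj.config = payload["config"]
        obj._sites = payload["sites"]
        return obj


def reference_checksum(contigs: dict[str, str], config: ReferenceConfig) -> str:
    h = hashlib.md5()
    for name, seq in contigs.items():
        h.update(name.encode())
        h.update(hashlib.md5(seq.encode()).digest())
    for orig, eff in config.entries:
        h.update(f"{orig}->{eff};".encode())
    h.update(str(_INDEX_VERSION).encode())
    return h.hexdigest()


def build_index(contigs: dict[str, str], config: ReferenceConfig | None = None,
                cache_dir: str | Path | None = None) -> ReferenceIndex:
    """Build (or reload from *cache_dir*) the 20-mer index.

    The on-disk index is keyed by a checksum of the FASTA content and config,
    so editing either invalidates the cache automatically.
    """
    if config is None:
        config = full_config(list(contigs))
    checksum = reference_checksum(contigs, config)
    if cache_dir is not None:
        cache = Path(cache_dir) / f"refindex_{checksum}.pkl"
        if cache.exists():
            logger.info("reused reference index %s", cache.name)
            return ReferenceIndex.load(cache)
    index = ReferenceIndex(contigs, config, checksum=checksum)
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        index.save(Path(cache_dir) / f"refindex_{checksum}.pkl")
    return index
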