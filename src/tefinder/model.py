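"""Domain records shared by both detection algorithms.

Coordinates are 1-based and fully closed throughout (BED export converts at
the boundary). The *head junction* is the last base of the upstream flank
(i.e. the last base of the upstream TSD copy); the *tail junction* is the
first base of the downstream flank (first base of the downstream TSD copy),
so ``head_junction - tail_junction + 1 == len(tsd)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

from ._sequence import reverse_complement

SAMPLE_A = "A"
SAMPLE_B = "B"

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


@dataclass(frozen=True)
class Parameters:
    """Tunable thresholds; defaults are the published operating point."""

    tsd_size: Optional[int] = None          # fixed TSD length (TSD method only)
    specificity_threshold: float = 0.7      # fraction of sample-specific TSDs
    min_tsd_kinds: int = 2                  # distinct TSDs required per pair
    tsd_min: int = 3                        # junction method TSD length bounds
    tsd_max: int = 16
    min_junction_reads: int = 1             # carrier head/tail probe support
    min_noninsertion_other: int = 2         # wild-type support in the other sample
    max_other_junction_reads: int = 0       # junction probes must be carrier-specific
    mono_repeat: int = 10                   # simple-repeat caps (Alg 2 step 4)
    di_repeat: int = 9
    repeat_depth_factor: float = 3.0        # non-insertion count > factor x median
    end_k: int = 20                         # TE end / flank length


class ProbeCounts(NamedTuple):
    """Read support for one candidate locus in one sample."""

    upstream_head: int
    tail_downstream: int
    non_insertion: int


@dataclass
class HeadTailPair:
    """Candidate TE end pair with its per-sample TSD repertoires."""

    head: str
    tail: str
    tsds_a: frozenset[str] = frozenset()
    tsds_b: frozenset[str] = frozenset()
    cross_ref: Optional[tuple[str, str]] = None  # reverse-complement orientation

    @property
    def tsd_union(self) -> frozenset[str]:
        return self.tsds_a | self.tsds_b

    @property
    def specificity(self) -> float:
        """Fraction of TSDs seen in exactly one sample.

        Shared TSDs mark an element already resident at the same site in
        both genomes; a transposed element shows (mostly) disjoint TSD sets.
        """
        union = self.tsd_union
        if not union:
            return 0.0
        return len(self.tsds_a ^ self.tsds_b) / len(union)

    def reverse_complemented(self) -> "HeadTailPair":
        """The same pair read from the opposite strand."""
        return HeadTailPair(
            head=reverse_complement(self.tail),
            tail=reverse_complement(self.head),
            tsds_a=frozenset(reverse_complement(s) for s in self.tsds_a),
            tsds_b=frozenset(reverse_complement(s) for s in self.tsds_b),
        )

    def key(self) -> tuple[str, str]:
        return (self.head, self.tail)


def merge_reverse_complement_pairs(pairs: list[HeadTailPair]) -> list[HeadTailPair]:
    """Collapse pairs that are reverse complements of each other.

    Reads cover each junction on both strands, so a pair discovered as
    (head, tail) can reappear as (revcomp(tail), revcomp(head)) with
    reverse-complemented TSDs. The canonical orientation is the one with the
    lexicographically smaller head; the other orientation is recorded in
    ``cross_ref``. TSD sets of a merged mate are mapped back through the
    reverse complement before the union.
    """
    by_key: dict[tuple[str, str], HeadTailPair] = {}
    for p in pairs:
        rc = p.reverse_complemented()
        canonical, mate = (p, rc) if min(p.key(), rc.key()) == p.key() else (rc, p)
        key = canonical.key()
        if key in by_key:
            existing = by_key[key]
            by_key[key] = replace(
                existing,
                tsds_a=existing.tsds_a | canonical.tsds_a,
                tsds_b=existing.tsds_b | canonical.tsds_b,
            )
        else:
            by_key[key] = replace(canonical, cross_ref=mate.key())
    out = list(by_key.values())
    out.sort(key=lambda p: (-len(p.tsd_union), p.head, p.tail))
    return out


@dataclass
class InsertionCall:
    """One verified (or draft) insertion locus.

    ``contig``/junction coordinates are absent when no reference genome was
    supplied or when the flanks do not map uniquely (repetitive target).
    """

    head: str
    tail: str
    tsd: str
    upstream_flank: str
    downstream_flank: str
    carrier: str                                  # sample label A or B
    contig: Optional[str] = None
    head_junction: Optional[int] = None
    tail_junction: Optional[int] = None
    counts_a: Optional[ProbeCounts] = None
    counts_b: Optional[ProbeCounts] = None
    genotype: Optional[str] = None
    repetitive_flag: bool = False
    overlap_flag: bool = False
    te_length: Optional[int] = None
    tg_ca_flag: Optional[bool] = None

    @property
    def tsd_len(self) -> int:
        return len(self.tsd)

    @property
    def carrier_counts(self) -> Optional[ProbeCounts]:
        return self.counts_a if self.carrier == SAMPLE_A else self.counts_b

    @property
    def other_counts(self) -> Optional[ProbeCounts]:
        return self.counts_b if self.carrier == SAMPLE_A else self.counts_a


@dataclass
class TeAnnotation:
    """Where the resident copy of a detected element lives, and how big it is."""

    head: str
    tail: str
    head_sources: tuple = ()
    tail_sources: tuple = ()
    estimated_length: Optional[int] = None
    tg_ca_flag: bool = False


@dataclass
class TruthRecord:
    """Ground truth for one engineered insertion in the synthetic fixture."""

    te_id: str
    contig: str
    insertion_pos: int            # 1-based first duplicated base
    tsd: str
    zygosity: str                 # 'hom' | 'het'
    sample: str                   # carrier: A or B
    expected_head: str
    expected_tail: str
    expected_head_junction: int
    expected_tail_junction: int
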