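"""Read-level confirmation, genotyping and annotation of candidate insertions.

Every candidate locus is reduced to three probes and their read counts in
both samples:

* ``upstream_head``   — 20-base upstream flank (ending with the TSD) + 20-base
  TE head: a 40-mer that exists only in a genome carrying the insertion;
* ``tail_downstream`` — 20-base TE tail + 20-base downstream flank (starting
  with the TSD): the other junction 40-mer;
* ``non_insertion``   — the pre-insertion (wild-type) locus, i.e. the two
  flanks joined with the duplicated TSD copy removed (40 - tsd_len bases).

A true new transposition shows both junction probes in exactly one sample
(the carrier) and wild-type support in the other; the carrier's own
wild-type count separates heterozygous from homozygous insertions.
"""

from __future__ import annotations

import logging
import statistics
from typing import Optional

from ._sequence import reverse_complement
from .kmer import KmerCatalog
from .model import (HETEROZYGOUS, HOMOZYGOUS, InsertionCall, Parameters,
                    ProbeCounts, TeAnnotation)
from .reference import FORWARD, ReferenceIndex

logger = logging.getLogger(__name__)


class ProbeSet:
    """The three diagnostic sequences for one candidate insertion locus."""

    def __init__(self, upstream_head: str, tail_downstream: str,
                 non_insertion: str, tsd: str):
        self.upstream_head = upstream_head
        self.tail_downstream = tail_downstream
        self.non_insertion = non_insertion
        self.tsd = tsd


def build_probes(upstream_flank: str, downstream_flank: str,
                 head: str, tail: str, tsd: str) -> ProbeSet:
    """Assemble junction and wild-type probes for one locus.

    *upstream_flank* must end with the TSD and *downstream_flank* must start
    with it — both flanks include their TSD copy by construction, so a
    violation means the caller paired inconsistent sequences.
    """
    if tsd and not upstream_flank.endswith(tsd):
        raise ValueError(
            f"upstream flank {upstream_flank!r} does not end with TSD {tsd!r}")
    if tsd and not downstream_flank.startswith(tsd):
        raise ValueError(
            f"downstream flank {downstream_flank!r} does not start with TSD {tsd!r}")
    non_insertion = upstream_flank + downstream_flank[len(tsd):]
    return ProbeSet(
        upstream_head=upstream_flank + head,
        tail_downstream=tail + downstream_flank,
        non_insertion=non_insertion,
        tsd=tsd,
    )


def _count_exact_both(catalog: KmerCatalog, seq: str) -> int:
    rc = reverse_complement(seq)
    n = catalog.count(seq)
    if rc != seq:  # a palindromic probe is counted once per occurrence
        n += catalog.count(rc)
    return n


def _count_prefix_both(catalog: KmerCatalog, seq: str) -> int:
    rc = reverse_complement(seq)
    n = catalog.count_prefix(seq)
    if rc != seq:
        n += catalog.count_prefix(rc)
    return n


def count_probes(probes: ProbeSet, catalog_a: KmerCatalog,
                 catalog_b: KmerCatalog) -> tuple[ProbeCounts, ProbeCounts]:
    """Count each probe (both orientations) in both samples' 40-mer catalogs.

    The junction probes are exact 40-mers; the shorter non-insertion probe is
    counted as a catalog prefix, i.e. over read windows that start with it.
    """
    out = []
    for cat in (catalog_a, catalog_b):
        out.append(ProbeCounts(
            upstream_head=_count_exact_both(cat, probes.upstream_head),
            tail_downstream=_count_exact_both(cat, probes.tail_downstream),
            non_insertion=_count_prefix_both(cat, probes.non_insertion),
        ))
    return out[0], out[1]


def median_read_depth(catalog: KmerCatalog) -> float:
    """Median per-k-mer count: a robust stand-in for single-copy read depth."""
    if not catalog.counts:
        return 0.0
    return float(statistics.median(catalog.counts.values()))


def filter_and_genotype(call: InsertionCall, params: Parameters,
                        other_median_depth: float = 0.0) -> Optional[InsertionCall]:
    """Apply the true-transposition filter and assign a genotype.

    Accept only when the carrier shows both junctions, the other sample
    shows wild-type reads, and the junction probes are carrier-specific
    (already-resident elements appear in both samples and are rejected
    here). Heterozygous when the carrier retains wild-type reads. A
    wild-type count in the other sample far above the per-copy read depth
    marks a highly repetitive target locus.
    """
    carrier, other = call.carrier_counts, call.other_counts
    if carrier is None or other is None:
        raise ValueError("counts must be populated before genotyping")
    if carrier.upstream_head < params.min_junction_reads:
        return None
    if carrier.tail_downstream < params.min_junction_reads:
        return None
    if other.non_insertion < params.min_noninsertion_other:
        return None
    if other.upstream_head > params.max_other_junction_reads:
        return None
    if other.tail_downstream > params.max_other_junction_reads:
        return None
    call.genotype = HETEROZYGOUS if carrier.non_insertion >= 1 else HOMOZYGOUS
    if other_median_depth > 0:
        call.repetitive_flag = (
            other.non_insertion > params.repeat_depth_factor * other_median_depth)
    return call


def estimate_te_length(head_source_pos: int, tail_source_pos: Optional[int],
                       k: int = 20) -> Optional[int]:
    """Element size from the resident copy's end coordinates.

    The head 20-mer starts the element and the tail 20-mer ends it, so the
    span is ``tail_start + k - head_start``. Returns None when either end is
    unknown (e.g. the two ends map to different contigs).
    """
    if head_source_pos is None or tail_source_pos is None:
        return None
    return tail_source_pos + k - head_source_pos


def annotate_pair(head: str, tail: str,
                  index: Optional[ReferenceIndex]) -> TeAnnotation:
    """Locate the resident copy of a head/tail pair and estimate its size.

    All match sites are reported (an LTR element legitimately shows its end
    pair twice). The size is computed only when each end has exactly one
    forward-strand site and both lie on the same contig in head-before-tail
    order; TG..CA ends flag the retrotransposon terminal consensus.
    """
    ann = TeAnnotation(
        head=head, tail=tail,
        tg_ca_flag=head.startswith("TG") and tail.endswith("CA"),
    )
    if index is None:
        return ann
    ann.head_sources = index.matches(head)
    ann.tail_sources = index.matches(tail)
    head_fwd = [p for p in ann.head_sources if p.strand == FORWARD]
    tail_fwd = [p for p in ann.tail_sources if p.strand == FORWARD]
    if (len(head_fwd) == 1 and len(tail_fwd) == 1
            and head_fwd[0].contig == tail_fwd[0].contig
            and tail_fwd[0].pos >= head_fwd[0].pos):
        ann.estimated_length = estimate_te_length(
            head_fwd[0].pos, tail_fwd[0].pos, index.k)
        return ann
    # the pair may be reported in reverse-complement orientation, in which
    # case the resident copy matches on the reverse strand with the roles of
    # the two coordinates swapped
    head_rev = [p for p in ann.head_sources if p.strand != FORWARD]
    tail_rev = [p for p in ann.tail_sources if p.strand != FORWARD]
    if (len(head_rev) == 1 and len(tail_rev) == 1
            and head_rev[0].contig == tail_rev[0].contig
            and head_rev[0].pos >= tail_rev[0].pos):
        ann.estimated_length = estimate_te_length(
            tail_rev[0].pos, head_rev[0].pos, index.k)
    return ann


def flag_overlapping_calls(calls: list[InsertionCall]) -> None:
    """Mark calls whose TSD intervals overlap on the same contig.

    Shared bases between TE ends and target site can make one transposition
    surface as several shifted calls; they are flagged, never collapsed.
    """
    located = [c for c in calls if c.contig is not None]
    located.sort(key=lambda c: (c.contig, c.tail_junction, c.head_junction))
    for prev, cur in zip(located, located[1:]):
        if prev.contig == cur.contig and cur.tail_junction <= prev.head_junction:
            prev.overlap_flag = True
            cur.overlap_flag = True


def sort_calls(calls: list[InsertionCall],
               contig_order: list[str] | None = None) -> list[InsertionCall]:
    order = {name: i for i, name in enumerate(contig_order or [])}

    def keyfn(c: InsertionCall):
        return (
            0 if c.contig is not None else 1,
            order.get(c.contig, len(order)),
            c.contig or "",
            c.head_junction or 0,
            c.tsd, c.head, c.tail, c.carrier,
        )

    return sorted(calls, key=keyfn)
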