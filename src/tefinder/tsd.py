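"""TSD method: reference-free discovery of TE ends (Algorithm 1).

With a fixed TSD length *t*, every sample-specific (20+t)-mer is read in
two ways: as TSD followed by a TE head (first t bases + last 20), and as a
TE tail followed by TSD (first 20 + last t). A transposed element leaves
both junctions in its carrier genome, so a genuine head/tail pair is linked
by the *same* TSD string on both sides, at two or more distinct target
sites. Pairs whose TSD repertoires are largely private to one sample mark
new transpositions; shared repertoires mark elements resident in both
genomes and are filtered out. No reference genome is required; when one is
available the verified calls are additionally positioned by mapping their
flanks.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Iterable, NamedTuple, Optional, Sequence

from ._sequence import reverse_complement
from .junction import DetectionResult, head_junction_position
from .kmer import KmerCatalog, slice_kmers, specific_kmers
from .model import (HeadTailPair, InsertionCall, Parameters, SAMPLE_A, SAMPLE_B,
                    merge_reverse_complement_pairs)
from .reference import FORWARD, ReferenceIndex, UNIQUE
from .verify import (annotate_pair, build_probes, count_probes,
                     filter_and_genotype, flag_overlapping_calls,
                     median_read_depth, sort_calls)

logger = logging.getLogger(__name__)


class TsdHeadCandidate(NamedTuple):
    tsd: str
    head: str
    sample: str
    count: int


class TailTsdCandidate(NamedTuple):
    tail: str
    tsd: str
    sample: str
    count: int


def split_candidates(specific: Iterable[str], t: int, sample: str,
                     counts: KmerCatalog | None = None
                     ) -> tuple[list[TsdHeadCandidate], list[TailTsdCandidate]]:
    """Read every specific (20+t)-mer both as TSD+head and as tail+TSD.

    Both interpretations are emitted for every sequence; pairing decides
    which one survives. ``counts`` optionally supplies occurrence counts.
    """
    if t < 1:
        raise ValueError("tsd length must be >= 1")
    heads: list[TsdHeadCandidate] = []
    tails: list[TailTsdCandidate] = []
    for seq in specific:
        if len(seq) != 20 + t:
            raise ValueError(f"sequence {seq!r} is not {20 + t} bases long")
        n = counts.count(seq) if counts is not None else 1
        heads.append(TsdHeadCandidate(seq[:t], seq[t:], sample, n))
        tails.append(TailTsdCandidate(seq[:20], seq[20:], sample, n))
    return heads, tails


def pair_by_tsd(heads: Iterable[TsdHeadCandidate],
                tails: Iterable[TailTsdCandidate],
                min_tsd_kinds: int = 2) -> list[HeadTailPair]:
    """Pair heads and tails that share TSD strings within one sample.

    A TSD supports a (head, tail) pair only when that TSD was seen adjoining
    the head AND the tail in the *same* sample — one transposition writes
    both junctions into one genome. Pairs with fewer than ``min_tsd_kinds``
    distinct supporting TSDs (pooled over samples) are dropped.
    """
    head_by: dict[tuple[str, str], set[str]] = defaultdict(set)
    tail_by: dict[tuple[str, str], set[str]] = defaultdict(set)
    for c in heads:
        head_by[(c.sample, c.tsd)].add(c.head)
    for c in tails:
        tail_by[(c.sample, c.tsd)].add(c.tail)
    tsds_for: dict[tuple[str, str], dict[str, set[str]]] = defaultdict(
        lambda: {SAMPLE_A: set(), SAMPLE_B: set()})
    for (sample, tsd), hset in head_by.items():
        tset = tail_by.get((sample, tsd))
        if not tset:
            continue
        for h in hset:
            for t in tset:
                tsds_for[(h, t)][sample].add(tsd)
    pairs = []
    for (h, t), by_sample in sorted(tsds_for.items()):
        union = by_sample[SAMPLE_A] | by_sample[SAMPLE_B]
        if len(union) < min_tsd_kinds:
            continue
        pairs.append(HeadTailPair(h, t,
                                  frozenset(by_sample[SAMPLE_A]),
                                  frozenset(by_sample[SAMPLE_B])))
    logger.info("head/tail pairs with >=%d TSDs: %d", min_tsd_kinds, len(pairs))
    return pairs


def specificity_filter(pairs: Iterable[HeadTailPair],
                       threshold: float = 0.7) -> list[HeadTailPair]:
    """Keep pairs whose sample-specific TSD fraction exceeds *threshold*."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    kept = [p for p in pairs if p.specificity > threshold]
    logger.info("pairs passing specificity > %.2f: %d", threshold, len(kept))
    return kept


# -- verification ------------------------------------------------------------

def _collect_flanks(pair: HeadTailPair, catalog40: KmerCatalog, k: int = 20
                    ) -> tuple[set[str], set[str]]:
    """Upstream/downstream 20-mer flanks adjoining the pair's ends in reads.

    A read covering the head junction contains the 40-mer U+head (or its
    reverse complement); one covering the tail junction contains tail+D.
    """
    head, tail = pair.head, pair.tail
    rc_head, rc_tail = reverse_complement(head), reverse_complement(tail)
    ups: set[str] = set()
    downs: set[str] = set()
    for seq in catalog40.counts:
        if seq.endswith(head):
            ups.add(seq[:k])
        if seq.startswith(rc_head):
            ups.add(reverse_complement(seq[k:]))
        if seq.startswith(tail):
            downs.add(seq[k:])
        if seq.endswith(rc_tail):
            downs.add(reverse_complement(seq[:k]))
    return ups, downs


def _position_flanks(upstream: str, downstream: str, tsd: str,
                     index: Optional[ReferenceIndex]
                     ) -> tuple[Optional[str], Optional[int], Optional[int], bool]:
    """Map flanks to reference coordinates; detect mirror orientations.

    Returns (contig, head_junction, tail_junction, is_mirror). A candidate
    whose flanks map uniquely to the reverse strand is the same junction
    seen from the opposite strand; it is skipped because the forward
    orientation generates the canonical call.
    """
    if index is None:
        return None, None, None, False
    up = index.lookup(upstream)
    down = index.lookup(downstream)
    strands = {r.position.strand for r in (up, down) if r.status == UNIQUE}
    if strands and FORWARD not in strands:
        return None, None, None, True
    if up.status == UNIQUE and down.status == UNIQUE \
            and up.position.strand == FORWARD and down.position.strand == FORWARD \
            and up.position.contig == down.position.contig:
        hj = head_junction_position(up.position, index.k)
        tj = down.position.pos
        if hj - tj + 1 == len(tsd) \
                and index.fetch(up.position.contig, tj, hj) == tsd:
            return up.position.contig, hj, tj, False
    return None, None, None, False


def verify_tsd_pairs(pairs: list[HeadTailPair], catalog40_a: KmerCatalog,
                     catalog40_b: KmerCatalog,
                     index: Optional[ReferenceIndex],
                     params: Parameters) -> list[InsertionCall]:
    """Steps 8-13: recover flanks from reads, count probes, genotype.

    For each surviving pair and each sample-specific TSD, upstream flanks
    ending with the TSD and downstream flanks starting with it are joined
    into candidate loci; combinations that do not correspond to a real
    junction are eliminated by the read-count filter (their wild-type
    sequence exists in neither sample).
    """
    depth_a = median_read_depth(catalog40_a)
    depth_b = median_read_depth(catalog40_b)
    calls: dict[tuple, InsertionCall] = {}
    for pair in pairs:
        for sample, catalog, tsds in (
                (SAMPLE_A, catalog40_a, pair.tsds_a),
                (SAMPLE_B, catalog40_b, pair.tsds_b)):
            if not tsds:
                continue
            ups, downs = _collect_flanks(pair, catalog)
            for tsd in sorted(tsds):
                for up in sorted(u for u in ups if u.endswith(tsd)):
                    for down in sorted(d for d in downs if d.startswith(tsd)):
                        contig, hj, tj, mirror = _position_flanks(
                            up, down, tsd, index)
                        if mirror:
                            continue
                        if index is None:
                            # canonical orientation: avoid emitting the same
                            # junction twice (once per strand reading)
                            if (up + pair.head) > reverse_complement(
                                    pair.tail + down):
                                continue
                        probes = build_probes(up, down, pair.head, pair.tail,
                                              tsd)
                        counts_a, counts_b = count_probes(
                            probes, catalog40_a, catalog40_b)
                        draft = InsertionCall(
                            head=pair.head, tail=pair.tail, tsd=tsd,
                            upstream_flank=up, downstream_flank=down,
                            carrier=sample, contig=contig,
                            head_junction=hj, tail_junction=tj,
                            counts_a=counts_a, counts_b=counts_b)
                        other_depth = depth_b if sample == SAMPLE_A else depth_a
                        accepted = filter_and_genotype(draft, params,
                                                       other_depth)
                        if accepted is None:
                            continue
                        key = (contig, hj, tj, tsd, pair.head, pair.tail,
                               sample, up, down)
                        calls.setdefault(key, accepted)
    return list(calls.values())


def run_tsd_method(reads_a: Sequence[str], reads_b: Sequence[str],
                   tsd_size: int,
                   index: Optional[ReferenceIndex] = None,
                   params: Parameters = Parameters(),
                   catalog40_a: KmerCatalog | None = None,
                   catalog40_b: KmerCatalog | None = None) -> DetectionResult:
    """Full Algorithm 1 pipeline on in-memory read sequences.

    ``tsd_size`` is a single fixed TSD length for the run. Values of 3 or
    less are allowed but warned against: with so few distinct TSD strings,
    unrelated junctions collide on the same TSD and the method loses power.
    Pre-built 40-mer catalogs (e.g. from a junction-method run on the same
    samples) are reused for verification when supplied.
    """
    if tsd_size < 1:
        raise ValueError("tsd_size must be >= 1")
    if tsd_size <= 3:
        warnings.warn("TSD lengths of 3 or less give poor discrimination "
                      "between unrelated junctions")
    k = params.end_k + tsd_size
    cat_a = slice_kmers(reads_a, k, SAMPLE_A)
    cat_b = slice_kmers(reads_b, k, SAMPLE_B)
    logger.info("%d-mer catalogs: A=%d B=%d", k, len(cat_a), len(cat_b))
    specific_a, specific_b = specific_kmers(cat_a, cat_b)
    logger.info("sample-specific %d-mers: A=%d B=%d", k,
                len(specific_a), len(specific_b))
    heads_a, tails_a = split_candidates(specific_a, tsd_size, SAMPLE_A, cat_a)
    heads_b, tails_b = split_candidates(specific_b, tsd_size, SAMPLE_B, cat_b)
    pairs = pair_by_tsd(heads_a + heads_b, tails_a + tails_b,
                        params.min_tsd_kinds)
    pairs = specificity_filter(pairs, params.specificity_threshold)
    if catalog40_a is None:
        catalog40_a = slice_kmers(reads_a, 2 * params.end_k, SAMPLE_A)
    if catalog40_b is None:
        catalog40_b = slice_kmers(reads_b, 2 * params.end_k, SAMPLE_B)
    calls = verify_tsd_pairs(pairs, catalog40_a, catalog40_b, index, params)
    contig_order = index.config.active if index is not None else None
    calls = sort_calls(calls, contig_order)
    flag_overlapping_calls(calls)
    merged = merge_reverse_complement_pairs(pairs)
    annotations = {}
    for p in merged:
        annotations[(p.head, p.tail)] = annotate_pair(p.head, p.tail, index)
    for call in calls:
        key = (call.head, call.tail)
        if key not in annotations:
            annotations[key] = annotate_pair(call.head, call.tail, index)
        call.te_length = annotations[key].estimated_length
        call.tg_ca_flag = annotations[key].tg_ca_flag
    logger.info("TSD method: %d pairs, %d verified calls", len(merged),
                len(calls))
    return DetectionResult(pairs=merged, calls=calls, annotations=annotations,
                           repetitive_candidates=[])
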