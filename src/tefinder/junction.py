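"""Junction method: reference-based discovery of TE ends (Algorithm 2).

Every sample-specific 40-mer is split into two 20-mer halves and both are
located in the reference. A half that maps uniquely while its neighbour
does not sit immediately next to it marks a junction: the mapped half is
genomic flank, the other half is a TE end candidate (which must itself
occur somewhere in the reference — an element entirely absent from the
reference is invisible to this method). Head and tail junctions whose
coordinates overlap by a plausible TSD length (3-16 bp), with identical TSD
copies in the reference and in both flanks, define an insertion; pairs
supported by several distinct TSDs that differ between the samples are
candidate active elements, which then pass through read-level verification.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

from ._sequence import reverse_complement
from .kmer import KmerCatalog, slice_kmers, specific_kmers
from .model import (HeadTailPair, InsertionCall, Parameters, SAMPLE_A, SAMPLE_B,
                    merge_reverse_complement_pairs)
from .parallel import parallel_map
from .reference import FORWARD, GenomePosition, ReferenceIndex
from .verify import (annotate_pair, build_probes, count_probes,
                     filter_and_genotype, flag_overlapping_calls,
                     median_read_depth, sort_calls)

logger = logging.getLogger(__name__)

HEAD = "head"
TAIL = "tail"


@dataclass(frozen=True)
class JunctionObservation:
    """One junction-spanning 40-mer, canonicalised to the forward strand."""

    kind: str                 # 'head' (flank + TE head) or 'tail' (TE tail + flank)
    flank: str                # the uniquely mapped 20-mer half
    te_end: str               # the TE end candidate half
    flank_pos: GenomePosition
    sample: str
    count: int = 0

    @property
    def head_junction(self) -> int:
        """Coordinate of the upstream flank's last base (head kind only)."""
        return head_junction_position(self.flank_pos)

    @property
    def tail_junction(self) -> int:
        """Coordinate of the downstream flank's first base (tail kind only)."""
        return self.flank_pos.pos


@dataclass(frozen=True)
class JunctionPair:
    """A head and a tail junction reconciled at one insertion locus."""

    head_obs: JunctionObservation
    tail_obs: JunctionObservation
    contig: str
    head_junction: int
    tail_junction: int
    tsd: str
    sample: str

    @property
    def tsd_len(self) -> int:
        return self.head_junction - self.tail_junction + 1


def head_junction_position(flank_pos: GenomePosition, k: int = 20) -> int:
    """Last base of an upstream flank whose first base maps at ``pos``."""
    return flank_pos.pos + k - 1


def _repeat_regex(mono: int, di: int) -> re.Pattern:
    mono_alt = "|".join(f"{b}{{{mono},}}" for b in "ACGT")
    di_alt = "|".join(f"(?:{d}){{{di},}}" for d in ("AC", "AG", "AT", "TC", "TG"))
    return re.compile(f"{mono_alt}|{di_alt}")


_REPEAT_CACHE: dict[tuple[int, int], re.Pattern] = {}


def repeat_filter(end20: str, mono: int = 10, di: int = 9) -> bool:
    """True when a candidate TE end is simple repeat and must be excluded.

    Triggers on a mononucleotide run of >= *mono* bases or >= *di*
    consecutive tandem copies of AC, AG, AT, TC or TG.
    """
    pat = _REPEAT_CACHE.get((mono, di))
    if pat is None:
        pat = _REPEAT_CACHE[(mono, di)] = _repeat_regex(mono, di)
    return pat.search(end20) is not None


def classify_40mer(seq40: str, index: ReferenceIndex,
                   params: Parameters = Parameters()
                   ) -> tuple[list[tuple], list[tuple]]:
    """Classify one 40-mer (in the given orientation) into junction evidence.

    Returns ``(observations, repetitive_candidates)`` where observations are
    ``(kind, flank, te_end, flank_pos)`` tuples. A 40-mer whose halves map
    next to each other is ordinary genome and yields nothing. Flank halves
    are accepted only when globally unique on the forward strand (the caller
    evaluates both orientations, so reverse-strand junctions are picked up
    in the opposite orientation); te_end halves must occur somewhere in the
    reference but not at the adjacent site. Ambiguously mapping flanks with
    a mapped te_end are returned separately — insertions into repetitive
    loci, reportable but not pairable.
    """
    k = index.k
    left, right = seq40[:k], seq40[k:]
    obs: list[tuple] = []
    repetitive: list[tuple] = []
    left_hits = index.matches(left) if len(left) == k else ()
    right_hits = index.matches(right) if len(right) == k else ()

    # left half = upstream flank, right half = TE head candidate
    if len(left_hits) == 1 and left_hits[0].strand == FORWARD:
        pos = left_hits[0]
        adjacent = GenomePosition(pos.contig, pos.pos + k, FORWARD)
        if right_hits and adjacent not in right_hits \
                and not repeat_filter(right, params.mono_repeat, params.di_repeat):
            obs.append((HEAD, left, right, pos))
    elif len(left_hits) > 1 and right_hits \
            and not repeat_filter(right, params.mono_repeat, params.di_repeat):
        repetitive.append((HEAD, left, right))

    # right half = downstream flank, left half = TE tail candidate
    if len(right_hits) == 1 and right_hits[0].strand == FORWARD:
        pos = right_hits[0]
        adjacent = GenomePosition(pos.contig, pos.pos - k, FORWARD)
        if left_hits and adjacent not in left_hits \
                and not repeat_filter(left, params.mono_repeat, params.di_repeat):
            obs.append((TAIL, right, left, pos))
    elif len(right_hits) > 1 and left_hits \
            and not repeat_filter(left, params.mono_repeat, params.di_repeat):
        repetitive.append((TAIL, right, left))

    return obs, repetitive


def _classify_shard(shard: list[tuple[str, int, str]]):
    """Worker: classify (seq40, count, sample) items in both orientations."""
    index, params = _WORKER_STATE
    acc: dict[tuple, int] = {}
    repetitive: set[tuple] = set()
    for seq40, count, sample in shard:
        rc = reverse_complement(seq40)
        orientations = (seq40,) if rc == seq40 else (seq40, rc)
        for oriented in orientations:
            obs, rep = classify_40mer(oriented, index, params)
            for kind, flank, te_end, pos in obs:
                key = (kind, flank, te_end, pos, sample)
                acc[key] = acc.get(key, 0) + count
            for kind, flank, te_end in rep:
                repetitive.add((kind, flank, te_end, sample))
    return acc, repetitive


_WORKER_STATE: tuple = ()


def collect_observations(specific_a: Iterable[str], specific_b: Iterable[str],
                         catalog_a: KmerCatalog, catalog_b: KmerCatalog,
                         index: ReferenceIndex, params: Parameters,
                         threads: int = 1
                         ) -> tuple[list[JunctionObservation], list[tuple]]:
    """Classify all sample-specific 40-mers of both samples.

    Each specific 40-mer is evaluated in both orientations so that every
    observation carries forward-strand coordinates; a junction covered on
    both strands contributes the summed read count of both orientations.
    Work is sharded by 2-base prefix, making results independent of the
    worker count.
    """
    items = (
        [(s, catalog_a.count(s), SAMPLE_A) for s in sorted(specific_a)]
        + [(s, catalog_b.count(s), SAMPLE_B) for s in sorted(specific_b)]
    )
    shards: dict[str, list] = {}
    for item in items:
        shards.setdefault(item[0][:2], []).append(item)
    shard_list = [shards[p] for p in sorted(shards)]

    global _WORKER_STATE
    _WORKER_STATE = (index, params)
    try:
        results = parallel_map(_classify_shard, shard_list, threads)
    finally:
        _WORKER_STATE = ()

    acc: dict[tuple, int] = {}
    repetitive: set[tuple] = set()
    for shard_acc, shard_rep in results:
        for key, count in shard_acc.items():
            acc[key] = acc.get(key, 0) + count
        repetitive |= shard_rep
    observations = [
        JunctionObservation(kind, flank, te_end, pos, sample, count)
        for (kind, flank, te_end, pos, sample), count in sorted(
            acc.items(), key=lambda kv: (kv[0][3].contig, kv[0][3].pos, kv[0]))
    ]
    logger.info("junction observations: %d (%d repetitive-locus candidates)",
                len(observations), len(repetitive))
    return observations, sorted(repetitive)


def pair_junctions(observations: list[JunctionObservation],
                   index: ReferenceIndex,
                   params: Parameters = Parameters()) -> list[JunctionPair]:
    """Match head and tail junctions whose coordinates overlap by a TSD.

    Within one sample and contig, a head junction at ``h`` pairs with a tail
    junction at ``t`` when ``h - t + 1`` lies in the allowed TSD length range
    and the three TSD copies — the reference substring [t, h], the upstream
    flank suffix and the downstream flank prefix — are the same string.
    """
    pairs: list[JunctionPair] = []
    groups: dict[tuple[str, str], tuple[list, list]] = {}
    for obs in observations:
        key = (obs.sample, obs.flank_pos.contig)
        heads, tails = groups.setdefault(key, ([], []))
        (heads if obs.kind == HEAD else tails).append(obs)
    for (sample, contig), (heads, tails) in sorted(groups.items()):
        tails.sort(key=lambda o: o.tail_junction)
        for head_obs in sorted(heads, key=lambda o: o.head_junction):
            h = head_obs.head_junction
            for tail_obs in tails:
                t = tail_obs.tail_junction
                tsd_len = h - t + 1
                if tsd_len > params.tsd_max:
                    continue
                if tsd_len < params.tsd_min:
                    break  # tails sorted ascending; all later ones are shorter
                tsd = index.fetch(contig, t, h)
                if (head_obs.flank.endswith(tsd)
                        and tail_obs.flank.startswith(tsd)):
                    pairs.append(JunctionPair(
                        head_obs=head_obs, tail_obs=tail_obs, contig=contig,
                        head_junction=h, tail_junction=t, tsd=tsd,
                        sample=sample))
    logger.info("junction pairs with TSD: %d", len(pairs))
    return pairs


def select_te_pairs(pairs: list[JunctionPair],
                    params: Parameters = Parameters()
                    ) -> tuple[list[HeadTailPair], dict]:
    """Keep end pairs with several TSDs that differ between the samples.

    Pairs are grouped by (head, tail) end sequences; a group survives when
    it shows at least ``min_tsd_kinds`` distinct TSDs overall and at least
    one TSD private to a single sample (a fixed element present in both
    genomes shows identical TSDs in both and is discarded).
    """
    groups: dict[tuple[str, str], list[JunctionPair]] = {}
    for p in pairs:
        groups.setdefault((p.head_obs.te_end, p.tail_obs.te_end), []).append(p)
    kept_pairs: list[HeadTailPair] = []
    kept_groups: dict[tuple[str, str], list[JunctionPair]] = {}
    for (head, tail), members in sorted(groups.items()):
        tsds_a = frozenset(p.tsd for p in members if p.sample == SAMPLE_A)
        tsds_b = frozenset(p.tsd for p in members if p.sample == SAMPLE_B)
        if len(tsds_a | tsds_b) < params.min_tsd_kinds:
            continue
        if not (tsds_a ^ tsds_b):
            continue
        kept_pairs.append(HeadTailPair(head, tail, tsds_a, tsds_b))
        kept_groups[(head, tail)] = members
    logger.info("TE end pairs selected: %d of %d groups",
                len(kept_pairs), len(groups))
    return kept_pairs, kept_groups


@dataclass
class DetectionResult:
    """Outcome of one full method run."""

    pairs: list[HeadTailPair]
    calls: list[InsertionCall]
    annotations: dict[tuple[str, str], object]
    repetitive_candidates: list[tuple] = None


def verify_junction_groups(kept_groups: dict, catalog_a: KmerCatalog,
                           catalog_b: KmerCatalog, params: Parameters,
                           ) -> list[InsertionCall]:
    """Steps 8-13 verification for every paired junction locus."""
    depth_a = median_read_depth(catalog_a)
    depth_b = median_read_depth(catalog_b)
    calls: dict[tuple, InsertionCall] = {}
    for (head, tail), members in sorted(kept_groups.items()):
        for jp in members:
            key = (jp.contig, jp.head_junction, jp.tail_junction, jp.tsd,
                   head, tail, jp.sample)
            if key in calls:
                continue
            probes = build_probes(jp.head_obs.flank, jp.tail_obs.flank,
                                  head, tail, jp.tsd)
            counts_a, counts_b = count_probes(probes, catalog_a, catalog_b)
            draft = InsertionCall(
                head=head, tail=tail, tsd=jp.tsd,
                upstream_flank=jp.head_obs.flank,
                downstream_flank=jp.tail_obs.flank,
                carrier=jp.sample, contig=jp.contig,
                head_junction=jp.head_junction, tail_junction=jp.tail_junction,
                counts_a=counts_a, counts_b=counts_b)
            other_depth = depth_b if jp.sample == SAMPLE_A else depth_a
            accepted = filter_and_genotype(draft, params, other_depth)
            if accepted is not None:
                calls[key] = accepted
    return list(calls.values())


def run_junction_method(reads_a: Iterable[str], reads_b: Iterable[str],
                        index: ReferenceIndex,
                        params: Parameters = Parameters(),
                        threads: int = 1,
                        catalog_a: KmerCatalog | None = None,
                        catalog_b: KmerCatalog | None = None
                        ) -> DetectionResult:
    """Full Algorithm 2 pipeline on in-memory read iterables.

    Pre-built 40-mer catalogs may be passed to reuse sorted k-mer data
    across runs (the expensive step); otherwise they are sliced here.
    """
    k = 2 * index.k
    if catalog_a is None:
        catalog_a = slice_kmers(reads_a, k, SAMPLE_A)
    if catalog_b is None:
        catalog_b = slice_kmers(reads_b, k, SAMPLE_B)
    logger.info("40-mer catalogs: A=%d B=%d", len(catalog_a), len(catalog_b))
    specific_a, specific_b = specific_kmers(catalog_a, catalog_b)
    logger.info("sample-specific 40-mers: A=%d B=%d",
                len(specific_a), len(specific_b))
    observations, repetitive = collect_observations(
        specific_a, specific_b, catalog_a, catalog_b, index, params, threads)
    jpairs = pair_junctions(observations, index, params)
    pairs, kept_groups = select_te_pairs(jpairs, params)
    calls = verify_junction_groups(kept_groups, catalog_a, catalog_b, params)
    calls = sort_calls(calls, index.config.active)
    flag_overlapping_calls(calls)
    merged = merge_reverse_complement_pairs(pairs)
    annotations = {}
    for call_or_pair in merged:
        key = (call_or_pair.head, call_or_pair.tail)
        annotations[key] = annotate_pair(*key, index)
    for call in calls:
        key = (call.head, call.tail)
        if key not in annotations:
            annotations[key] = annotate_pair(*key, index)
        call.te_length = annotations[key].estimated_length
        call.tg_ca_flag = annotations[key].tg_ca_flag
    logger.info("junction method: %d pairs, %d verified calls",
                len(merged), len(calls))
    return DetectionResult(pairs=merged, calls=calls, annotations=annotations,
                           repetitive_candidates=repetitive)
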