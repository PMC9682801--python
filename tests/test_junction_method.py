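"""Junction method: repeat filter, 40-mer classification, TSD-window pairing."""

import numpy as np
import pytest

from tefinder import (classify_40mer, head_junction_position, pair_junctions,
                      repeat_filter, reverse_complement, run_junction_method,
                      select_te_pairs)
from tefinder.junction import HEAD, TAIL, JunctionObservation, JunctionPair
from tefinder.model import SAMPLE_A, SAMPLE_B
from tefinder.reference import FORWARD, GenomePosition, ReferenceIndex


@pytest.mark.parametrize(
    "seq,excluded",
    [
        ("AAAAAAAAAA" + "CGTACGTACG", True),    # mononucleotide run of 10
        ("AAAAAAAAA" + "CGTACGTACGT", False),   # run of 9 passes
        ("ACACACACACACACACAC" + "GG", True),    # 9 tandem AC copies
        ("ACACACACACACACAC" + "GGTT", False),   # 8 copies pass
        ("CA" * 10, True),                      # phase-shifted AC repeat
        ("TGTTGGAATTAATGAATGGG", False),        # real element head: keep
        ("TTTTTTTTTT" + "ACGTACGTAC", True),
        ("TCTCTCTCTCTCTCTCTC" + "AA", True),    # 9 tandem TC copies
    ],
)
def test_repeat_filter_boundaries(seq, excluded):
    assert len(seq) == 20
    assert repeat_filter(seq) is excluded


@pytest.mark.parametrize(
    "pos,k,expected",
    [
        (22530988, 20, 22531007),  # worked example from the rice data
        (1, 20, 20),
        (100, 5, 104),
    ],
)
def test_head_junction_position(pos, k, expected):
    assert head_junction_position(GenomePosition("c", pos, FORWARD), k) \
        == expected


@pytest.fixture(scope="module")
def toy_setup():
    """A genome with a distant 'TE end' block for classification tests."""
    rng = np.random.default_rng(23)
    genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=3000)])
    index = ReferenceIndex({"c1": genome})
    return genome, index


def test_contiguous_40mer_yields_nothing(toy_setup):
    genome, index = toy_setup
    obs, rep = classify_40mer(genome[100:140], index)
    assert obs == [] and rep == []


def test_flank_plus_distant_end_is_head_observation(toy_setup):
    genome, index = toy_setup
    flank, te_end = genome[100:120], genome[2500:2520]
    obs, _ = classify_40mer(flank + te_end, index)
    assert len(obs) >= 1
    kinds = {o[0] for o in obs}
    assert HEAD in kinds
    head = next(o for o in obs if o[0] == HEAD)
    assert head[1] == flank and head[2] == te_end
    assert head[3] == GenomePosition("c1", 101, FORWARD)


def test_unmapped_te_end_is_invisible(toy_setup):
    """An element absent from the reference cannot be located by this
    method: the TE-end half must occur somewhere in the reference."""
    genome, index = toy_setup
    flank = genome[100:120]
    novel = "TGTTGGAATTAATGAATGGG"
    assert index.matches(novel) == ()
    obs, _ = classify_40mer(flank + novel, index)
    assert obs == []
    obs, _ = classify_40mer(novel + flank, index)
    assert obs == []


def test_repeat_te_end_suppressed(toy_setup):
    genome, index = toy_setup
    # make the repeat run exist in the reference so only the repeat filter
    # can be responsible for suppression
    poly = "A" * 20
    genome2 = genome[:1500] + poly + genome[1500:]
    index2 = ReferenceIndex({"c1": genome2})
    flank = genome2[100:120]
    obs, _ = classify_40mer(flank + poly, index2)
    assert all(o[0] != HEAD for o in obs)


def test_ambiguous_flank_reported_separately(toy_setup):
    genome, index = toy_setup
    dup = genome[100:120]
    genome2 = genome + ("T" * 40) + dup
    index2 = ReferenceIndex({"c1": genome2})
    te_end = genome[2500:2520]
    obs, rep = classify_40mer(dup + te_end, index2)
    assert all(o[1] != dup for o in obs)
    assert (HEAD, dup, te_end) in rep


def _obs(kind, flank, te_end, pos, sample=SAMPLE_A):
    return JunctionObservation(kind, flank, te_end, pos, sample, 5)


def _junction_obs_at(genome, head_junction, tail_junction, te_head, te_tail,
                     sample=SAMPLE_A, contig="c1"):
    up = genome[head_junction - 20 : head_junction]
    down = genome[tail_junction - 1 : tail_junction + 19]
    return (
        _obs(HEAD, up, te_head, GenomePosition(contig, head_junction - 19,
                                               FORWARD), sample),
        _obs(TAIL, down, te_tail, GenomePosition(contig, tail_junction,
                                                 FORWARD), sample),
    )


@pytest.mark.parametrize("tsd_len,admitted", [(2, False), (3, True),
                                              (5, True), (16, True),
                                              (17, False)])
def test_tsd_length_bounds(toy_setup, tsd_len, admitted):
    """Pairs are admitted for TSD lengths 3..16 only."""
    genome, index = toy_setup
    tail_junction = 400
    head_junction = tail_junction + tsd_len - 1
    head_obs, tail_obs = _junction_obs_at(
        genome, head_junction, tail_junction, genome[2500:2520],
        genome[2600:2620])
    pairs = pair_junctions([head_obs, tail_obs], index)
    if admitted:
        assert len(pairs) == 1
        pair = pairs[0]
        assert pair.tsd_len == tsd_len
        assert pair.tsd == genome[tail_junction - 1 : head_junction]
    else:
        assert pairs == []


def test_pairing_requires_same_sample(toy_setup):
    genome, index = toy_setup
    head_obs, tail_obs = _junction_obs_at(genome, 404, 400,
                                          genome[2500:2520],
                                          genome[2600:2620])
    tail_other = JunctionObservation(TAIL, tail_obs.flank, tail_obs.te_end,
                                     tail_obs.flank_pos, SAMPLE_B, 5)
    assert pair_junctions([head_obs, tail_other], index) == []


def _jpair(head, tail, tsd, sample):
    head_obs = _obs(HEAD, "A" * 15 + tsd, head,
                    GenomePosition("c1", 100, FORWARD), sample)
    tail_obs = _obs(TAIL, tsd + "A" * 15, tail,
                    GenomePosition("c1", 100, FORWARD), sample)
    return JunctionPair(head_obs, tail_obs, "c1", 104, 100, tsd, sample)


H2 = "CATGATGAAATAACATAAGG"
T2 = "CCTTATGTTATTTCATCATG"


def test_select_requires_multiple_tsd_kinds():
    pairs, _ = select_te_pairs([_jpair(H2, T2, "GATCC", SAMPLE_A)])
    assert pairs == []


def test_select_requires_sample_private_tsd():
    members = [_jpair(H2, T2, "GATCC", SAMPLE_A),
               _jpair(H2, T2, "GATCC", SAMPLE_B),
               _jpair(H2, T2, "TTGCA", SAMPLE_A),
               _jpair(H2, T2, "TTGCA", SAMPLE_B)]
    pairs, _ = select_te_pairs(members)
    assert pairs == []  # identical repertoires: a fixed, not active, element


def test_select_keeps_differing_repertoires():
    members = [_jpair(H2, T2, "GATCC", SAMPLE_A),
               _jpair(H2, T2, "TTGCA", SAMPLE_A),
               _jpair(H2, T2, "AATTC", SAMPLE_B)]
    pairs, groups = select_te_pairs(members)
    assert len(pairs) == 1
    assert pairs[0].tsds_a == {"GATCC", "TTGCA"}
    assert pairs[0].tsds_b == {"AATTC"}
    assert (H2, T2) in groups


def test_self_comparison_yields_nothing(small_fixture):
    from tefinder import build_index

    index = build_index(small_fixture.reference)
    result = run_junction_method(small_fixture.reads_a, small_fixture.reads_a,
                                 index)
    assert result.pairs == [] and result.calls == []


def test_triple_tsd_consistency(junction_result, default_index):
    """Every call's TSD equals the reference substring between its junctions,
    the upstream-flank suffix and the downstream-flank prefix."""
    assert junction_result.calls
    for call in junction_result.calls:
        ref_tsd = default_index.fetch(call.contig, call.tail_junction,
                                      call.head_junction)
        assert call.tsd == ref_tsd
        assert call.upstream_flank.endswith(call.tsd)
        assert call.downstream_flank.startswith(call.tsd)
        assert call.head_junction - call.tail_junction + 1 == call.tsd_len


def test_no_emitted_end_is_simple_repeat(junction_result):
    for call in junction_result.calls:
        assert not repeat_filter(call.head)
        assert not repeat_filter(call.tail)


def test_observations_canonicalised_to_forward_strand(toy_setup):
    """A junction read from the reverse strand yields the same forward
    observation as its forward-strand mate."""
    genome, index = toy_setup
    flank, te_end = genome[100:120], genome[2500:2520]
    fwd, _ = classify_40mer(flank + te_end, index)
    rev, _ = classify_40mer(reverse_complement(flank + te_end), index)
    head_fwd = [o for o in fwd if o[0] == HEAD]
    head_rev = [o for o in rev if o[0] == HEAD]
    assert head_fwd and not head_rev  # caller re-orients; one orientation fires
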