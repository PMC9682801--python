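"""TSD method: candidate splitting, TSD pairing, specificity filtering."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tefinder import (pair_by_tsd, run_tsd_method, specificity_filter,
                      split_candidates)
from tefinder.model import SAMPLE_A, SAMPLE_B, HeadTailPair
from tefinder.tsd import TailTsdCandidate, TsdHeadCandidate


def test_split_candidates_positional_split():
    seq = "GATACGTACGTACGTACGTACGT"  # 23 bases, t=3
    heads, tails = split_candidates([seq], 3, SAMPLE_A)
    assert heads == [TsdHeadCandidate("GAT", seq[3:], SAMPLE_A, 1)]
    assert tails == [TailTsdCandidate(seq[:20], "CGT", SAMPLE_A, 1)]
    assert heads[0].tsd + heads[0].head == seq
    assert tails[0].tail + tails[0].tsd == seq


def test_split_candidates_empty_and_length_checks():
    assert split_candidates([], 5, SAMPLE_A) == ([], [])
    with pytest.raises(ValueError, match="25 bases"):
        split_candidates(["ACGT"], 5, SAMPLE_A)
    with pytest.raises(ValueError, match=">= 1"):
        split_candidates([], 0, SAMPLE_A)


def _cands(head_items, tail_items):
    heads = [TsdHeadCandidate(tsd, head, sample, 1)
             for tsd, head, sample in head_items]
    tails = [TailTsdCandidate(tail, tsd, sample, 1)
             for tail, tsd, sample in tail_items]
    return heads, tails


H = "CATGATGAAATAACATAAGG"
T = "CCTTATGTTATTTCATCATG"


def test_single_tsd_yields_no_pair():
    heads, tails = _cands([("AAAAA", H, SAMPLE_A)], [(T, "AAAAA", SAMPLE_A)])
    assert pair_by_tsd(heads, tails) == []


def test_two_shared_tsds_in_one_sample_pair():
    heads, tails = _cands(
        [("GATCC", H, SAMPLE_A), ("TTGCA", H, SAMPLE_A)],
        [(T, "GATCC", SAMPLE_A), (T, "TTGCA", SAMPLE_A)])
    pairs = pair_by_tsd(heads, tails)
    assert len(pairs) == 1
    assert pairs[0].key() == (H, T)
    assert pairs[0].tsds_a == {"GATCC", "TTGCA"}
    assert pairs[0].tsds_b == frozenset()


def test_tsd_seen_with_head_only_not_counted():
    heads, tails = _cands(
        [("GATCC", H, SAMPLE_A), ("TTGCA", H, SAMPLE_A), ("CCCCC", H, SAMPLE_A)],
        [(T, "GATCC", SAMPLE_A), (T, "TTGCA", SAMPLE_A)])
    pairs = pair_by_tsd(heads, tails)
    assert pairs[0].tsd_union == {"GATCC", "TTGCA"}  # CCCCC lacks a tail


def test_tsd_split_across_samples_is_not_evidence():
    """A TSD adjoining the head in A and the tail only in B does not pair."""
    heads, tails = _cands(
        [("GATCC", H, SAMPLE_A), ("TTGCA", H, SAMPLE_A)],
        [(T, "GATCC", SAMPLE_B), (T, "TTGCA", SAMPLE_B)])
    assert pair_by_tsd(heads, tails) == []


def test_pairing_symmetric_under_sample_swap():
    head_items = [("GATCC", H, SAMPLE_A), ("TTGCA", H, SAMPLE_A),
                  ("AATTC", H, SAMPLE_B)]
    tail_items = [(T, "GATCC", SAMPLE_A), (T, "TTGCA", SAMPLE_A),
                  (T, "AATTC", SAMPLE_B)]
    swap = {SAMPLE_A: SAMPLE_B, SAMPLE_B: SAMPLE_A}
    pairs = pair_by_tsd(*_cands(head_items, tail_items))
    swapped = pair_by_tsd(*_cands(
        [(t, h, swap[s]) for t, h, s in head_items],
        [(t2, t, swap[s]) for t2, t, s in tail_items]))
    assert {p.key() for p in pairs} == {p.key() for p in swapped}
    assert pairs[0].tsds_a == swapped[0].tsds_b
    assert pairs[0].tsds_b == swapped[0].tsds_a


def _pair(tsds_a, tsds_b):
    return HeadTailPair(H, T, frozenset(tsds_a), frozenset(tsds_b))


def test_specificity_filter_keeps_sample_private_repertoires():
    kept = specificity_filter([_pair({"s1", "s2", "s3"}, {"s4"})], 0.7)
    assert len(kept) == 1  # 4 of 4 TSDs are sample-private


def test_specificity_filter_drops_shared_repertoires():
    assert specificity_filter([_pair({"s1", "s2"}, {"s1", "s2"})], 0.7) == []


def test_specificity_filter_boundary_is_strict():
    # 3 private of 4 total = 0.75 passes 0.7 but not 0.75 (strict >)
    pair = _pair({"s1", "s2", "s3"}, {"s3", "s4"})
    assert pair.specificity == 0.75
    assert specificity_filter([pair], 0.7) == [pair]
    assert specificity_filter([pair], 0.75) == []


def test_specificity_threshold_validated():
    with pytest.raises(ValueError):
        specificity_filter([], 0.0)


@given(st.sets(st.text(alphabet="ACGT", min_size=5, max_size=5), max_size=6),
       st.sets(st.text(alphabet="ACGT", min_size=5, max_size=5), max_size=6))
def test_specificity_is_symmetric_and_bounded(tsds_a, tsds_b):
    p = _pair(tsds_a, tsds_b)
    q = _pair(tsds_b, tsds_a)
    assert p.specificity == q.specificity
    assert 0.0 <= p.specificity <= 1.0


def test_run_rejects_bad_tsd_size(small_fixture):
    with pytest.raises(ValueError):
        run_tsd_method(small_fixture.reads_a, small_fixture.reads_b, 0)


def test_short_tsd_sizes_warned(small_fixture):
    with pytest.warns(UserWarning, match="discrimination"):
        run_tsd_method(small_fixture.reads_a[:50], small_fixture.reads_a[:50],
                       3)


def test_self_comparison_yields_nothing(small_fixture):
    result = run_tsd_method(small_fixture.reads_a, small_fixture.reads_a, 5)
    assert result.pairs == []
    assert result.calls == []


def test_reported_tsds_have_requested_length(tsd_result, default_fixture):
    for pair in tsd_result.pairs:
        assert all(len(s) == default_fixture.tsd_len
                   for s in pair.tsd_union)
    for call in tsd_result.calls:
        assert len(call.tsd) == default_fixture.tsd_len


def test_engineered_tsd_repertoire_recovered(tsd_result, default_fixture):
    """Reads are error-free and the genome repeat-free: the TSD union of the
    detected pair equals the engineered TSD set exactly (up to strand)."""
    from tefinder import reverse_complement

    engineered = {t.tsd for t in default_fixture.truth}
    assert len(tsd_result.pairs) == 1
    reported = set(tsd_result.pairs[0].tsd_union)
    assert reported == engineered or \
        reported == {reverse_complement(s) for s in engineered}
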