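"""Probe construction, read-count verification, genotyping, TE annotation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tefinder import (annotate_pair, build_probes, count_probes,
                      estimate_te_length, filter_and_genotype,
                      reverse_complement, slice_kmers)
from tefinder.model import (HETEROZYGOUS, HOMOZYGOUS, SAMPLE_A, SAMPLE_B,
                            InsertionCall, Parameters, ProbeCounts)
from tefinder.reference import ReferenceIndex

H = "CATGATGAAATAACATAAGG"
T = "CCTTATGTTATTTCATCATG"


def test_build_probes_single_tsd_copy():
    up = "A" * 15 + "TTTTT"
    down = "TTTTT" + "G" * 15
    probes = build_probes(up, down, H, T, "TTTTT")
    assert probes.upstream_head == up + H
    assert probes.tail_downstream == T + down
    assert probes.non_insertion == "A" * 15 + "TTTTT" + "G" * 15
    assert probes.non_insertion.count("TTTTT") == 1
    assert len(probes.non_insertion) == 40 - 5


def test_build_probes_rejects_inconsistent_flanks():
    with pytest.raises(ValueError, match="TSD"):
        build_probes("A" * 20, "TTTTT" + "G" * 15, H, T, "TTTTT")
    with pytest.raises(ValueError, match="TSD"):
        build_probes("A" * 15 + "TTTTT", "G" * 20, H, T, "TTTTT")


def brute_force_count(reads, probe, exact_40=True):
    """Independent oracle: scan reads for the probe on both strands."""
    rc = reverse_complement(probe)
    queries = {probe, rc}
    n = 0
    for read in reads:
        limit = len(read) - 40 if not exact_40 else len(read) - len(probe)
        for q in queries:
            for i in range(len(read) - len(q) + 1):
                if not exact_40 and i > len(read) - 40:
                    continue
                if read[i : i + len(q)] == q:
                    n += 1
    return n


def test_count_probes_matches_read_scan_oracle():
    up = "ACGGATTCAGGCATTACGAT"
    down = "CTGAGGTACCAGATTACCCA"
    tsd = ""
    probes = build_probes(up, down, H, T, tsd)
    pad = "ACGTACGTAC"
    reads_a = [
        pad + probes.upstream_head + pad,                          # fwd
        reverse_complement(pad + probes.upstream_head),            # rev
        pad + probes.tail_downstream,
        "A" * 60,
    ]
    reads_b = [pad + probes.non_insertion + pad + "ACGTA"]
    cat_a = slice_kmers(reads_a, 40, SAMPLE_A)
    cat_b = slice_kmers(reads_b, 40, SAMPLE_B)
    counts_a, counts_b = count_probes(probes, cat_a, cat_b)
    assert counts_a.upstream_head == \
        brute_force_count(reads_a, probes.upstream_head) == 2
    assert counts_a.tail_downstream == \
        brute_force_count(reads_a, probes.tail_downstream) == 1
    assert counts_b.upstream_head == 0
    assert counts_b.non_insertion == \
        brute_force_count(reads_b, probes.non_insertion, exact_40=False) == 1


def test_palindromic_probe_counted_once_per_occurrence():
    half = "ACGGATTCAGGCATTACGAT"
    palindrome = half + reverse_complement(half)
    assert palindrome == reverse_complement(palindrome)
    cat = slice_kmers([palindrome, palindrome], 40, SAMPLE_A)
    from tefinder.verify import _count_exact_both

    assert _count_exact_both(cat, palindrome) == 2


def _draft(counts_a, counts_b, carrier=SAMPLE_A):
    return InsertionCall(head=H, tail=T, tsd="GATCC",
                         upstream_flank="A" * 15 + "GATCC",
                         downstream_flank="GATCC" + "G" * 15,
                         carrier=carrier,
                         counts_a=ProbeCounts(*counts_a),
                         counts_b=ProbeCounts(*counts_b))


@pytest.mark.parametrize(
    "carrier_counts,other_counts,genotype",
    [
        ((5, 4, 0), (0, 0, 8), HOMOZYGOUS),
        ((5, 4, 6), (0, 0, 8), HETEROZYGOUS),
        ((1, 1, 0), (0, 0, 2), HOMOZYGOUS),   # minimal acceptable evidence
    ],
)
def test_genotype_assignment(carrier_counts, other_counts, genotype):
    call = filter_and_genotype(_draft(carrier_counts, other_counts),
                               Parameters())
    assert call is not None
    assert call.genotype == genotype


@pytest.mark.parametrize(
    "carrier_counts,other_counts",
    [
        ((1, 0, 0), (0, 0, 8)),   # missing tail junction
        ((0, 1, 0), (0, 0, 8)),   # missing head junction
        ((5, 4, 0), (0, 0, 1)),   # insufficient wild-type in the other sample
        ((5, 4, 0), (1, 0, 8)),   # junction leaks into the other sample
    ],
)
def test_true_transposition_filter_rejects(carrier_counts, other_counts):
    assert filter_and_genotype(_draft(carrier_counts, other_counts),
                               Parameters()) is None


def test_repetitive_target_flagged_by_high_wildtype_count():
    call = filter_and_genotype(_draft((5, 4, 0), (0, 0, 90)), Parameters(),
                               other_median_depth=20.0)
    assert call is not None and call.repetitive_flag
    call = filter_and_genotype(_draft((5, 4, 0), (0, 0, 22)), Parameters(),
                               other_median_depth=20.0)
    assert call is not None and not call.repetitive_flag


@pytest.mark.parametrize(
    "head_pos,tail_pos,expected",
    [
        (26_694_795, 26_698_889, 4114),   # resident copy, chromosome 7
        (15_415_374, 15_419_558, 4204),   # resident copy, chromosome 10
        (100, 100, 20),                   # degenerate: ends coincide
    ],
)
def test_estimate_te_length(head_pos, tail_pos, expected):
    assert estimate_te_length(head_pos, tail_pos, 20) == expected


@given(st.integers(min_value=1, max_value=10**8),
       st.integers(min_value=0, max_value=10**4),
       st.integers(min_value=-1000, max_value=1000))
def test_te_length_translation_invariant(head_pos, span, shift):
    length = estimate_te_length(head_pos, head_pos + span)
    assert estimate_te_length(head_pos + shift, head_pos + span + shift) \
        == length


def test_annotate_tg_ca_consensus():
    assert annotate_pair("TGTTGGAATTAATGAATGGG", "ATATGCCCATAATCTCAACA",
                         None).tg_ca_flag
    assert not annotate_pair(H, T, None).tg_ca_flag


def test_annotate_locates_resident_copy(default_fixture, default_index,
                                        junction_result):
    te = default_fixture.te
    ann = junction_result.annotations.get((te[:20], te[-20:]))
    if ann is None:  # pair table may be canonicalised to the other strand
        ann = annotate_pair(te[:20], te[-20:], default_index)
    assert ann.estimated_length == len(te)


def test_annotate_unmappable_end_has_unknown_length():
    index = ReferenceIndex({"c": "ACGT" * 20})
    ann = annotate_pair(H, T, index)
    assert ann.head_sources == ()
    assert ann.estimated_length is None


def test_calls_reproduce_raw_read_counts(junction_result, default_fixture):
    """Catalog/scan agreement: re-scanning the raw reads reproduces the
    reported probe counts for every accepted call."""
    call = max(junction_result.calls, key=lambda c: c.counts_a.upstream_head)
    probes = build_probes(call.upstream_flank, call.downstream_flank,
                          call.head, call.tail, call.tsd)
    reads = (default_fixture.reads_a if call.carrier == SAMPLE_A
             else default_fixture.reads_b)
    assert call.carrier_counts.upstream_head == \
        brute_force_count(reads, probes.upstream_head)
    assert call.carrier_counts.tail_downstream == \
        brute_force_count(reads, probes.tail_downstream)


def test_genotype_recovery_on_fixture(junction_result, default_fixture):
    """Homozygous carriers show zero wild-type reads; heterozygous carriers
    about half depth (binomial spread)."""
    by_pos = {t.expected_head_junction: t for t in default_fixture.truth}
    for call in junction_result.calls:
        truth = by_pos[call.head_junction]
        if truth.zygosity == "hom":
            assert call.carrier_counts.non_insertion == 0
        else:
            half = default_fixture.depth / 2 * (
                default_fixture.read_len - 40 + 1 - len(call.tsd)
            ) / default_fixture.read_len
            assert 0 < call.carrier_counts.non_insertion < 3 * half
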