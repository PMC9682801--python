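import pytest
from hypothesis import HealthCheck, settings

from tefinder import (build_index, make_fixture, run_junction_method,
                      run_tsd_method, slice_kmers)
from tefinder.model import HETEROZYGOUS, HOMOZYGOUS, SAMPLE_A, SAMPLE_B

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

FIXTURE_SEED = 1


def truth_keys(truth):
    """Comparable key set for truth records (genotype spelled out)."""
    geno = {"hom": HOMOZYGOUS, "het": HETEROZYGOUS}
    return {
        (t.contig, t.expected_head_junction, t.expected_tail_junction, t.tsd,
         t.sample, geno[t.zygosity], t.expected_head, t.expected_tail)
        for t in truth
    }


def call_keys(calls):
    return {
        (c.contig, c.head_junction, c.tail_junction, c.tsd, c.carrier,
         c.genotype, c.head, c.tail)
        for c in calls
    }


@pytest.fixture(scope="session")
def default_fixture():
    """The default study conditions: 100 kb genome, 4 kb TE, 5+3 insertions,
    5-base TSDs, 30x error-free reads."""
    return make_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def default_index(default_fixture):
    return build_index(default_fixture.reference)


@pytest.fixture(scope="session")
def catalogs40(default_fixture):
    a = slice_kmers(default_fixture.reads_a, 40, SAMPLE_A)
    b = slice_kmers(default_fixture.reads_b, 40, SAMPLE_B)
    return a, b


@pytest.fixture(scope="session")
def junction_result(default_fixture, default_index, catalogs40):
    a, b = catalogs40
    return run_junction_method(default_fixture.reads_a,
                               default_fixture.reads_b, default_index,
                               catalog_a=a, catalog_b=b)


@pytest.fixture(scope="session")
def tsd_result(default_fixture, default_index, catalogs40):
    a, b = catalogs40
    return run_tsd_method(default_fixture.reads_a, default_fixture.reads_b,
                          default_fixture.tsd_len, default_index,
                          catalog40_a=a, catalog40_b=b)


@pytest.fixture(scope="session")
def small_fixture():
    """A cheaper fixture for pipeline-shaped unit tests."""
    return make_fixture(seed=3, genome_len=20_000, te_len=600, n_a=2, n_b=1,
                        depth=25)
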