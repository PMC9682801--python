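"""Synthetic two-sample fixtures with engineered TE transpositions.

The generator emulates the minimal situation both algorithms exploit: a
reference genome carrying one resident copy of a TE, and two samples whose
genomes are that reference plus new insertions at sample-private sites,
each flanked by an exact target-site duplication. Reads are uniform,
error-free and drawn from both strands — the algorithms use exact k-mer
matching with no mismatch tolerance, so sequencing errors only shrink
counts without changing the logic being tested.

Every engineered insertion is described by a :class:`~tefinder.model.TruthRecord`
so that pipeline output can be compared to ground truth field by field.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import write_fasta, write_fastq
from .model import SAMPLE_A, SAMPLE_B, TruthRecord
from .reference import write_config

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

HOM = "hom"
HET = "het"


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def make_genome(length: int, gc: float = 0.5, seed: int = 0,
                spikes: Sequence[tuple[int, str]] = ()) -> str:
    """Reproducible random genome of *length* bases at the given GC content.

    ``spikes`` inserts literal low-complexity runs (position, sequence) by
    overwriting — useful for exercising the simple-repeat filter.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10000")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    rng = _rng(seed, 0)
    seq = "".join(BASES[rng.choice(4, size=length, p=p)])
    for pos, run in spikes:
        seq = seq[:pos] + run + seq[pos + len(run):]
    return seq[:length]


def make_te(length: int, ltr_len: Optional[int] = None, tg_ca: bool = True,
            seed: int = 0) -> str:
    """A random element, optionally with identical long terminal repeats.

    With ``tg_ca`` the element carries the retrotransposon terminal
    consensus (starts TG, ends CA); with ``ltr_len`` its first and last
    ``ltr_len`` bases are identical direct repeats, which makes the end
    detection fire twice per element, as real LTR elements do.
    """
    if length < 100:
        raise ValueError("TE length must be >= 100")
    rng = _rng(seed, 1)
    if ltr_len is not None:
        if ltr_len >= length / 2:
            raise ValueError("ltr_len must be < length/2")
        ltr = "".join(BASES[rng.choice(4, size=ltr_len)])
        if tg_ca:
            ltr = "TG" + ltr[2:-2] + "CA"
        core = "".join(BASES[rng.choice(4, size=length - 2 * ltr_len)])
        return ltr + core + ltr
    seq = "".join(BASES[rng.choice(4, size=length)])
    if tg_ca:
        seq = "TG" + seq[2:-2] + "CA"
    return seq


@dataclass(frozen=True)
class PlannedInsertion:
    te_id: str
    pos: int          # 1-based first duplicated base in reference coordinates
    tsd_len: int
    zygosity: str     # 'hom' | 'het'
    sample: str       # 'A' | 'B'


def insertion_truth(reference: str, te: str, plan: PlannedInsertion,
                    contig: str = "chr1") -> TruthRecord:
    """Expected junctions for one planned insertion.

    The ``tsd_len`` bases starting at ``pos`` are duplicated: the head
    junction is the last base of the upstream copy (``pos + tsd_len - 1``)
    and the tail junction is the first duplicated base (``pos``).
    """
    tsd = reference[plan.pos - 1 : plan.pos - 1 + plan.tsd_len]
    return TruthRecord(
        te_id=plan.te_id, contig=contig, insertion_pos=plan.pos, tsd=tsd,
        zygosity=plan.zygosity, sample=plan.sample,
        expected_head=te[:20], expected_tail=te[-20:],
        expected_head_junction=plan.pos + plan.tsd_len - 1,
        expected_tail_junction=plan.pos,
    )


def apply_insertions(reference: str, te_by_id: dict[str, str],
                     insertions: Sequence[PlannedInsertion]) -> str:
    """Insert elements into one haplotype sequence.

    The inserted allele is ``ref[..pos+tsd_len-1] + TE + ref[pos..]`` so the
    target-site bases appear once before the element and once after it.
    Overlapping insertions are rejected.
    """
    spans = sorted((p.pos, p.pos + p.tsd_len - 1, p) for p in insertions)
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if s2 <= e1 + 1:
            raise ValueError(f"overlapping insertions at {s1} and {s2}")
    seq = reference
    for _, _, plan in reversed(spans):
        te = te_by_id[plan.te_id]
        cut = plan.pos + plan.tsd_len - 1  # 1-based last duplicated base
        seq = seq[:cut] + te + seq[plan.pos - 1:]
    return seq


def insert_te(genome: str, te: str, pos: int, tsd_len: int,
              zygosity: str = HOM, sample: str = SAMPLE_A,
              te_id: str = "TE1", contig: str = "chr1"
              ) -> tuple[tuple[str, str], TruthRecord]:
    """Single-insertion convenience: returns both haplotypes and the truth.

    Heterozygous insertions keep one unmodified haplotype.
    """
    if pos < 1 or pos + tsd_len - 1 > len(genome):
        raise ValueError("insertion does not fit the genome")
    plan = PlannedInsertion(te_id, pos, tsd_len, zygosity, sample)
    inserted = apply_insertions(genome, {te_id: te}, [plan])
    hap2 = inserted if zygosity == HOM else genome
    return (inserted, hap2), insertion_truth(genome, te, plan, contig)


def simulate_reads(haplotypes: Sequence[tuple[str, float]], depth: float,
                   read_len: int, seed: int = 0, stream: int = 7,
                   error_rate: float = 0.0) -> list[str]:
    """Uniform reads from both strands of weighted haplotypes.

    ``depth`` is the total fold-coverage across haplotypes; each haplotype
    receives ``depth * weight``. ``error_rate`` introduces independent
    base substitutions (default 0: the exact-match k-mer logic has no
    mismatch tolerance, so errors only shrink counts). Read length below
    40 leaves the junction method blind (it slices 40-mers), hence the
    warning.
    """
    import warnings

    if read_len < 40:
        warnings.warn("read length < 40 makes 40-mer junction slicing "
                      "impossible")
    rng = _rng(seed, stream)
    reads: list[str] = []
    comp = str.maketrans("ACGT", "TGCA")
    for seq, weight in haplotypes:
        n = int(round(depth * weight * len(seq) / read_len))
        starts = rng.integers(0, len(seq) - read_len + 1, size=n)
        flips = rng.integers(0, 2, size=n)
        for start, flip in zip(starts, flips):
            r = seq[start : start + read_len]
            if flip:
                r = r.translate(comp)[::-1]
            if error_rate > 0:
                sites = np.nonzero(rng.random(read_len) < error_rate)[0]
                if sites.size:
                    chars = list(r)
                    for i in sites:
                        choices = [b for b in "ACGT" if b != chars[i]]
                        chars[i] = choices[int(rng.integers(0, 3))]
                    r = "".join(chars)
            reads.append(r)
    return reads


@dataclass
class Fixture:
    """A complete two-sample test case with ground truth."""

    reference: dict[str, str]
    te: str
    reads_a: list[str]
    reads_b: list[str]
    truth: list[TruthRecord]
    tsd_len: int
    depth: float
    read_len: int
    seed: int


def _choose_sites(reference: str, te: str, rng: np.random.Generator, n: int,
                  tsd_len: int, resident_span: tuple[int, int],
                  left_base: str, right_base: str,
                  margin: int = 2000, min_gap: int = 600) -> list[int]:
    """Rejection-sample insertion positions with unambiguous target sites.

    Sites keep a margin from contig ends and from each other, and each TSD
    is distinct from every other chosen TSD. Two further conditions exclude
    the shifted-junction degeneracy — a base outside the TSD equal to a TE
    terminal base, or a TSD edge base equal to a base adjacent to the
    resident copy, makes one event legitimately surface as several shifted
    calls, which the detection deliberately does not collapse — so that
    expected output equals the truth table exactly:

    * the base left of the TSD must differ from the TE's last base, and the
      base right of it from the TE's first base;
    * the TSD's last base must differ from the base preceding the resident
      copy, and its first base from the base following it.
    """
    chosen: list[int] = []
    tsds: set[str] = set()
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place insertions; genome too small?")
        pos = int(rng.integers(margin, len(reference) - margin - tsd_len))
        if resident_span[0] - min_gap <= pos <= resident_span[1] + min_gap:
            continue
        if any(abs(pos - p) < min_gap for p in chosen):
            continue
        tsd = reference[pos - 1 : pos - 1 + tsd_len]
        if reference[pos - 2] == te[-1]:          # base left of the TSD
            continue
        if reference[pos - 1 + tsd_len] == te[0]:  # base right of the TSD
            continue
        if tsd_len > 0:
            if tsd in tsds:
                continue
            if tsd[-1] == left_base or tsd[0] == right_base:
                continue
        chosen.append(pos)
        tsds.add(tsd)
    return chosen


def make_fixture(seed: int = 0, genome_len: int = 100_000, te_len: int = 4_000,
                 n_a: int = 5, n_b: int = 3, tsd_len: int = 5,
                 depth: float = 30.0, read_len: int = 100,
                 zygosity_a: Sequence[str] | None = None,
                 zygosity_b: Sequence[str] | None = None,
                 ltr_len: Optional[int] = None) -> Fixture:
    """The default study conditions: one active element, two samples.

    A 100 kb random genome carries one resident TE copy (so element ends
    map on the reference); sample A receives ``n_a`` new insertions and
    sample B ``n_b``, at disjoint sites with distinct ``tsd_len``-base
    TSDs, in a mix of homozygous and heterozygous states; both samples are
    sequenced to ``depth`` with uniform error-free reads.
    """
    base = make_genome(genome_len, seed=seed)
    te = make_te(te_len, ltr_len=ltr_len, tg_ca=True, seed=seed)
    resident_cut = genome_len // 2
    reference = base[:resident_cut] + te + base[resident_cut:]
    # bases adjacent to the resident copy, reference coordinates
    left_base = reference[resident_cut - 1]
    right_base = reference[resident_cut + te_len]
    resident_span = (resident_cut + 1, resident_cut + te_len)

    rng = _rng(seed, 2)
    sites = _choose_sites(reference, te, rng, n_a + n_b, tsd_len,
                          resident_span, left_base, right_base)
    if zygosity_a is None:
        zygosity_a = [HOM, HOM, HOM, HET, HET][:n_a] or []
        zygosity_a = list(zygosity_a) + [HOM] * (n_a - len(zygosity_a))
    if zygosity_b is None:
        zygosity_b = [HOM, HOM, HET][:n_b] or []
        zygosity_b = list(zygosity_b) + [HOM] * (n_b - len(zygosity_b))

    plans: list[PlannedInsertion] = []
    for i, pos in enumerate(sites[:n_a]):
        plans.append(PlannedInsertion("TE1", pos, tsd_len, zygosity_a[i],
                                      SAMPLE_A))
    for i, pos in enumerate(sites[n_a:]):
        plans.append(PlannedInsertion("TE1", pos, tsd_len, zygosity_b[i],
                                      SAMPLE_B))

    te_by_id = {"TE1": te}
    truth = [insertion_truth(reference, te, p) for p in plans]

    reads = {}
    for stream, sample in ((3, SAMPLE_A), (4, SAMPLE_B)):
        own = [p for p in plans if p.sample == sample]
        hap1 = apply_insertions(reference, te_by_id, own)
        hap2 = apply_insertions(reference, te_by_id,
                                [p for p in own if p.zygosity == HOM])
        reads[sample] = simulate_reads([(hap1, 0.5), (hap2, 0.5)], depth,
                                       read_len, seed=seed, stream=stream)
    logger.info("fixture: %d+%d insertions, %d/%d reads",
                n_a, n_b, len(reads[SAMPLE_A]), len(reads[SAMPLE_B]))
    return Fixture(reference={"chr1": reference}, te=te,
                   reads_a=reads[SAMPLE_A], reads_b=reads[SAMPLE_B],
                   truth=truth, tsd_len=tsd_len, depth=depth,
                   read_len=read_len, seed=seed)


def write_fixture(fixture: Fixture, outdir: str | Path,
                  compress: bool = False) -> dict[str, Path]:
    """Write reference, config, FASTQs and the truth table to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if compress else ""
    paths = {
        "reference": outdir / "reference.fasta",
        "config": outdir / "reference.fasta.config",
        "reads_a": outdir / f"sample_A.fastq{suffix}",
        "reads_b": outdir / f"sample_B.fastq{suffix}",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(paths["reference"], fixture.reference)
    if not paths["config"].exists():
        write_config(list(fixture.reference), paths["config"])
    write_fastq(paths["reads_a"], fixture.reads_a, "A")
    write_fastq(paths["reads_b"], fixture.reads_b, "B")
    fields = [f.name for f in dataclasses.fields(TruthRecord)]
    with open(paths["truth"], "w", newline="\n") as out:
        out.write("\t".join(fields) + "\n")
        for rec in fixture.truth:
            out.write("\t".join(str(getattr(rec, f)) for f in fields) + "\n")
    return paths
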