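# tefinder

Finding **actively transposing transposable elements (TEs)** from
whole-genome short reads of **two samples**, with no TE reference library
and (optionally) no reference genome.

Most TE-insertion callers need a curated library of element sequences and
paired-end mapping. `tefinder` instead exploits the one footprint nearly
every retrotransposon and DNA transposon leaves behind: on integration,
the target site is duplicated, so the new locus reads

```
...upstream flank [TSD] | TE head ...... TE tail | [TSD] downstream flank...
```

A fresh transposition therefore creates junction sequences that exist in
one sample's reads and not the other's. Comparing the complete k-mer
catalogs of two samples — a mutant and its progenitor, two cultivars, two
recombinant lines — isolates exactly those junctions, and from them the
element's first and last 20 bases (its *head* and *tail*), the TSD at each
insertion, the insertion coordinates and the genotype. Intended users are
plant/animal genomicists studying TE mobilisation (tissue culture, stress,
hypomethylation mutants) who want to discover *which* elements moved, not
just re-map known ones.

## The two algorithms

Let `H`/`T` be the unknown 20-base head/tail of an active element and `s`
a TSD (typically 3–10 bp).

**TSD method** (reference-free; fixed TSD length `t`). Slice every
(20+t)-mer from both samples' reads, sort, count, and keep the
sample-specific ones. Read each specific (20+t)-mer both as `s + H` and as
`T + s`. A genuine pair (H, T) is supported by TSD `s` when `s+H` and
`T+s` co-occur in the same sample; pairs need ≥ 2 distinct supporting TSDs
and a fraction of sample-private TSDs above a threshold (default > 0.7):

```
specificity(H,T) = |tsds_A Δ tsds_B| / |tsds_A ∪ tsds_B|
```

**Junction method** (default; needs a reference genome). Slice
sample-specific 40-mers; map both 20-mer halves. A half that maps
uniquely while its neighbour does not sit immediately adjacent marks a
junction: the mapped half is genomic flank, the other half a TE end
candidate (which must itself occur somewhere in the reference — an element
wholly absent from the reference is invisible to this method). A head
junction at `h` (last base of the upstream flank, `h = flank_start + 20 − 1`)
and a tail junction at `j` pair when

```
tsd_len = h − j + 1  ∈  [3, 16]
```

and the reference substring `[j, h]`, the upstream-flank suffix and the
downstream-flank prefix are the same string. Simple-repeat ends
(mononucleotide run ≥ 10, or ≥ 9 tandem copies of AC/AG/AT/TC/TG) are
excluded.

**Verification and genotyping** (shared). Each candidate locus is reduced
to three probes counted in both samples' 40-mer catalogs, in both
orientations: `upstream_flank + head`, `tail + downstream_flank`, and the
reconstructed pre-insertion locus (flanks joined with one TSD copy
removed). A call is accepted when the carrier shows both junctions
(≥ 1 read each), the junctions are absent from the other sample, and the
other sample shows ≥ 2 wild-type reads; the carrier's own wild-type count
decides heterozygous (≥ 1) vs homozygous (0). Element size is estimated
from the resident copy's end coordinates as `tail_start + 20 − head_start`,
and pairs starting `TG` and ending `CA` are flagged with the LTR
retrotransspon terminal consensus.

## Worked example

Generate a synthetic study (100 kb genome with a resident 4 kb element,
5 new insertions in sample A and 3 in sample B, 5-base TSDs, 30× error-free
reads) and run both algorithms:

```bash
tef make-fixture --outdir fixture --seed 1
tef run --a fixture/sample_A.fastq --b fixture/sample_B.fastq \
        --ref fixture/reference.fasta --tsd-size 5 \
        --workdir work --out out
# junction: 1 TE end pairs, 8 verified insertions -> out/junction_calls.tsv
# tsd: 1 TE end pairs, 8 verified insertions -> out/tsd_calls.tsv
```

`out/junction_pairs.tsv` — one detected active element, all eight TSDs
sample-private (specificity 1.0), resident copy 4000 bp, TG..CA ends:

```
head                  tail                  n_tsd_a  n_tsd_b  specificity  te_length  tg_ca
TGAATTTATCACTATTGGGT  AAAGGATATGAATCCCCGCA  5        3        1.0          4000       True
```

`out/junction_calls.tsv` (selected columns) — every insertion with its
junction coordinates (`head_junction − tail_junction + 1 = 5`, the TSD
length), carrier sample, genotype and read support; homozygous carriers
have zero wild-type (`non_insertion`) reads at the locus, heterozygous
carriers about half depth:

```
contig  head_junction  tail_junction  tsd    carrier  genotype      upstream_head_a  non_insertion_a  non_insertion_b
chr1    6978           6974           CTCTG  A        homozygous    21               0                22
chr1    7801           7797           CACCC  B        homozygous    0                17               0
chr1    10797          10793          CCACA  A        homozygous    15               0                14
chr1    42513          42509          AGTCA  A        heterozygous  15               4                17
...
```

The TSD method (`out/tsd_calls.tsv`) reports the identical pair and call
tables, without needing the reference for discovery. Sorted k-mer catalogs
are persisted under `--workdir` and reused on re-runs; on first use with a
new reference a contig-list config is written next to the FASTA (rename a
contig to `NOP` to exclude it) and the run stops for review.

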