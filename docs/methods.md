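# Methods

## Model

A transposition event copies (class I) or moves (class II) an element into
a new genomic site and, for nearly all such elements, duplicates the
3–10 bp target site so that identical TSD copies flank the new insertion.
`tefinder` treats the element's first and last 20 bases as its identity
(head/tail) and detects transposition purely from the novel junction
sequences the event writes into one sample's genome and not the other's.
Consequences of the model, inherited as hard limitations: elements that
make no TSD (many non-LTR retrotransposons, Helitrons) or whose TSD has
mutated are undetectable; an element resident at the same site in both
samples is deliberately invisible (its junctions are shared); excisions
are not detected; and the junction method additionally requires the
element's end 20-mers to occur somewhere in the reference genome — an
element entirely absent from the reference can only be found by the
reference-free TSD method.

Coordinates are 1-based and fully closed everywhere; the head junction is
the last base of the upstream TSD copy and the tail junction the first
base of the downstream copy, so `head_junction − tail_junction + 1`
equals the TSD length. BED export converts to 0-based half-open at the
boundary only.

## Catalogs and sample-specific k-mers

Reads (single- or paired-end, pooled as single reads) are sliced into
k-mers with a 1-base step; windows containing non-ACGT characters are
skipped, and quality strings are ignored. Catalogs are strand-naive: reads
enter as sequenced, and reverse-complement reconciliation happens during
classification, probe counting and pair reporting. Sorting/counting runs
through an external merge sort whose memory is bounded by a chunk size
(default 4 M distinct k-mers per spill), with sorted chunk files on disk;
the merged catalogs are persisted as plain `SEQ<TAB>COUNT` text under the
working directory, keyed by a checksum of the input files, and reused
across runs — rerunning, adding the TSD method after a junction run, or
resuming after interruption skips the dominant cost. Membership in the
sample-specific sets is by sequence only; counts are kept for evidence.
An optional exact-duplicate read cap (off by default) can down-weight PCR
duplicates; it is a deliberately crude whole-read filter, not a bias
model.

## Reference index

All 20-mers of every unmasked contig are indexed on both strands;
reverse-strand occurrences are stored under the reverse complement with
the forward coordinate, so one dictionary probe answers both strands. A
20-mer with two or more sites in total (counting a forward and a reverse
hit separately, and therefore also palindromes) is *ambiguous*: ambiguous
flanks never enter junction pairing but are reported in a side table of
repetitive-locus candidates. The index is persisted and invalidated by a
checksum of FASTA content plus config, and the config file (one contig
name per line, `NOP` = ignore) is created on first use, never overwritten.

## Design choices where the design was open

* **Specificity ratio (TSD method).** The filter keeps pairs whose TSD
  repertoires differ between samples. We define specificity as the
  fraction of TSDs private to either sample,
  `|A Δ B| / |A ∪ B|` (> 0.7 by default). The alternative reading —
  the larger single-sample private fraction — wrongly rejects the common
  situation of one element inserting at disjoint sites in both samples
  (5 + 3 disjoint TSDs gives 5/8 = 0.625), which is precisely the
  signature of an active element; the symmetric-difference form gives 1.0
  there and 0 for identical repertoires.
* **TSD evidence is per-sample.** A TSD supports a pair only when it
  adjoins the head and the tail in the *same* sample: one transposition
  writes both junctions into one genome. Junction pairing is likewise
  restricted to observations from one sample.
* **TE-end half must map.** A 40-mer yields a junction observation only
  when its flank half maps uniquely (forward strand, after canonical
  re-orientation) *and* its TE-end half has at least one genomic match at
  a non-adjacent site. Besides matching the method's stated inability to
  see elements missing from the reference, this suppresses shifted
  pseudo-junctions in which part of the TSD masquerades as element
  sequence.
* **Orientation canonicalisation.** Every specific 40-mer is classified in
  both orientations and observations carry forward-strand coordinates, so
  a junction covered on both strands accumulates one observation with the
  summed count. Head/tail pairs that are reverse complements of each other
  are merged at reporting time (lexicographically smaller head wins, the
  mate recorded in a cross-reference column, TSD sets mapped through the
  reverse complement); calls keep genome-forward orientation.
* **Non-insertion probe.** The wild-type probe is the two 20-base flanks
  joined with one TSD copy removed — `40 − tsd_len` bases. It is counted
  as a *prefix* of the sorted 40-mer catalog (both orientations), i.e.
  over read windows that begin with it. This keeps verification identical
  for both algorithms and independent of the reference; a full 40-base
  probe would require reference extension and would break reference-free
  operation. Junction probes are exact 40-mers; a palindromic probe is
  counted once per occurrence.
* **Multiple counting is flagged, not collapsed.** When bases adjacent to
  the target site coincide with the element's terminal bases, one event
  legitimately appears as several calls with shifted junctions and TSD
  lengths. Calls whose TSD intervals overlap are flagged
  (`overlap_flag`), never merged.
* **Repetitive-target flag.** A wild-type count in the non-carrier above
  3× that sample's median 40-mer count (a robust proxy for single-copy
  depth) marks the locus as highly repetitive. The factor is a heuristic
  default, exposed as a parameter.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `tsd_size` | — | fixed TSD length for the TSD method (bases); values ≤ 3 warned — too few distinct TSD strings |
| `specificity_threshold` | 0.7 | minimum sample-private TSD fraction (strict >) |
| `min_tsd_kinds` | 2 | distinct TSDs required per head/tail pair |
| `tsd_min`, `tsd_max` | 3, 16 | admitted TSD lengths in junction pairing |
| `min_junction_reads` | 1 | carrier support per junction probe |
| `min_noninsertion_other` | 2 | wild-type reads required in the other sample |
| `max_other_junction_reads` | 0 | junction probes must be absent from the non-carrier (strict) |
| `mono_repeat`, `di_repeat` | 10, 9 | simple-repeat caps on candidate ends |
| `repeat_depth_factor` | 3.0 | repetitive-locus flag threshold (× median depth) |
| `end_k` | 20 | flank / TE-end length; 40-mer slicing is `2 × end_k` |

## Synthetic data: what it emulates and what it does not

The generator builds a uniform-random genome (default 100 kb, GC 0.5)
carrying one resident copy of a random element (default 4 kb, TG..CA
ends, optional LTRs), then plants new insertions (default 5 in sample A,
3 in B; mixed homozygous/heterozygous) with exact TSDs and samples
uniform, error-free reads from both strands of both haplotypes at 30×
total per sample. Insertion sites are rejection-sampled so that TSDs are
mutually distinct and no site sits in a junction-ambiguous configuration
(a TSD edge base equal to a base adjacent to the resident copy, or a base
outside the TSD equal to a TE terminal base); this makes "recover the
truth table exactly, with zero extra calls" a well-defined check rather
than one confounded by the legitimate multiple-counting behaviour, which
is exercised separately through the overlap flag. Defaults keep a full
two-method run around half a minute on one CPU.

Deliberately not modelled: sequencing errors and indels (exact-match
k-mer logic means errors only shrink counts; an error knob exists but
defaults to 0), non-uniform coverage, PCR duplicates, paired-end insert
sizes, nested/overlapping insertions, TSD mutation. Passing tests on this
fixture therefore demonstrate the correctness of the algorithms' logic
and arithmetic, not robustness to noisy or repeat-rich real genomes,
where depth ≥ 20× per sample and the repetitive-locus reporting become
important in practice.

## Numerical and procedural details

Determinism is a contract: catalogs are independent of read order;
classification work is sharded by 2-base k-mer prefix and merged in shard
order, so worker count never changes output; all tables are sorted
(config-file contig order, then position; pairs by descending TSD-union
size, then head) and written with fixed formats — re-runs, resumed runs
and different `--threads` produce byte-identical files. Degenerate inputs:
reads shorter than k contribute nothing (an entirely empty catalog
warns); contigs shorter than 20 are skipped with a warning; a malformed
FASTQ record aborts with its record index; `A == B` self-comparison
yields empty output by construction. All randomness in the generator
flows from a single integer seed through independent named streams.
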