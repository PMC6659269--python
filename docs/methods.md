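# Methods

This note documents the algorithms, the parameter defaults and the numerical
conventions implemented in `splicemap`, the design decisions taken where the
design was genuinely open, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Seeding

The lookup table indexes the reads, not the genome. Every `word_size`-base
word (default 16) of every read is recorded for both the read and its
reverse complement, so the reference is scanned exactly once on its plus
strand; alignments found through reverse-complement words are reported with
the SAM reverse flag, and all read coordinates of such alignments refer to
the reverse-complemented sequence (matching how SAM stores minus-strand
records).

Masking:

* **Poly-A.** Words with at least `word_size − 1` A's or T's (15-of-16 at
  the default) are never indexed. The threshold scales with the word size
  and can be overridden.
* **Repeats.** Words occurring more than `max_db_word_count` times
  (default 60) on the reference plus strand are removed from the index.
  Only words already present in the reads are counted, which keeps the
  counting pass linear in the genome with a small constant. Because both
  read orientations are indexed, reverse-complement repeats are caught
  through the read-side entries without double counting.
* **N handling.** Words containing N are not indexed, and N never counts as
  a match during extension. This is the conservative choice.

Word hits on the same (read, reference, strand, diagonal) are merged and
extended to the maximal exact run; runs of at least `seed_len` bases
(default 18) become seeds. The 18-base extension is applied to a single
maximal run, not to unions of adjacent hits. Coordinates are 0-based
half-open internally and 1-based in SAM output.

## Greedy gapped extension

Extension proceeds rightward from the seed end; the left side runs the same
machine on the reversed prefixes (the operation table is symmetric under
this mirroring, and nothing in the scheme distinguishes directions). At a
mismatch, the rules are tried strictly in table order:

| operation | length | required matches | allowed mismatches |
|---|---|---|---|
| substitution | 1 | 9 | 0 |
| insertion | 1 | 10 | 0 |
| deletion | 1 | 10 | 0 |
| insertion | 2 | 10 | 0 |
| deletion | 2 | 10 | 0 |
| insertion | 3 | 13 | 0 |
| deletion | 3 | 13 | 0 |
| substitution | 2 | 12 | 0 |
| insertion | 1 | 10 | 2 |
| deletion | 1 | 10 | 2 |
| insertion | 2 | 10 | 2 |
| deletion | 2 | 10 | 2 |
| insertion | 3 | 13 | 2 |
| deletion | 3 | 13 | 2 |

A requirement with `r` required matches and `m` allowed mismatches is read
as: within the window of `r + m` bases following the applied operation, at
most `m` may mismatch. This is the only reading consistent with the paired
columns of the table. When fewer than `r + m` bases remain before a
sequence end, the window truncates and the same mismatch allowance applies
to the remaining bases — forbidding events near read ends would needlessly
clip otherwise clean tails. If no rule is satisfied, a single substitution
is emitted. Substituted columns are scored by actual comparison, so a
stored score always equals recomputation from the edit script (an enforced
invariant).

Scoring: match +1, substitution −4, gap open 0, gap extension −4 per base.
The X-drop bound is the cost of the most penalised tabled operation — a
three-base gap, 12 under defaults — and is recomputed from the active
scheme if the user changes penalties. Extension stops at a sequence end or
when the running score falls more than the bound below its maximum, then
backtracks to the maximum (the rightmost position attaining it, so
equal-score extensions are kept). One local alignment is emitted per seed;
interior maxima do not split an alignment.

Indels that can slide at equal score are normalised to the upstream-most
placement in the orientation of the reference: a deletion of `ref[p:p+k]`
moves one step upstream whenever `ref[p−1] == ref[p+k−1]` (the aligned
column that hops over the gap keeps its match status, hence the score),
insertions under the mirror condition on the read. This keeps indel
reporting deterministic for downstream variant comparison.

FASTQ quality strings are carried through to SAM output but never influence
the alignment score.

## Spliced alignment

Local alignments on one read, reference and strand are clustered by locus
(reference gap ≤ `max_intron`) and chained by dynamic programming over the
collinear partial order. A segment may follow another when it advances on
both read and reference, the reference gap lies within
[`min_intron`, `max_intron`] (defaults 30 and 500,000 — chosen to bound the
search; both configurable), and any unaligned read gap is at most 10 bases.
Read overlap between neighbours is allowed and retained for junction
resolution. The chain score is the plain sum of segment scores; there is no
splice reward or penalty, so a spliced placement and a same-quality
continuous placement (a processed-pseudogene copy, say) tie exactly.

**Junction resolution.** For two read-continuous (possibly overlapping)
segments, every breakpoint in the meeting window — the read overlap
extended by 4 bases each way, the same width as the gap-repair search — is
examined. At each breakpoint the two exon candidates are re-scored
column-by-column (trimming or diagonal extension of the original segments),
and the intron's boundary dinucleotides are classified: canonical GT-AG or
CT-AC; minor GC-AG/CT-GC then AT-AC/GT-AT; anything else non-canonical.
Minor and non-canonical placements require both original segments to score
at least 50 (`splice_score_threshold`); the same gate is applied to
non-canonical sites as to minor ones, since they are rarer still.
Candidates rank by class, then re-scored quality, then upstream-most donor
position (mirroring the gap-shift convention). When no placement qualifies
the chain is split and each piece stands alone; the read's representative
is then simply its highest-scoring piece.

**Gap repair.** When 1–10 read bases between two segments are unaligned, a
GT donor (or CT for minus-strand genes) is sought within 4 bases of the
left segment's end; once fixed, the AG (AC) acceptor is sought at offsets
restoring read continuity, allowing one extra 1-base insertion or deletion
beside the junction. If the donor-first pass fails, the roles are swapped.
Offsets are tried in increasing distance from the existing alignment ends,
exact placement before the ±1 indel variants, and the first qualifying
placement is accepted. Only the canonical signal is allowed here, because
the search is sensitive enough to find spurious minor signals otherwise.

**Short reads.** For reads under 100 bases, any intron whose signal is not
canonical is removed and the alignment splits at the removed junction.

Exons shorter than the seed length cannot be captured: the anchoring word
match must lie entirely within one exon. Junction-edge reads whose short
anchor is below 18 bases therefore align partially (soft-clipped), or
occasionally overhang a base or two into the intron through chance matches.

## Pair selection and reporting

Pair score is the plain sum of the two mates' spliced-alignment scores — no
proper-pair bonus, since the scoring system gives no reason for one.
Concordance requires the same reference, opposite strands, and mate starts
within `max_pair_distance` (default 1 Mb, deliberately generous because
RNA-seq fragments span long introns; no orientation-order constraint is
imposed beyond opposite strands). The concordant combination with the
maximal pair score is primary and flagged proper; a mate that is ambiguous
alone but pinned by its partner is thereby reported unique. Without any
concordant combination, mates are selected independently.

Every mapped read gets exactly one primary record; ties break by higher
score, then fewer introns, then smaller reference coordinate. MAPQ is 60
for a sole placement, 1 for a best-of-several, 0 for ties. Up to 10
secondaries are reported (configurable). Unaligned read termini are
soft-clipped, never hard-clipped, so records always carry the full
sequence. `NM` counts substituted, inserted and deleted bases (splice `N`
gaps excluded) and is validated against base-by-base recomputation in the
test suite. The tabular format is this package's own documented column set
(query, reference, identity, coordinates, strand, score, edit distance,
intron count, compact edit string); it deliberately does not try to guess
any other tool's column order.

## The synthetic-data generator

`simulate_genome` draws i.i.d. bases with a tunable AT fraction, up to the
~80% AT of compositionally extreme protozoan genomes. `simulate_transcripts_and_reads`
plants non-overlapping multi-exon transcripts (default 6 exons of 80–300
bases, introns of 60–2,000 bases — compact desk-scale stand-ins for
vertebrate-like gene structure), writes the splice dinucleotides into the
genome (GT-AG for plus-strand genes, CT-AC for minus; an optional fraction
of GC-AG minor introns), and samples single reads or read pairs (default
100+100, fragments 220–320 bases) with i.i.d. substitutions and
geometric-length indels (mean ≈ 1.2, capped at 3 to stay within the
extension table's repertoire). Defaults cover the few-per-kb to
tens-per-kb mismatch regime of Illumina-like benchmarks. Every read records
its true genomic blocks and injected error counts in a plain-text truth
track.

Intron boundaries are re-drawn (interior bases only) when an equal-scoring
shifted canonical placement exists within 6 bases, so every simulated
intron has recoverable coordinates; without this, a handful of junctions
per genome would be genuinely ambiguous and "exact coordinate" evaluation
would not be well-defined even for a perfect aligner.

What the generator does **not** emulate: position-dependent error profiles,
quality-score correlation, coverage bias, alternative splicing,
overlapping genes, paralogy beyond what i.i.d. sequence produces, and
polymorphism between sample and reference. Passing tests on this generator
therefore demonstrate algorithmic correctness under controlled conditions,
not performance on real libraries.

## Evaluation machinery

Intron calls (one per distinct reference/donor/acceptor, support = number
of supporting primary alignments) are compared with the truth by exact
coordinates. For every minimal coverage c in 1..100 (support above 100
collapses into the top bin) the report carries TP, FP, FN, precision,
recall and F; TP(c) and FP(c) are non-increasing in c by construction.
With empty denominators, precision defaults to 0, recall to
not-applicable (NaN) when the truth is empty, and F to 0 when TP = 0 with
FP or FN positive.

Alignment categories against the truth: **exact** — fully aligned, no
clips, no edits, blocks identical to the truth; **partial** — every aligned
base inside the truth intervals; **misaligned** — any aligned base outside
them; **unmapped** otherwise. A missing exon is thus partial but an extra
exon is misaligned — an incorrect exon is the more serious defect.

The QC pass recounts mismatches base-by-base from the reference over
primary alignments only, reporting mismatches per kb aligned
(1000 · mismatches / aligned bases), the per-cycle profile (reverse-strand
records unflipped to sequencing cycles), an aligned-length histogram and
substitution identity pairs (a finer mutation taxonomy is left to the
caller; the identity pairs are sufficient to derive one). Because local
alignment censors mismatches at read ends — a terminal substitution is
trimmed by the backtrack, not aligned — the plain rate underestimates the
true per-base error rate by several percent at 100-base reads;
`interior_mismatches_per_kb` estimates the rate from interior cycles only
and recovers injected rates within sampling error. A small residual
censoring remains near splice junctions (short mismatching anchors are
more likely to be clipped than clean ones).

## Problem sizes used in the shipped checks

The acceptance script and end-to-end tests use a 1 Mb genome, 40
transcripts with 5 introns each (200 introns), and 5,000 error-free
100+100 read pairs; mismatch recovery uses 1,500 pairs at 6 substitutions
per kb over 300 kb; oracle suites run 1,000 extension instances against
full Smith–Waterman and 500 instances each against exhaustive chain
enumeration and windowed junction scans. These sizes give every stage
dense coverage (every intron ~50× supported) while keeping a full run in
tens of seconds.

In the extension-oracle instances, events are placed so they cannot slide:
a deletion whose boundary bases match (e.g. inside a homopolymer) lets the
greedy walk consume part of the following run before noticing the event,
which shortens the isolation spacing the instances are meant to guarantee
and makes greedy-vs-optimal disagreement possible by construction rather
than by defect. Slideable event placements are redrawn.

## Known limitations

* Single-pass only; no annotation-guided or two-pass splicing, by design.
* No BLAST database format, no BAM/CRAM writing (SAM text only), no
  accession fetching.
* The greedy extender is exact for isolated events with ≥13-match spacing;
  clustered events or indels longer than 3 bases fall back to chains of
  tabled operations and may score below the DP optimum — the intended
  trade-off of the method.
* Mate rescue by local re-alignment around a mapped partner is not
  implemented; an unmapped mate stays unmapped.
* Reported pair concordance uses a distance bound, not an insert-size
  model.
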