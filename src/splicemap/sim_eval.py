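"""Synthetic genomes, transcripts and reads with truth tracks, plus the
evaluation machinery for intron discovery and alignment quality.

The generator emulates the structure of an RNA-seq benchmark at desk scale:
an i.i.d. random genome with tunable AT fraction (up to the ~80% AT of
compositionally extreme genomes), multi-exon transcripts whose introns carry
GT-AG boundaries (CT-AC for minus-strand genes; a minor-signal fraction is
optional), and single or paired reads with tunable substitution and indel
rates covering the few-to-tens of mismatches per kilobase regime of real
Illumina-like data.  Every read records its true genomic placement and
injected errors, so alignments can be scored against an exact truth.

Evaluation follows standard practice for spliced aligners: introns are
compared to the truth by exact donor/acceptor coordinates, precision
p = TP/(TP+FP), recall r = TP/(TP+FN) and F = 2pr/(p+r) are reported per
minimal read-coverage threshold from 1 to 100 (a ROC over coverage), and
alignments are partitioned into exact / partial / misaligned / unmapped
against the truth intervals.  A mismatch-QC pass recounts mismatches
base-by-base from the reference over primary alignments only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

from .io_formats import SamRecord
from .seed_index import Read, ReadBatch, Reference, ReferenceSet, revcomp

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome and transcript simulation

def simulate_genome(
    length: int,
    at_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    name: str = "chr1",
) -> ReferenceSet:
    """I.i.d. random genome with P(A)+P(T) = ``at_fraction`` split evenly."""
    if not 0 < at_fraction < 1:
        raise ValueError("at_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    p = [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    seq = "".join(rng.choice(BASES, size=length, p=p))
    return ReferenceSet([Reference(name, seq)])


@dataclass(frozen=True)
class TruthIntron:
    ref_name: str
    donor_pos: int      # first intron base, 0-based
    acceptor_pos: int   # last intron base, 0-based
    strand: str

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.ref_name, self.donor_pos, self.acceptor_pos)


@dataclass
class Transcript:
    ref_name: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, increasing

    @property
    def introns(self) -> list[TruthIntron]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append(TruthIntron(self.ref_name, e1, s2 - 1, self.strand))
        return out

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class ReadTruth:
    """True placement of one simulated read on the genome plus strand."""

    read_id: str
    ref_name: str
    strand: str
    blocks: list[tuple[int, int]]  # genomic, increasing, half-open
    n_subs: int = 0
    n_indels: int = 0

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def spans_junction(self) -> bool:
        return len(self.blocks) > 1

    def junction_anchor(self) -> int:
        """Smallest exon-side anchor over the junctions this read spans
        (0 when none)."""
        if not self.spans_junction:
            return 0
        return min(e - s for s, e in self.blocks)

    @property
    def has_errors(self) -> bool:
        return self.n_subs > 0 or self.n_indels > 0


@dataclass
class TruthTrack:
    """Simulation ground truth: transcripts, their introns, per-read
    placements."""

    transcripts: list[Transcript]
    reads: dict[str, ReadTruth] = field(default_factory=dict)

    @property
    def introns(self) -> set[tuple[str, int, int]]:
        return {i.key for t in self.transcripts for i in t.introns}

    def covered_introns(self, min_anchor: int = 1) -> set[tuple[str, int, int]]:
        """Truth introns spanned by at least one read whose every aligned
        block is at least ``min_anchor`` bases."""
        out = set()
        truth_introns = self.introns
        for rt in self.reads.values():
            if not rt.spans_junction or rt.junction_anchor() < min_anchor:
                continue
            for (s1, e1), (s2, e2) in zip(rt.blocks, rt.blocks[1:]):
                key = (rt.ref_name, e1, s2 - 1)
                if key in truth_introns:
                    out.add(key)
        return out

    def write_tsv(self, stream: TextIO) -> None:
        for t in self.transcripts:
            exons = ",".join(f"{s}-{e}" for s, e in t.exons)
            stream.write(f"T\t{t.ref_name}\t{t.strand}\t{exons}\n")
        for rt in self.reads.values():
            blocks = ",".join(f"{s}-{e}" for s, e in rt.blocks)
            stream.write(
                f"R\t{rt.read_id}\t{rt.ref_name}\t{rt.strand}\t{blocks}\t{rt.n_subs}\t{rt.n_indels}\n"
            )

    @classmethod
    def read_tsv(cls, stream: TextIO) -> "TruthTrack":
        track = cls([])
        for line in stream:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "T":
                exons = [tuple(map(int, x.split("-"))) for x in parts[3].split(",")]
                track.transcripts.append(Transcript(parts[1], parts[2], exons))
            elif parts[0] == "R":
                blocks = [tuple(map(int, x.split("-"))) for x in parts[4].split(",")]
                track.reads[parts[1]] = ReadTruth(
                    parts[1], parts[2], parts[3], blocks,
                    int(parts[5]), int(parts[6]),
                )
        return track


def _signal_for(strand: str) -> tuple[str, str]:
    return ("GT", "AG") if strand == "+" else ("CT", "AC")


def _ambiguous_shift(seq: list[str], s: int, e: int, pad: int = 6) -> bool:
    """True when the intron [s, e) has an equal-scoring canonical placement
    at a shifted offset, which would make its coordinates unrecoverable."""
    n = len(seq)
    for k in range(1, pad + 1):
        if e + k + 2 <= n and seq[s : s + k] == seq[e : e + k]:
            d = "".join(seq[s + k : s + k + 2])
            a = "".join(seq[e + k - 2 : e + k])
            if (d, a) in (("GT", "AG"), ("CT", "AC")):
                return True
        if s - k >= 2 and seq[s - k : s] == seq[e - k : e]:
            d = "".join(seq[s - k : s - k + 2])
            a = "".join(seq[e - k - 2 : e - k])
            if (d, a) in (("GT", "AG"), ("CT", "AC")):
                return True
    return False


def simulate_transcripts_and_reads(
    genome: ReferenceSet,
    n_transcripts: int = 40,
    n_reads: int = 5000,
    exons_per_transcript: int = 6,
    exon_length: tuple[int, int] = (80, 300),
    intron_length: tuple[int, int] = (60, 2000),
    read_length: int = 100,
    paired: bool = True,
    fragment_length: tuple[int, int] = (220, 320),
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    indel_mean_length: float = 1.2,
    indel_max_length: int = 3,
    minor_signal_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[ReferenceSet, ReadBatch, TruthTrack]:
    """Plant multi-exon transcripts in a genome and sample reads from them.

    Splice signals are written into the genome (GT-AG for plus-strand
    transcripts, CT-AC for minus; a ``minor_signal_fraction`` of introns
    get GC-AG instead).  Intron boundaries are re-drawn when an
    equal-scoring shifted canonical placement exists, so every simulated
    intron has recoverable coordinates.  Returns the (modified) genome,
    the read batch and the truth track.

    Substitutions and indels are injected per base at the given rates;
    indel lengths are geometric (mean ~1.2, capped at 3) to stay within the
    extender's tabled repertoire.
    """
    if not (0 <= sub_rate <= 0.2 and 0 <= indel_rate <= 0.2):
        raise ValueError("error rates must be within [0, 0.2]")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    ref = genome.records[0]
    seq = list(ref.sequence)
    glen = len(seq)

    transcripts: list[Transcript] = []
    cursor = 100
    for t in range(n_transcripts):
        n_exons = exons_per_transcript
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor + int(rng.integers(50, 200))
        ok = True
        for k in range(n_exons):
            elen = int(rng.integers(exon_length[0], exon_length[1] + 1))
            if pos + elen + intron_length[1] + 10 >= glen:
                ok = False
                break
            exons.append((pos, pos + elen))
            if k < n_exons - 1:
                ilen = int(rng.integers(intron_length[0], intron_length[1] + 1))
                pos = pos + elen + ilen
        if not ok or len(exons) < 2:
            break
        tx = Transcript(ref.name, strand, exons)
        donor_di, acceptor_di = _signal_for(strand)
        for intron in tx.introns:
            s, e = intron.donor_pos, intron.acceptor_pos + 1
            d_di, a_di = donor_di, acceptor_di
            if minor_signal_fraction and rng.random() < minor_signal_fraction:
                d_di = "GC" if strand == "+" else "CT"
                a_di = "AG" if strand == "+" else "GC"
            seq[s : s + 2] = list(d_di)
            seq[e - 2 : e] = list(a_di)
            for _ in range(20):
                if not _ambiguous_shift(seq, s, e):
                    break
                interior = rng.choice(BASES, size=2)
                seq[s + 2] = str(interior[0])
                seq[e - 3] = str(interior[1])
        transcripts.append(tx)
        cursor = exons[-1][1] + 50

    genome = ReferenceSet([Reference(ref.name, "".join(seq))])
    gseq = genome.records[0].sequence

    def transcript_seq(tx: Transcript) -> str:
        s = "".join(gseq[a:b] for a, b in tx.exons)
        return s if tx.strand == "+" else revcomp(s)

    def genomic_blocks(tx: Transcript, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Map a transcript-coordinate window (on the transcript's strand)
        to genomic plus-strand blocks."""
        if tx.strand == "-":
            t_start, t_end = tx.length - t_end, tx.length - t_start
        blocks = []
        off = 0
        for a, b in tx.exons:
            lo = max(t_start, off)
            hi = min(t_end, off + (b - a))
            if lo < hi:
                blocks.append((a + lo - off, a + hi - off))
            off += b - a
        return blocks

    tx_seqs = [transcript_seq(t) for t in transcripts]
    usable = [k for k, t in enumerate(transcripts)
              if t.length >= (fragment_length[0] if paired else read_length)]
    if not usable:
        raise ValueError("no transcript long enough for the requested reads")

    reads: list[Read] = []
    track = TruthTrack(transcripts)

    def inject_errors(s: str):
        out = []
        n_subs = n_indels = 0
        i = 0
        while i < len(s):
            r = rng.random()
            if r < indel_rate:
                length = min(int(rng.geometric(1.0 / indel_mean_length)), indel_max_length)
                if rng.random() < 0.5:
                    out.extend(rng.choice(BASES, size=length))  # insertion
                    out.append(s[i])
                    i += 1
                else:
                    i += length  # deletion
                n_indels += 1
            elif r < indel_rate + sub_rate:
                base = s[i]
                choices = [b for b in "ACGT" if b != base]
                out.append(choices[int(rng.integers(3))])
                n_subs += 1
                i += 1
            else:
                out.append(s[i])
                i += 1
        return "".join(out), n_subs, n_indels

    for n in range(n_reads):
        k = usable[int(rng.integers(len(usable)))]
        tx, ts = transcripts[k], tx_seqs[k]
        if paired:
            flen = int(rng.integers(fragment_length[0], min(fragment_length[1], tx.length) + 1))
            start = int(rng.integers(0, tx.length - flen + 1))
            frag = ts[start : start + flen]
            frag_id = f"frag{n}"
            for mate, (sub, t_lo, t_hi, strand_flip) in enumerate(
                (
                    (frag[:read_length], start, start + read_length, False),
                    (revcomp(frag[-read_length:]), start + flen - read_length, start + flen, True),
                ),
                start=1,
            ):
                seq_err, n_subs, n_indels = inject_errors(sub)
                rid = f"{frag_id}/{mate}"
                strand = tx.strand if not strand_flip else ("-" if tx.strand == "+" else "+")
                blocks = genomic_blocks(tx, t_lo, t_hi)
                reads.append(Read(rid, seq_err, mate=mate, fragment_id=frag_id))
                track.reads[rid] = ReadTruth(rid, tx.ref_name, strand, blocks, n_subs, n_indels)
        else:
            start = int(rng.integers(0, tx.length - read_length + 1))
            sub = ts[start : start + read_length]
            seq_err, n_subs, n_indels = inject_errors(sub)
            rid = f"read{n}"
            blocks = genomic_blocks(tx, start, start + read_length)
            reads.append(Read(rid, seq_err))
            track.reads[rid] = ReadTruth(rid, tx.ref_name, tx.strand, blocks, n_subs, n_indels)

    return genome, ReadBatch(reads, paired=paired), track


# ---------------------------------------------------------------------------
# intron evaluation

@dataclass
class RocPoint:
    coverage: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_score: float


@dataclass
class IntronEvaluation:
    """Precision/recall/F per minimal-coverage threshold 1..100."""

    points: list[RocPoint]
    n_truth: int

    @property
    def at_coverage_1(self) -> RocPoint:
        return self.points[0]

    @property
    def best(self) -> RocPoint:
        return max(self.points, key=lambda p: p.f_score)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    # empty truth: recall (and hence F) is not applicable
    r = tp / (tp + fn) if tp + fn else float("nan")
    if np.isnan(r):
        f = float("nan")
    elif p + r > 0:
        f = 2 * p * r / (p + r)
    else:
        f = 0.0
    return p, r, f


def evaluate_introns(
    calls: Sequence,
    truth_introns: set[tuple[str, int, int]],
    max_coverage: int = 100,
) -> IntronEvaluation:
    """ROC over minimal read coverage: for each threshold c in 1..100,
    count calls with support >= c as positives; truth membership requires
    exact donor/acceptor coordinates.  Coverage above 100 collapses into
    the top bin."""
    points = []
    for c in range(1, max_coverage + 1):
        kept = [call for call in calls if min(call.support, max_coverage) >= c]
        keys = {call.key for call in kept}
        tp = len(keys & truth_introns)
        fp = len(keys - truth_introns)
        fn = len(truth_introns) - tp
        p, r, f = _prf(tp, fp, fn)
        points.append(RocPoint(c, tp, fp, fn, p, r, f))
    return IntronEvaluation(points, len(truth_introns))


# ---------------------------------------------------------------------------
# alignment evaluation

EXACT = "exact"
PARTIAL = "partial"
MISALIGNED = "misaligned"
UNMAPPED = "unmapped"


@dataclass
class AlignmentCategories:
    exact: int = 0
    partial: int = 0
    misaligned: int = 0
    unmapped: int = 0

    @property
    def total(self) -> int:
        return self.exact + self.partial + self.misaligned + self.unmapped


def _aligned_blocks(record: SamRecord) -> list[tuple[int, int]]:
    """Genomic intervals covered by M/D ops, split at N gaps."""
    blocks = []
    j = record.pos - 1
    cur_start = j
    for op, n in record.cigar_ops():
        if op in ("M", "D"):
            j += n
        elif op == "N":
            if j > cur_start:
                blocks.append((cur_start, j))
            j += n
            cur_start = j
    if j > cur_start:
        blocks.append((cur_start, j))
    return blocks


def categorize_alignment(record: SamRecord, truth: ReadTruth) -> str:
    """Classify one primary record against its read's true placement.

    Exact: fully aligned (no clips), no edits, blocks identical to truth.
    Partial: every aligned base lies within the truth intervals.
    Misaligned: any aligned base outside the truth (or wrong reference).
    """
    if record.is_unmapped:
        return UNMAPPED
    if record.rname != truth.ref_name:
        return MISALIGNED
    blocks = _aligned_blocks(record)
    clipped = any(op == "S" for op, _ in record.cigar_ops())
    nm = record.tags.get("NM", None)
    if (
        not clipped
        and nm == 0
        and blocks == truth.blocks
        and (record.is_reverse) == (truth.strand == "-")
    ):
        return EXACT
    contained = all(
        any(ts <= s and e <= te for ts, te in truth.blocks) for s, e in blocks
    )
    return PARTIAL if contained else MISALIGNED


def evaluate_alignments(
    records: Iterable[SamRecord],
    truth: TruthTrack,
) -> AlignmentCategories:
    """Category counts over primary records; reads in the truth with no
    record at all are counted unmapped."""
    cats = AlignmentCategories()
    seen = set()
    for rec in records:
        if not rec.is_primary:
            continue
        rt = truth.reads.get(rec.qname)
        if rt is None:
            continue
        seen.add(rec.qname)
        cat = categorize_alignment(rec, rt)
        setattr(cats, cat, getattr(cats, cat) + 1)
    for rid in truth.reads:
        if rid not in seen:
            cats.unmapped += 1
    return cats


# ---------------------------------------------------------------------------
# mismatch QC

@dataclass
class MismatchStats:
    total_aligned_bases: int
    total_mismatches: int
    per_cycle_mismatches: np.ndarray
    per_cycle_bases: np.ndarray
    aligned_length_hist: dict[int, int]
    substitution_pairs: dict[str, int]

    @property
    def mismatches_per_kb(self) -> float:
        if not self.total_aligned_bases:
            return 0.0
        return 1000.0 * self.total_mismatches / self.total_aligned_bases

    def interior_mismatches_per_kb(self, trim_cycles: int = 5) -> float:
        """Rate over interior sequencing cycles only.

        Local alignment censors mismatches near read ends (a terminal
        substitution is trimmed rather than aligned), biasing the plain
        rate downward; skipping the first and last few cycles removes most
        of that censoring.
        """
        mm = self.per_cycle_mismatches
        nb = self.per_cycle_bases
        last = int(np.max(np.nonzero(nb)[0])) + 1 if nb.any() else 0
        sel = slice(trim_cycles, max(trim_cycles, last - trim_cycles))
        denom = int(nb[sel].sum())
        return 1000.0 * int(mm[sel].sum()) / denom if denom else 0.0


def mismatch_qc(
    records: Iterable[SamRecord],
    reference: ReferenceSet,
    length_bin: int = 10,
    max_cycle: int = 1000,
) -> MismatchStats:
    """Recount mismatches base-by-base from the reference over primary
    mapped records; reports the rate per kb aligned, the per-cycle profile
    (cycle = position in the sequenced read, reverse records unflipped),
    an aligned-length histogram and substitution identity pairs."""
    per_cycle_mm = np.zeros(max_cycle, dtype=int)
    per_cycle_bases = np.zeros(max_cycle, dtype=int)
    hist: dict[int, int] = {}
    pairs: dict[str, int] = {}
    total_bases = 0
    total_mm = 0
    for rec in records:
        if not rec.is_primary or rec.is_unmapped:
            continue
        if rec.rname not in reference:
            raise ValueError(f"record {rec.qname!r} names unknown reference {rec.rname!r}")
        ref = reference[rec.rname]
        i = 0
        j = rec.pos - 1
        read_len = len(rec.seq)
        aligned = 0
        for op, n in rec.cigar_ops():
            if op == "M":
                for k in range(n):
                    cycle = (read_len - 1 - (i + k)) if rec.is_reverse else (i + k)
                    per_cycle_bases[cycle] += 1
                    if rec.seq[i + k] != ref[j + k]:
                        per_cycle_mm[cycle] += 1
                        total_mm += 1
                        pair = f"{ref[j + k]}>{rec.seq[i + k]}"
                        pairs[pair] = pairs.get(pair, 0) + 1
                total_bases += n
                aligned += n
                i += n
                j += n
            elif op == "I":
                i += n
                aligned += n
            elif op in ("D", "N"):
                j += n
            elif op == "S":
                i += n
        bin_ = (aligned // length_bin) * length_bin
        hist[bin_] = hist.get(bin_, 0) + 1
    return MismatchStats(
        total_aligned_bases=total_bases,
        total_mismatches=total_mm,
        per_cycle_mismatches=per_cycle_mm,
        per_cycle_bases=per_cycle_bases,
        aligned_length_hist=dict(sorted(hist.items())),
        substitution_pairs=dict(sorted(pairs.items())),
    )
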