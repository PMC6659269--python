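"""Read-side word lookup, repeat/poly-A masking, and reference scanning.

The aligner indexes fixed-length words (16 bases by default) of the *reads*,
not the genome.  Both read orientations are indexed so a single plus-strand
pass over the reference finds seeds on either strand.  Two masking rules keep
the index informative:

* words with at least ``word_size - 1`` A's (or T's) are never indexed, which
  stops seeding on poly-A tails;
* words that occur in the reference more than a cutoff number of times
  (60 by default) are dropped from the index, so interspersed repeats never
  anchor an alignment.  Only words actually present in the reads are counted,
  which keeps the reference pass cheap.

Word hits on the same read/reference diagonal are merged and extended to the
maximal exact run; runs at least ``seed_len`` bases long (18 by default)
become :class:`SeedMatch` seeds for gapped extension.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_WORD_SIZE = 16
DEFAULT_SEED_LEN = 18
DEFAULT_MAX_DB_WORD_COUNT = 60

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class EmptyInputError(ValueError):
    """Raised when an operation receives an empty read batch."""


@dataclass
class Reference:
    """A single named reference sequence."""

    name: str
    sequence: str


@dataclass
class ReferenceSet:
    """Named genome sequences with 0-based half-open coordinates.

    Sequence names must be unique; sequences are normalised to uppercase and
    restricted to the {A, C, G, T, N} alphabet.
    """

    records: list[Reference]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("reference names must be unique")
        for r in self.records:
            if not r.sequence:
                raise ValueError(f"reference {r.name!r} is empty")
            r.sequence = r.sequence.upper()
            if set(r.sequence) - set("ACGTN"):
                raise ValueError(f"reference {r.name!r} has non-ACGTN characters")
        self._by_name = {r.name: r for r in self.records}

    def __getitem__(self, name: str) -> str:
        return self._by_name[name].sequence

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[Reference]:
        return iter(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    @property
    def total_length(self) -> int:
        return sum(len(r.sequence) for r in self.records)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        """Load references from a (optionally gzipped) FASTA file."""
        return cls([Reference(rec.id, str(rec.seq)) for rec in _parse_seqs(path, "fasta")])


@dataclass
class Read:
    """One sequencing read.  ``mate`` is 0 for unpaired, 1 or 2 for pairs."""

    id: str
    sequence: str
    qualities: str | None = None
    mate: int = 0
    fragment_id: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")
        if not self.fragment_id:
            self.fragment_id = self.id


@dataclass
class ReadBatch:
    """An ordered batch of reads, optionally paired.

    In a paired batch every fragment id must appear exactly once as mate 1
    and once as mate 2.
    """

    reads: list[Read]
    paired: bool = False

    def __post_init__(self) -> None:
        if self.paired:
            mates: dict[str, set[int]] = {}
            for r in self.reads:
                mates.setdefault(r.fragment_id, set()).add(r.mate)
            for frag, seen in mates.items():
                if seen != {1, 2}:
                    raise ValueError(f"fragment {frag!r} lacks a complete mate pair")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)


@dataclass
class WordLookup:
    """Index of word occurrences in a read batch.

    ``postings`` maps each word to ``(read index, offset, strand)`` triples,
    where the offset is taken on the read's plus strand for ``+`` entries and
    on its reverse complement for ``-`` entries, so the reference only ever
    needs to be scanned on its plus strand.
    """

    word_size: int
    postings: dict[str, list[tuple[int, int, str]]]
    masked_polyA: set[str] = field(default_factory=set)
    masked_repeat: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class SeedMatch:
    """A maximal exact match anchoring gapped extension.

    Intervals are 0-based half-open and equal in length; for ``-`` strand
    seeds the read interval refers to the reverse-complemented read.
    """

    read_index: int
    read_start: int
    read_end: int
    ref_name: str
    ref_start: int
    ref_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.read_end - self.read_start != self.ref_end - self.ref_start:
            raise ValueError("seed intervals differ in length")

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_seqs(path: str | Path, fmt: str):
    with _open_text(path) as fh:
        yield from SeqIO.parse(fh, fmt)


def read_batch_from_files(
    path1: str | Path,
    path2: str | Path | None = None,
    fmt: str | None = None,
    interleaved: bool = False,
) -> ReadBatch:
    """Build a :class:`ReadBatch` from one or two FASTA/FASTQ files.

    With two files the batch is paired: record *i* of each file forms one
    fragment.  With ``interleaved`` a single file is read as consecutive
    mate-1/mate-2 record pairs.  The format is sniffed from the first
    character when not given.
    """

    def sniff(path: str | Path) -> str:
        with _open_text(path) as fh:
            first = fh.read(1)
        return "fastq" if first == "@" else "fasta"

    fmt1 = fmt or sniff(path1)
    reads: list[Read] = []
    if path2 is None and interleaved:
        recs = list(_parse_seqs(path1, fmt1))
        if len(recs) % 2:
            raise ValueError("interleaved input has an odd number of records")
        for k in range(0, len(recs), 2):
            frag = recs[k].id.removesuffix("/1").removesuffix(".1")
            for mate, rec in ((1, recs[k]), (2, recs[k + 1])):
                qual = None
                if "phred_quality" in rec.letter_annotations:
                    qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
                reads.append(Read(rec.id, str(rec.seq), qual, mate=mate, fragment_id=frag))
        return ReadBatch(reads, paired=True)
    if path2 is None:
        for rec in _parse_seqs(path1, fmt1):
            qual = None
            if "phred_quality" in rec.letter_annotations:
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(Read(rec.id, str(rec.seq), qual))
        return ReadBatch(reads, paired=False)

    fmt2 = fmt or sniff(path2)
    recs1 = list(_parse_seqs(path1, fmt1))
    recs2 = list(_parse_seqs(path2, fmt2))
    if len(recs1) != len(recs2):
        raise ValueError("paired files have different record counts")
    for rec1, rec2 in zip(recs1, recs2):
        frag = rec1.id.removesuffix("/1").removesuffix(".1")
        for mate, rec in ((1, rec1), (2, rec2)):
            qual = None
            if "phred_quality" in rec.letter_annotations:
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(Read(rec.id, str(rec.seq), qual, mate=mate, fragment_id=frag))
    return ReadBatch(reads, paired=True)


def is_polyA_masked(word: str, threshold: int | None = None) -> bool:
    """True if ``word`` has at least ``threshold`` A's or T's.

    The default threshold is ``len(word) - 1``, reproducing the 15-of-16
    rule at the default word size.
    """
    if threshold is None:
        threshold = len(word) - 1
    return word.count("A") >= threshold or word.count("T") >= threshold


def build_lookup(
    reads: ReadBatch,
    word_size: int = DEFAULT_WORD_SIZE,
    polyA_threshold: int | None = None,
) -> WordLookup:
    """Index every word of every read, in both orientations.

    Words containing N and poly-A/poly-T words are excluded.  Reads shorter
    than ``word_size`` contribute no postings (a warning is logged).
    """
    if len(reads) == 0:
        raise EmptyInputError("cannot build a lookup table from an empty read batch")
    if word_size < 8:
        raise ValueError("word_size must be at least 8")
    if polyA_threshold is None:
        polyA_threshold = word_size - 1

    postings: dict[str, list[tuple[int, int, str]]] = {}
    masked_polyA: set[str] = set()
    short_reads = 0
    for idx, read in enumerate(reads):
        if len(read.sequence) < word_size:
            short_reads += 1
            continue
        for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
            for off in range(len(seq) - word_size + 1):
                word = seq[off : off + word_size]
                if "N" in word:
                    continue
                if word in masked_polyA:
                    continue
                if is_polyA_masked(word, polyA_threshold):
                    masked_polyA.add(word)
                    postings.pop(word, None)
                    continue
                postings.setdefault(word, []).append((idx, off, strand))
    if short_reads:
        logger.warning("%d reads shorter than word size %d contributed no postings", short_reads, word_size)
    return WordLookup(word_size, postings, masked_polyA=masked_polyA)


def count_and_mask_repeats(
    lookup: WordLookup,
    reference: ReferenceSet,
    cutoff: int = DEFAULT_MAX_DB_WORD_COUNT,
) -> WordLookup:
    """Drop indexed words occurring more than ``cutoff`` times in the reference.

    Counting is restricted to words already present in the lookup; a word
    occurring exactly ``cutoff`` times is retained.  The lookup is modified
    in place and returned.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be at least 1")
    w = lookup.word_size
    counts: dict[str, int] = {}
    present = lookup.postings
    for ref in reference:
        seq = ref.sequence
        for off in range(len(seq) - w + 1):
            word = seq[off : off + w]
            if word in present:
                counts[word] = counts.get(word, 0) + 1
    for word, n in counts.items():
        if n > cutoff:
            lookup.masked_repeat.add(word)
            del lookup.postings[word]
    return lookup


def scan_reference(
    reference: ReferenceSet,
    lookup: WordLookup,
    seed_len: int = DEFAULT_SEED_LEN,
    reads: ReadBatch | None = None,
) -> list[SeedMatch]:
    """Scan the reference plus strand for lookup hits and emit seeds.

    Word hits on the same (read, reference, strand, diagonal) are merged and
    extended to the maximal exact run around the hit; runs shorter than
    ``seed_len`` are discarded.  ``reads`` must be the batch the lookup was
    built from (needed to recover read sequences for exact extension).
    """
    if reads is None:
        raise ValueError("reads batch is required for exact seed extension")
    w = lookup.word_size
    postings = lookup.postings

    read_seqs: dict[tuple[int, str], str] = {}

    def oriented(read_idx: int, strand: str) -> str:
        key = (read_idx, strand)
        seq = read_seqs.get(key)
        if seq is None:
            seq = reads.reads[read_idx].sequence
            if strand == "-":
                seq = revcomp(seq)
            read_seqs[key] = seq
        return seq

    seeds: list[SeedMatch] = []
    for ref in reference:
        rseq = ref.sequence
        # (read, strand, diagonal) -> ref_end of the last maximal run found,
        # used to skip word hits already inside an emitted run.
        seen_until: dict[tuple[int, str, int], int] = {}
        for off in range(len(rseq) - w + 1):
            hits = postings.get(rseq[off : off + w])
            if not hits:
                continue
            for read_idx, read_off, strand in hits:
                diag = off - read_off
                key = (read_idx, strand, diag)
                if seen_until.get(key, -1) >= off + w:
                    continue
                qseq = oriented(read_idx, strand)
                qs, qe = _maximal_exact_run(qseq, rseq, read_off, off, w)
                seen_until[key] = qe + diag
                if qe - qs >= seed_len:
                    seeds.append(
                        SeedMatch(read_idx, qs, qe, ref.name, qs + diag, qe + diag, strand)
                    )
    return seeds


def _maximal_exact_run(query: str, ref: str, qoff: int, roff: int, length: int) -> tuple[int, int]:
    """Extend an exact match at (qoff, roff, length) maximally in both
    directions; N never matches.  Returns the query interval."""
    qs, rs = qoff, roff
    while qs > 0 and rs > 0 and query[qs - 1] == ref[rs - 1] and query[qs - 1] != "N":
        qs -= 1
        rs -= 1
    qe, re_ = qoff + length, roff + length
    n = len(query)
    m = len(ref)
    while qe < n and re_ < m and query[qe] == ref[re_] and query[qe] != "N":
        qe += 1
        re_ += 1
    return qs, qe
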