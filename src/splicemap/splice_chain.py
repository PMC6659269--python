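"""Chaining of collinear local alignments into spliced alignments.

Local alignments on the same read, reference and strand are chained to
maximise the combined score; gaps between chained segments on the reference
become introns.  Splicing is *score neutral*: an intron carries no reward or
penalty, so a spliced placement never beats (or loses to) a continuous one
of equal base-level quality.

Junction placement follows a signal hierarchy.  Where two segments meet on
the read (possibly overlapping), every candidate breakpoint in the meeting
window is examined and the intron boundary dinucleotides are classified:

1. canonical  GT-AG (CT-AC on the minus strand) — always eligible;
2. minor      GC-AG / CT-GC and AT-AC / GT-AT — only when both segments
   score at least 50;
3. non-canonical (anything else) — same gate as the minor classes.

The highest class available wins; within a class the breakpoint with the
best re-scored boundary wins, ties resolved upstream-most on the reference.
For reads shorter than 100 bases only GT-AG introns are ever called.

When segments are separated by one to ten unaligned read bases, a repair
pass looks for a GT donor within four bases of the left segment's end (and
symmetrically an AG acceptor near the right segment's start), allowing one
extra 1-base insertion or deletion next to the junction; only GT-AG is
accepted in this situation because the search is aggressive enough to find
spurious signals otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .greedy_extend import (
    READ_CONSUMING,
    REF_CONSUMING,
    LocalAlignment,
    ScoringScheme,
    _ScriptBuilder,
)
from .seed_index import ReferenceSet

DEFAULT_MIN_SIDE_SCORE = 50
DEFAULT_MIN_INTRON = 30
DEFAULT_MAX_INTRON = 500_000
DEFAULT_SHORT_READ_THRESHOLD = 100
DEFAULT_MAX_REPAIR_GAP = 10
DEFAULT_DONOR_SEARCH_WINDOW = 4

CANONICAL = "canonical"
MINOR1 = "minor1"
MINOR2 = "minor2"
NON_CANONICAL = "non_canonical"

_CLASS_PRIORITY = {CANONICAL: 0, MINOR1: 1, MINOR2: 2, NON_CANONICAL: 3}

# (donor dinucleotide, acceptor dinucleotide) -> (class, intron genomic strand)
_SIGNALS = {
    ("GT", "AG"): (CANONICAL, "+"),
    ("CT", "AC"): (CANONICAL, "-"),
    ("GC", "AG"): (MINOR1, "+"),
    ("CT", "GC"): (MINOR1, "-"),
    ("AT", "AC"): (MINOR2, "+"),
    ("GT", "AT"): (MINOR2, "-"),
}


def classify_splice_signal(donor: str, acceptor: str) -> tuple[str, str]:
    """Classify an intron by its boundary dinucleotides on the reference
    plus strand; returns (class, intron strand).  Unrecognised signals are
    non-canonical with '.' strand."""
    return _SIGNALS.get((donor, acceptor), (NON_CANONICAL, "."))


@dataclass(frozen=True)
class Intron:
    """One intron on the reference plus strand; ``start`` is the first
    intron base (0-based), ``end`` is past the last."""

    ref_name: str
    start: int
    end: int
    signal_class: str
    strand: str

    @property
    def donor_pos(self) -> int:
        return self.start

    @property
    def acceptor_pos(self) -> int:
        """Last intron base, 0-based."""
        return self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SplicedAlignment:
    """A chain of exon-level alignments with typed introns.

    Segments are continuous on the read (segment ``k+1`` starts at the read
    position where segment ``k`` ends) and strictly increasing on the
    reference.  The total score is the plain sum of segment scores —
    splice-neutral by construction.
    """

    segments: list[LocalAlignment]
    introns: list[Intron] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a spliced alignment needs at least one segment")
        segs = self.segments
        if len({(s.read_index, s.strand, s.ref_name) for s in segs}) != 1:
            raise ValueError("segments disagree on read/reference/strand")
        for a, b in zip(segs, segs[1:]):
            if b.read_start != a.read_end:
                raise ValueError("segments are not continuous on the read")
            if b.ref_start <= a.ref_end:
                raise ValueError("segments do not advance on the reference")
        if len(self.introns) != len(segs) - 1:
            raise ValueError("intron count must be segment count minus one")

    @property
    def read_index(self) -> int:
        return self.segments[0].read_index

    @property
    def strand(self) -> str:
        return self.segments[0].strand

    @property
    def ref_name(self) -> str:
        return self.segments[0].ref_name

    @property
    def read_start(self) -> int:
        return self.segments[0].read_start

    @property
    def read_end(self) -> int:
        return self.segments[-1].read_end

    @property
    def ref_start(self) -> int:
        return self.segments[0].ref_start

    @property
    def ref_end(self) -> int:
        return self.segments[-1].ref_end

    @property
    def score(self) -> int:
        return sum(s.score for s in self.segments)

    @property
    def edit_distance(self) -> int:
        return sum(s.edit_distance for s in self.segments)

    def full_script(self) -> list[tuple[str, int]]:
        """Edit script across all segments with 'N' ops for introns."""
        ops: list[tuple[str, int]] = []
        for k, seg in enumerate(self.segments):
            if k:
                ops.append(("N", self.introns[k - 1].length))
            ops.extend(seg.script)
        return ops

    @classmethod
    def single(cls, aln: LocalAlignment) -> "SplicedAlignment":
        return cls([aln])


# ---------------------------------------------------------------------------
# segment trimming / extension helpers

def _split_segment(aln: LocalAlignment, b: int, scheme: ScoringScheme):
    """Split at read position ``b`` into (left, right) LocalAlignments.
    Terminal deletion runs created by the cut are dropped.  Either side may
    be None when empty."""
    left_cols: list[str] = []
    right_cols: list[str] = []
    i = aln.read_start
    for op, n in aln.script:
        for _ in range(n):
            (left_cols if (op in READ_CONSUMING and i < b) or
             (op == "D" and i < b) else right_cols).append(op)
            if op in READ_CONSUMING:
                i += 1
    return (
        _cols_to_alignment(aln, left_cols, aln.read_start, aln.ref_start, scheme),
        _cols_to_alignment(
            aln,
            right_cols,
            b,
            aln.ref_start + sum(1 for c in left_cols if c in REF_CONSUMING),
            scheme,
        ),
    )


def _cols_to_alignment(template, cols, read_start, ref_start, scheme):
    # trim terminal gap columns: alignments must start/end on aligned bases
    start, end = 0, len(cols)
    lead_ref_gap = 0
    while start < end and cols[start] in ("I", "D"):
        if cols[start] == "D":
            lead_ref_gap += 1
        else:
            read_start += 1
        start += 1
    while end > start and cols[end - 1] in ("I", "D"):
        end -= 1
    if start == end:
        return None
    builder = _ScriptBuilder()
    for c in cols[start:end]:
        builder.add(c, 1)
    script = builder.ops
    rlen = sum(n for op, n in script if op in READ_CONSUMING)
    flen = sum(n for op, n in script if op in REF_CONSUMING)
    aln = LocalAlignment(
        read_index=template.read_index,
        strand=template.strand,
        read_start=read_start,
        read_end=read_start + rlen,
        ref_name=template.ref_name,
        ref_start=ref_start + lead_ref_gap,
        ref_end=ref_start + lead_ref_gap + flen,
        script=script,
        score=0,
    )
    aln.score = aln.rescore(scheme)
    return aln


def _diagonal_columns(read_seq: str, ref_seq: str, i: int, j: int, n: int) -> list[str]:
    """Gapless comparison columns for read[i:i+n] vs ref[j:j+n]."""
    return [
        "=" if (read_seq[i + k] == ref_seq[j + k] and read_seq[i + k] != "N") else "X"
        for k in range(n)
    ]


def _trim_or_extend_left(aln, b, read_seq, ref_seq, scheme):
    """Left-exon candidate covering read [aln.read_start, b)."""
    if b <= aln.read_start:
        return None
    if b <= aln.read_end:
        left, _ = _split_segment(aln, b, scheme)
        return left
    extra = b - aln.read_end
    if aln.ref_end + extra > len(ref_seq):
        return None
    cols = []
    i = aln.read_start
    for op, n in aln.script:
        cols.extend([op] * n)
    cols.extend(_diagonal_columns(read_seq, ref_seq, aln.read_end, aln.ref_end, extra))
    return _cols_to_alignment(aln, cols, aln.read_start, aln.ref_start, scheme)


def _trim_or_extend_right(aln, b, read_seq, ref_seq, scheme):
    """Right-exon candidate covering read [b, aln.read_end)."""
    if b >= aln.read_end:
        return None
    if b >= aln.read_start:
        _, right = _split_segment(aln, b, scheme)
        return right
    extra = aln.read_start - b
    if aln.ref_start - extra < 0:
        return None
    cols = _diagonal_columns(read_seq, ref_seq, b, aln.ref_start - extra, extra)
    for op, n in aln.script:
        cols.extend([op] * n)
    return _cols_to_alignment(aln, cols, b, aln.ref_start - extra, scheme)


# ---------------------------------------------------------------------------
# chaining

def chain_alignments(
    locals_: list[LocalAlignment],
    scheme: ScoringScheme | None = None,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_intron: int = DEFAULT_MAX_INTRON,
    max_read_gap: int = DEFAULT_MAX_REPAIR_GAP,
) -> list[LocalAlignment]:
    """Best-scoring chain of collinear local alignments (one read, one
    reference, one strand), by dynamic programming over the partial order.

    Two segments are chainable when the later one advances on both read and
    reference, the reference gap lies within intron bounds, and any
    unaligned read gap is at most ``max_read_gap`` (read overlap is allowed
    and resolved later at the junction).  The chain score is the plain sum
    of segment scores.  Returns the segments of the best chain in order.
    """
    if not locals_:
        return []
    if scheme is None:
        scheme = ScoringScheme()
    segs = sorted(locals_, key=lambda a: (a.read_start, a.ref_start))
    n = len(segs)
    best = [s.score for s in segs]
    prev = [-1] * n
    for k in range(n):
        for p in range(k):
            if _chainable(segs[p], segs[k], min_intron, max_intron, max_read_gap):
                cand = best[p] + segs[k].score
                if cand > best[k]:
                    best[k] = cand
                    prev[k] = p
    end = max(range(n), key=lambda k: best[k])
    chain = []
    while end != -1:
        chain.append(segs[end])
        end = prev[end]
    chain.reverse()
    return chain


def _chainable(a, b, min_intron, max_intron, max_read_gap) -> bool:
    if b.read_start <= a.read_start or b.read_end <= a.read_end:
        return False
    if b.read_start - a.read_end > max_read_gap:
        return False
    ref_gap = b.ref_start - a.ref_end
    return min_intron <= ref_gap <= max_intron


# ---------------------------------------------------------------------------
# junction resolution

def resolve_junction(
    left: LocalAlignment,
    right: LocalAlignment,
    reference: ReferenceSet,
    read_seq: str,
    scheme: ScoringScheme | None = None,
    min_side_score: int = DEFAULT_MIN_SIDE_SCORE,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_intron: int = DEFAULT_MAX_INTRON,
    window_pad: int = DEFAULT_DONOR_SEARCH_WINDOW,
    canonical_only: bool = False,
):
    """Place the junction between two read-continuous (possibly overlapping)
    segments against the splice-signal hierarchy.

    Every breakpoint in the meeting window (the read overlap extended by
    ``window_pad`` bases each way) is scored; candidates are ranked by
    signal class, then re-scored boundary quality, then upstream reference
    position.  Minor and non-canonical classes require both original
    segments to score at least ``min_side_score``.  Returns
    (left', right', Intron) or None when no placement qualifies.
    """
    if scheme is None:
        scheme = ScoringScheme()
    ref_seq = reference[left.ref_name]
    lo = max(right.read_start - window_pad, left.read_start + 1)
    hi = min(left.read_end + window_pad, right.read_end - 1)
    minor_ok = (
        not canonical_only
        and left.score >= min_side_score
        and right.score >= min_side_score
    )
    best = None  # (priority, -total_score, donor_pos, L, R, intron)
    for b in range(lo, hi + 1):
        L = _trim_or_extend_left(left, b, read_seq, ref_seq, scheme)
        R = _trim_or_extend_right(right, b, read_seq, ref_seq, scheme)
        if L is None or R is None:
            continue
        intron_len = R.ref_start - L.ref_end
        if not (min_intron <= intron_len <= max_intron):
            continue
        donor = ref_seq[L.ref_end : L.ref_end + 2]
        acceptor = ref_seq[R.ref_start - 2 : R.ref_start]
        cls, strand = classify_splice_signal(donor, acceptor)
        if cls != CANONICAL and not minor_ok:
            continue
        key = (_CLASS_PRIORITY[cls], -(L.score + R.score), L.ref_end)
        if best is None or key < best[0]:
            intron = Intron(left.ref_name, L.ref_end, R.ref_start, cls, strand)
            best = (key, L, R, intron)
    if best is None:
        return None
    return best[1], best[2], best[3]


def repair_gap_junction(
    left: LocalAlignment,
    right: LocalAlignment,
    reference: ReferenceSet,
    read_seq: str,
    scheme: ScoringScheme | None = None,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_intron: int = DEFAULT_MAX_INTRON,
    search_window: int = DEFAULT_DONOR_SEARCH_WINDOW,
    max_gap: int = DEFAULT_MAX_REPAIR_GAP,
):
    """Bridge 1-10 unaligned read bases between two segments with a GT-AG
    intron (CT-AC on the minus strand).

    A donor is sought within ``search_window`` bases of the left segment's
    end; once fixed, the matching acceptor is sought at offsets that keep
    the read continuous, allowing one extra 1-base insertion or deletion
    beside the junction.  If the donor-first pass fails the roles are
    swapped.  The first qualifying placement is accepted.  Returns
    (left', right', Intron) or None.
    """
    if scheme is None:
        scheme = ScoringScheme()
    gap = right.read_start - left.read_end
    if not (1 <= gap <= max_gap):
        return None
    ref_seq = reference[left.ref_name]

    for donor_di, acceptor_di, strand in (("GT", "AG", "+"), ("CT", "AC", "-")):
        # pass 1: fix the donor near the left end, search the acceptor
        for d in range(0, search_window + 1):
            b = left.read_end + d
            if b >= right.read_end:
                break
            L = _trim_or_extend_left(left, b, read_seq, ref_seq, scheme)
            if L is None or ref_seq[L.ref_end : L.ref_end + 2] != donor_di:
                continue
            for delta in (0, 1, -1):  # 0: clean; +1: extra deletion; -1: extra insertion
                R = _right_exon_with_shift(right, b, delta, read_seq, ref_seq, scheme)
                if R is None:
                    continue
                intron_len = R.ref_start - L.ref_end
                if not (min_intron <= intron_len <= max_intron):
                    continue
                if ref_seq[R.ref_start - 2 : R.ref_start] == acceptor_di:
                    intron = Intron(left.ref_name, L.ref_end, R.ref_start, CANONICAL, strand)
                    return L, R, intron
        # pass 2: fix the acceptor near the right start, search the donor
        for d in range(0, search_window + 1):
            b = right.read_start - d
            if b <= left.read_start:
                break
            R = _trim_or_extend_right(right, b, read_seq, ref_seq, scheme)
            if R is None or ref_seq[R.ref_start - 2 : R.ref_start] != acceptor_di:
                continue
            for delta in (0, 1, -1):
                L = _left_exon_with_shift(left, b, delta, read_seq, ref_seq, scheme)
                if L is None:
                    continue
                intron_len = R.ref_start - L.ref_end
                if not (min_intron <= intron_len <= max_intron):
                    continue
                if ref_seq[L.ref_end : L.ref_end + 2] == donor_di:
                    intron = Intron(left.ref_name, L.ref_end, R.ref_start, CANONICAL, strand)
                    return L, R, intron
    return None


def _right_exon_with_shift(right, b, delta, read_seq, ref_seq, scheme):
    """Right exon starting at read ``b``; ``delta`` injects one extra 1-base
    deletion (+1) or insertion (-1) immediately after the junction."""
    if delta == 0:
        return _trim_or_extend_right(right, b, read_seq, ref_seq, scheme)
    x = right.read_start - b
    if x < 0:
        return None
    if delta == 1:  # one reference base deleted right after the acceptor
        start_ref = right.ref_start - x - 1
        if start_ref < 0:
            return None
        cols = ["D"] + _diagonal_columns(read_seq, ref_seq, b, start_ref + 1, x)
    else:  # read base b inserted right after the acceptor
        if x < 1:
            return None
        start_ref = right.ref_start - (x - 1)
        if start_ref < 0:
            return None
        cols = ["I"] + _diagonal_columns(read_seq, ref_seq, b + 1, start_ref, x - 1)
    for op, n in right.script:
        cols.extend([op] * n)
    aln = _cols_to_alignment(right, cols, b, start_ref, scheme)
    # leading gap would be trimmed away, defeating the purpose
    if aln is None or aln.read_start != b:
        return None
    if delta == 1 and aln.ref_start != start_ref:
        return None
    return aln


def _left_exon_with_shift(left, b, delta, read_seq, ref_seq, scheme):
    """Left exon ending at read ``b``; ``delta`` injects one extra 1-base
    deletion (+1) or insertion (-1) immediately before the junction."""
    if delta == 0:
        return _trim_or_extend_left(left, b, read_seq, ref_seq, scheme)
    x = b - left.read_end
    if x < 0:
        return None
    cols = []
    for op, n in left.script:
        cols.extend([op] * n)
    if delta == 1:
        cols.extend(_diagonal_columns(read_seq, ref_seq, left.read_end, left.ref_end, x))
        cols.append("D")
    else:
        if x < 1:
            return None
        cols.extend(_diagonal_columns(read_seq, ref_seq, left.read_end, left.ref_end, x - 1))
        cols.append("I")
    aln = _cols_to_alignment(left, cols, left.read_start, left.ref_start, scheme)
    if aln is None or aln.read_end != b:
        return None
    if delta == 1 and aln.ref_end != left.ref_end + x + 1:
        return None
    return aln


# ---------------------------------------------------------------------------
# chain finalisation and policies

def finalize_chain(
    chain: list[LocalAlignment],
    reference: ReferenceSet,
    read_seq: str,
    scheme: ScoringScheme | None = None,
    min_side_score: int = DEFAULT_MIN_SIDE_SCORE,
    min_intron: int = DEFAULT_MIN_INTRON,
    max_intron: int = DEFAULT_MAX_INTRON,
    canonical_only: bool = False,
) -> list[SplicedAlignment]:
    """Resolve every junction of a chain; where a junction cannot be placed
    the chain is split and each piece reported separately."""
    if scheme is None:
        scheme = ScoringScheme()
    if not chain:
        return []
    pieces: list[SplicedAlignment] = []
    cur_segments = [chain[0]]
    cur_introns: list[Intron] = []
    for nxt in chain[1:]:
        left = cur_segments[-1]
        gap = nxt.read_start - left.read_end
        if gap <= 0:
            result = resolve_junction(
                left, nxt, reference, read_seq, scheme,
                min_side_score=min_side_score, min_intron=min_intron,
                max_intron=max_intron, canonical_only=canonical_only,
            )
        else:
            result = repair_gap_junction(
                left, nxt, reference, read_seq, scheme,
                min_intron=min_intron, max_intron=max_intron,
            )
        if result is None:
            pieces.append(SplicedAlignment(cur_segments, cur_introns))
            cur_segments, cur_introns = [nxt], []
            continue
        L, R, intron = result
        cur_segments[-1] = L
        cur_segments.append(R)
        cur_introns.append(intron)
    pieces.append(SplicedAlignment(cur_segments, cur_introns))
    return pieces


def apply_short_read_policy(
    spliced: SplicedAlignment,
    read_length: int,
    threshold: int = DEFAULT_SHORT_READ_THRESHOLD,
) -> list[SplicedAlignment]:
    """For reads shorter than ``threshold`` bases, drop every intron whose
    signal is not canonical GT-AG, splitting the alignment at the removed
    junctions."""
    if read_length >= threshold or not spliced.introns:
        return [spliced]
    pieces: list[SplicedAlignment] = []
    cur_segments = [spliced.segments[0]]
    cur_introns: list[Intron] = []
    for intron, seg in zip(spliced.introns, spliced.segments[1:]):
        if intron.signal_class == CANONICAL:
            cur_segments.append(seg)
            cur_introns.append(intron)
        else:
            pieces.append(SplicedAlignment(cur_segments, cur_introns))
            cur_segments, cur_introns = [seg], []
    pieces.append(SplicedAlignment(cur_segments, cur_introns))
    return pieces


@dataclass
class IntronCall:
    """One distinct intron with its supporting read count."""

    ref_name: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    signal_class: str
    support: int

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.ref_name, self.donor_pos, self.acceptor_pos)


def collect_introns(alignments: list[SplicedAlignment]) -> list[IntronCall]:
    """Aggregate introns over finalized alignments; one call per distinct
    (reference, donor, acceptor), support = number of supporting reads."""
    calls: dict[tuple, IntronCall] = {}
    for aln in alignments:
        for intron in aln.introns:
            key = (intron.ref_name, intron.donor_pos, intron.acceptor_pos)
            if key in calls:
                calls[key].support += 1
            else:
                calls[key] = IntronCall(
                    intron.ref_name,
                    intron.donor_pos,
                    intron.acceptor_pos,
                    intron.strand,
                    intron.signal_class,
                    1,
                )
    return sorted(calls.values(), key=lambda c: c.key)
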