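"""Greedy gapped extension of exact seeds into local alignments.

Instead of dynamic programming the extender walks the read and reference in
lockstep.  At each mismatch it tries, in strict order, a fixed table of
candidate operations (substitutions of 1-2 bases, insertions and deletions of
1-3 bases).  Each rule carries a *requirement*: within the window of
``required_matches + allowed_mismatches`` bases following the applied
operation, at most ``allowed_mismatches`` may mismatch.  The first rule whose
requirement holds is applied; if none holds, a single substitution is
emitted and the walk continues.

Scoring: +1 per matching base, -4 per substituted base, gap opening free,
-4 per inserted or deleted base.  Extension stops at a sequence end or when
the running score drops more than the X-drop bound (the cost of the most
penalised tabled operation, a three-base gap: 12 under default penalties)
below the best score seen; the alignment is then backtracked to the position
of the best running score.

Where a gap can slide at equal score, it is normalised to the upstream-most
placement in the orientation of the reference, which keeps indel reporting
deterministic for variant calling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .seed_index import ReferenceSet, SeedMatch

# Edit-script opcodes: '=' exact match run, 'X' substitution run,
# 'I' insertion (read-only bases), 'D' deletion (reference-only bases).
READ_CONSUMING = {"=", "X", "I"}
REF_CONSUMING = {"=", "X", "D"}


@dataclass(frozen=True)
class ScoringScheme:
    """Per-base alignment scoring; gap opening is free by default."""

    match_reward: int = 1
    mismatch_penalty: int = -4
    gap_open: int = 0
    gap_extend_per_base: int = -4

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match_reward must be positive")
        if self.mismatch_penalty > 0 or self.gap_open > 0 or self.gap_extend_per_base > 0:
            raise ValueError("penalties must be non-positive")

    def gap_cost(self, length: int) -> int:
        return self.gap_open + length * self.gap_extend_per_base

    @property
    def xdrop(self) -> int:
        """Most penalised tabled gap operation: a three-base gap."""
        return -self.gap_cost(3)


@dataclass(frozen=True)
class OperationRule:
    """One candidate operation with its match requirement."""

    kind: str  # 'substitution' | 'insertion' | 'deletion'
    op_length: int
    required_matches: int
    allowed_mismatches: int

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown operation kind {self.kind!r}")


#: Default operation table, tried strictly in order.
DEFAULT_OPERATION_TABLE: tuple[OperationRule, ...] = (
    OperationRule("substitution", 1, 9, 0),
    OperationRule("insertion", 1, 10, 0),
    OperationRule("deletion", 1, 10, 0),
    OperationRule("insertion", 2, 10, 0),
    OperationRule("deletion", 2, 10, 0),
    OperationRule("insertion", 3, 13, 0),
    OperationRule("deletion", 3, 13, 0),
    OperationRule("substitution", 2, 12, 0),
    OperationRule("insertion", 1, 10, 2),
    OperationRule("deletion", 1, 10, 2),
    OperationRule("insertion", 2, 10, 2),
    OperationRule("deletion", 2, 10, 2),
    OperationRule("insertion", 3, 13, 2),
    OperationRule("deletion", 3, 13, 2),
)


def load_operation_table(path) -> tuple[OperationRule, ...]:
    """Read an operation table from a plain-text file: one rule per line,
    whitespace-separated ``kind length required_matches allowed_mismatches``;
    '#' starts a comment."""
    rules = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            kind, length, req, allowed = line.split()
            rules.append(OperationRule(kind, int(length), int(req), int(allowed)))
    return tuple(rules)


@dataclass
class LocalAlignment:
    """One gapped exon-level alignment with its edit script and score.

    Intervals are 0-based half-open; for ``-`` strand alignments the read
    interval refers to the reverse-complemented read, matching the seed
    convention.
    """

    read_index: int
    strand: str
    read_start: int
    read_end: int
    ref_name: str
    ref_start: int
    ref_end: int
    script: list[tuple[str, int]]
    score: int

    def __post_init__(self) -> None:
        q = sum(n for op, n in self.script if op in READ_CONSUMING)
        r = sum(n for op, n in self.script if op in REF_CONSUMING)
        if q != self.read_end - self.read_start:
            raise ValueError("edit script does not span the read interval")
        if r != self.ref_end - self.ref_start:
            raise ValueError("edit script does not span the reference interval")

    @property
    def read_length_aligned(self) -> int:
        return self.read_end - self.read_start

    @property
    def edit_distance(self) -> int:
        return sum(n for op, n in self.script if op in ("X", "I", "D"))

    def rescore(self, scheme: ScoringScheme) -> int:
        """Recompute the score from the edit script alone."""
        s = 0
        for op, n in self.script:
            if op == "=":
                s += n * scheme.match_reward
            elif op == "X":
                s += n * scheme.mismatch_penalty
            else:
                s += scheme.gap_cost(n)
        return s

    def verify(self, read_seq: str, ref_seq: str, scheme: ScoringScheme) -> None:
        """Assert the edit script is consistent with the sequences and score."""
        i, j = self.read_start, self.ref_start
        for op, n in self.script:
            if op == "=":
                if read_seq[i : i + n] != ref_seq[j : j + n]:
                    raise AssertionError("match run disagrees with sequences")
                i += n
                j += n
            elif op == "X":
                for k in range(n):
                    if read_seq[i + k] == ref_seq[j + k] and read_seq[i + k] != "N":
                        raise AssertionError("substitution column actually matches")
                i += n
                j += n
            elif op == "I":
                i += n
            elif op == "D":
                j += n
        if self.rescore(scheme) != self.score:
            raise AssertionError("stored score disagrees with edit script")


def _bases_match(a: str, b: str) -> bool:
    # N is never a match, conservatively.
    return a == b and a != "N"


def _window_ok(read: str, ref: str, i: int, j: int, rule: OperationRule) -> bool:
    """Check a rule's requirement at read pos i / ref pos j (positions just
    after the candidate operation).  Truncated windows at a sequence end are
    accepted when their mismatches stay within the allowance."""
    window = rule.required_matches + rule.allowed_mismatches
    span = min(window, len(read) - i, len(ref) - j)
    mismatches = 0
    for k in range(span):
        if not _bases_match(read[i + k], ref[j + k]):
            mismatches += 1
            if mismatches > rule.allowed_mismatches:
                return False
    return True


def step_state_machine(
    read_tail: str,
    ref_tail: str,
    table: tuple[OperationRule, ...] = DEFAULT_OPERATION_TABLE,
) -> OperationRule:
    """Choose the operation at a mismatch between two sequence tails.

    The tails start at the mismatching position.  Returns the first rule in
    the table whose requirement is satisfied, or the single-substitution
    fallback when none is.
    """
    if not read_tail or not ref_tail:
        raise ValueError("tails must be non-empty")
    for rule in table:
        if rule.kind == "substitution":
            i, j = rule.op_length, rule.op_length
        elif rule.kind == "insertion":
            i, j = rule.op_length, 0
        else:
            i, j = 0, rule.op_length
        if i > len(read_tail) or j > len(ref_tail):
            continue
        if _window_ok(read_tail, ref_tail, i, j, rule):
            return rule
    return OperationRule("substitution", 1, 0, 0)


class _ScriptBuilder:
    """Accumulates edit-script ops, merging adjacent runs of the same kind."""

    def __init__(self) -> None:
        self.ops: list[tuple[str, int]] = []

    def add(self, op: str, n: int) -> None:
        if n == 0:
            return
        if self.ops and self.ops[-1][0] == op:
            self.ops[-1] = (op, self.ops[-1][1] + n)
        else:
            self.ops.append((op, n))

    def __len__(self) -> int:
        return len(self.ops)


def _extend_one_way(
    read: str,
    ref: str,
    start_i: int,
    start_j: int,
    scheme: ScoringScheme,
    table: tuple[OperationRule, ...],
    xdrop: int,
) -> tuple[list[tuple[str, int]], int, int, int]:
    """Extend rightward from (start_i, start_j); returns the backtracked
    (script, consumed_read, consumed_ref, score_delta)."""
    i, j = start_i, start_j
    score = 0
    best_score = 0
    best: tuple[int, int, int] = (0, 0, 0)  # (#flat ops, read consumed, ref consumed)
    flat: list[tuple[str, int]] = []  # per-event ops, merged later

    n, m = len(read), len(ref)
    while i < n and j < m:
        if _bases_match(read[i], ref[j]):
            run = 0
            while i < n and j < m and _bases_match(read[i], ref[j]):
                run += 1
                i += 1
                j += 1
            score += run * scheme.match_reward
            flat.append(("=", run))
            if score > best_score:
                best_score = score
                best = (len(flat), i - start_i, j - start_j)
            continue
        rule = step_state_machine(read[i:], ref[j:], table)
        if rule.kind == "substitution":
            # Score substituted columns by actual comparison so the stored
            # score always equals a recomputation from the script.
            for _ in range(min(rule.op_length, n - i, m - j)):
                if _bases_match(read[i], ref[j]):
                    score += scheme.match_reward
                    flat.append(("=", 1))
                else:
                    score += scheme.mismatch_penalty
                    flat.append(("X", 1))
                i += 1
                j += 1
        elif rule.kind == "insertion":
            k = min(rule.op_length, n - i)
            score += scheme.gap_cost(k)
            flat.append(("I", k))
            i += k
        else:
            k = min(rule.op_length, m - j)
            score += scheme.gap_cost(k)
            flat.append(("D", k))
            j += k
        if score > best_score:
            best_score = score
            best = (len(flat), i - start_i, j - start_j)
        if score < best_score - xdrop:
            break

    n_ops, di, dj = best
    builder = _ScriptBuilder()
    for op, length in flat[:n_ops]:
        builder.add(op, length)
    return builder.ops, di, dj, best_score


def greedy_extend(
    read: str,
    reference: ReferenceSet,
    seed: SeedMatch,
    scheme: ScoringScheme | None = None,
    table: tuple[OperationRule, ...] = DEFAULT_OPERATION_TABLE,
    xdrop: int | None = None,
) -> LocalAlignment:
    """Extend an exact seed into a local gapped alignment.

    ``read`` must be the oriented read sequence the seed refers to (already
    reverse-complemented for ``-`` strand seeds).  Extension runs rightward
    from the seed end and leftward from the seed start with the operation
    table applied to the reversed sequences; both sides are backtracked to
    their running-score maximum.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if xdrop is None:
        xdrop = scheme.xdrop
    ref = reference[seed.ref_name]

    if read[seed.read_start : seed.read_end] != ref[seed.ref_start : seed.ref_end]:
        raise ValueError("seed is not an exact match")

    right_script, dr_i, dr_j, right_score = _extend_one_way(
        read, ref, seed.read_end, seed.ref_end, scheme, table, xdrop
    )
    # Leftward: run the same machine on the reversed prefixes.
    left_script_rev, dl_i, dl_j, left_score = _extend_one_way(
        read[: seed.read_start][::-1],
        ref[: seed.ref_start][::-1],
        0,
        0,
        scheme,
        table,
        xdrop,
    )
    left_script = [(op, n) for op, n in reversed(left_script_rev)]

    builder = _ScriptBuilder()
    for op, n in left_script:
        builder.add(op, n)
    builder.add("=", seed.length)
    for op, n in right_script:
        builder.add(op, n)

    aln = LocalAlignment(
        read_index=seed.read_index,
        strand=seed.strand,
        read_start=seed.read_start - dl_i,
        read_end=seed.read_end + dr_i,
        ref_name=seed.ref_name,
        ref_start=seed.ref_start - dl_j,
        ref_end=seed.ref_end + dr_j,
        script=builder.ops,
        score=seed.length * scheme.match_reward + left_score + right_score,
    )
    return shift_gaps_upstream(aln, reference, read)


def _columns(aln: LocalAlignment) -> list[tuple[str, int, int]]:
    """Flatten the edit script into per-column ops (op, read_pos, ref_pos);
    gap columns carry the position on the consumed sequence only."""
    cols = []
    i, j = aln.read_start, aln.ref_start
    for op, n in aln.script:
        for _ in range(n):
            cols.append((op, i, j))
            if op in READ_CONSUMING:
                i += 1
            if op in REF_CONSUMING:
                j += 1
    return cols


def shift_gaps_upstream(
    aln: LocalAlignment,
    reference: ReferenceSet,
    read_seq: str,
) -> LocalAlignment:
    """Slide every gap to its upstream-most equal-score placement.

    A deletion of ``ref[p:p+k]`` may move one base upstream when
    ``ref[p-1] == ref[p+k-1]`` (the aligned column that swaps sides keeps its
    match status); insertions slide under the mirror condition on the read.
    The score is unchanged by construction.
    """
    if not any(op in ("I", "D") for op, _ in aln.script):
        return aln
    ref = reference[aln.ref_name]
    cols = _columns(aln)

    changed = True
    while changed:
        changed = False
        idx = 0
        while idx < len(cols):
            op = cols[idx][0]
            if op not in ("I", "D") or (idx > 0 and cols[idx - 1][0] == op):
                idx += 1
                continue
            run_start = idx
            run_end = run_start
            while run_end + 1 < len(cols) and cols[run_end + 1][0] == op:
                run_end += 1
            # the column immediately before the run must be an aligned one
            prev = run_start - 1
            if prev < 0 or cols[prev][0] not in ("=", "X"):
                idx = run_end + 1
                continue
            _, pi, pj = cols[prev]
            if op == "D":
                slidable = ref[pj] == ref[cols[run_end][2]]
            else:
                slidable = read_seq[pi] == read_seq[cols[run_end][1]]
            if slidable:
                # the aligned column hops over the gap; its match status is
                # preserved by the base-equality condition, so score is too
                moved = cols[prev]
                cols[prev : run_end + 1] = cols[run_start : run_end + 1] + [moved]
                cols = _renumber(cols, aln)
                changed = True
                idx = max(prev, 0)
            else:
                idx = run_end + 1

    builder = _ScriptBuilder()
    for op, _, _ in cols:
        builder.add(op, 1)
    return replace(aln, script=builder.ops)


def _renumber(cols, aln: LocalAlignment):
    i, j = aln.read_start, aln.ref_start
    fixed = []
    for op, _, _ in cols:
        fixed.append((op, i, j))
        if op in READ_CONSUMING:
            i += 1
        if op in REF_CONSUMING:
            j += 1
    return fixed
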