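"""Independent brute-force oracles used to cross-check the aligner.

These deliberately share no code with the implementation: plain dynamic
programming, exhaustive enumeration and direct string comparison only.
"""

from __future__ import annotations

import itertools


def smith_waterman_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -4,
    gap_per_base: int = -4,
) -> int:
    """Optimal local-alignment score under linear gap costs, full DP."""
    n, m = len(a), len(b)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            v = prev[j - 1] + s
            up = prev[j] + gap_per_base
            left = cur[j - 1] + gap_per_base
            v = max(v, up, left, 0)
            cur[j] = v
            if v > best:
                best = v
        prev = cur
    return best


def maximal_exact_matches(query: str, ref: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal exact runs (q_start, r_start, length) of at least
    ``min_len`` bases, found by scanning every diagonal."""
    out = set()
    n, m = len(query), len(ref)
    for diag in range(-n + 1, m):
        q = max(0, -diag)
        r = q + diag
        run = 0
        while q <= n and r <= m:
            if q < n and r < m and query[q] == ref[r] and query[q] != "N":
                run += 1
            else:
                if run >= min_len:
                    out.add((q - run, r - run, run))
                run = 0
            q += 1
            r += 1
    return out


def best_chain_score(
    segments: list[tuple[int, int, int, int, int]],
    min_intron: int,
    max_intron: int,
    max_read_gap: int,
) -> int:
    """Exhaustively enumerate every ordered subset of segments
    (read_start, read_end, ref_start, ref_end, score) that forms a valid
    chain and return the maximal total score."""

    def chainable(a, b):
        return (
            b[0] > a[0]
            and b[1] > a[1]
            and b[0] - a[1] <= max_read_gap
            and min_intron <= b[2] - a[3] <= max_intron
        )

    best = 0
    n = len(segments)
    for size in range(1, n + 1):
        for combo in itertools.permutations(range(n), size):
            if all(chainable(segments[a], segments[b]) for a, b in zip(combo, combo[1:])):
                total = sum(segments[k][4] for k in combo)
                best = max(best, total)
    return best


_ORACLE_SIGNALS = {
    ("GT", "AG"): 0, ("CT", "AC"): 0,
    ("GC", "AG"): 1, ("CT", "GC"): 1,
    ("AT", "AC"): 2, ("GT", "AT"): 2,
}


def junction_oracle(
    read: str,
    ref: str,
    left_read_start: int,
    left_ref_start: int,
    left_read_end: int,
    right_read_start: int,
    right_read_end: int,
    right_ref_start_at: int,
    minor_allowed: bool,
    min_intron: int,
    pad: int = 4,
):
    """Brute-force junction placement for two gap-free segments.

    The left segment aligns read[left_read_start:b] on the diagonal anchored
    at (left_read_start, left_ref_start); the right aligns read[b:
    right_read_end] ending on the diagonal anchored at (right_read_start,
    right_ref_start_at).  Every breakpoint b in the meeting window is scored
    by direct base comparison; candidates rank by signal class, then score,
    then upstream donor position.  Returns (b, donor_pos, acceptor_end,
    class_rank) or None.
    """

    def side_score(seq_lo, ref_lo, length):
        s = 0
        for k in range(length):
            s += 1 if read[seq_lo + k] == ref[ref_lo + k] else -4
        return s

    lo = max(right_read_start - pad, left_read_start + 1)
    hi = min(left_read_end + pad, right_read_end - 1)
    best = None
    for b in range(lo, hi + 1):
        l_len = b - left_read_start
        l_end = left_ref_start + l_len
        r_len = right_read_end - b
        r_start = right_ref_start_at + (b - right_read_start)
        if l_end + 2 > len(ref) or r_start - 2 < 0 or r_start + r_len > len(ref):
            continue
        intron_len = r_start - l_end
        if intron_len < min_intron:
            continue
        sig = (ref[l_end : l_end + 2], ref[r_start - 2 : r_start])
        rank = _ORACLE_SIGNALS.get(sig, 3)
        if rank > 0 and not minor_allowed:
            continue
        score = side_score(left_read_start, left_ref_start, l_len) + side_score(
            b, r_start, r_len
        )
        key = (rank, -score, l_end)
        if best is None or key < best[0]:
            best = (key, b, l_end, r_start)
    if best is None:
        return None
    return best[1], best[2], best[3], best[0][0]


def count_words_with_at_least(n_repeats: int, word_size: int = 16) -> int:
    """Number of distinct words over {A,C,G,T} with at least ``n_repeats``
    copies of A or of T, counted by direct construction."""
    words = set()
    for base in "AT":
        words.add(base * word_size)
        for pos in range(word_size):
            for other in "ACGT":
                if other == base:
                    continue
                w = list(base * word_size)
                w[pos] = other
                words.add("".join(w))
    return len(words)
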