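"""Placement selection for single reads and read pairs.

A fragment's reported placement maximises the *pair score* — the plain sum
of the two mates' spliced-alignment scores.  This lets an unambiguous mate
disambiguate its partner: if mate 1 scores equally at two loci but mate 2
maps best near only one of them, the concordant combination wins and the
pair is reported uniquely there.  Concordance requires the same reference,
opposite strands, and mate starts within a configurable distance (1 Mb by
default, generous because RNA-seq fragments can span long introns).

Each mapped read gets exactly one primary alignment; ties are broken by
higher score, then fewer introns, then smaller reference coordinate.  MAPQ
is 60 for unique placements, 1 for a best-of-several, 0 for exact ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .splice_chain import SplicedAlignment

DEFAULT_MAX_PAIR_DISTANCE = 1_000_000
DEFAULT_MAX_SECONDARY = 10


@dataclass
class ReportedAlignment:
    """One alignment chosen for output, with SAM-oriented annotations."""

    alignment: SplicedAlignment
    is_primary: bool
    is_secondary: bool
    mapq: int
    proper_pair: bool = False
    mate: "ReportedAlignment | None" = None


@dataclass
class ReadPlacement:
    """Everything selected for one read: primary plus capped secondaries.
    ``unique`` means exactly one placement attains the top score."""

    reported: list[ReportedAlignment] = field(default_factory=list)
    unique: bool = False

    @property
    def mapped(self) -> bool:
        return bool(self.reported)

    @property
    def primary(self) -> ReportedAlignment | None:
        for r in self.reported:
            if r.is_primary:
                return r
        return None


def _sort_candidates(cands: list[SplicedAlignment]) -> list[SplicedAlignment]:
    """Score-descending, ties by fewer introns then leftmost coordinate."""
    return sorted(
        cands,
        key=lambda a: (-a.score, len(a.introns), a.ref_name, a.ref_start, a.strand),
    )


def _primary_mapq(n_cands: int, n_top: int) -> int:
    if n_top > 1:
        return 0
    return 60 if n_cands == 1 else 1


def designate_primary(
    cands: list[SplicedAlignment],
    max_secondary: int = DEFAULT_MAX_SECONDARY,
) -> ReadPlacement:
    """Pick the single primary alignment of a read and flag the rest as
    secondaries (capped).  An empty candidate list yields an unmapped
    placement."""
    if not cands:
        return ReadPlacement([], unique=False)
    ordered = _sort_candidates(cands)
    top = ordered[0].score
    n_top = sum(1 for c in ordered if c.score == top)
    unique = n_top == 1
    reported = [
        ReportedAlignment(ordered[0], is_primary=True, is_secondary=False,
                          mapq=_primary_mapq(len(ordered), n_top))
    ]
    for c in ordered[1 : 1 + max_secondary]:
        reported.append(ReportedAlignment(c, is_primary=False, is_secondary=True, mapq=0))
    return ReadPlacement(reported, unique=unique)


def _concordant(a: SplicedAlignment, b: SplicedAlignment, max_distance: int) -> bool:
    return (
        a.ref_name == b.ref_name
        and a.strand != b.strand
        and abs(a.ref_start - b.ref_start) <= max_distance
    )


def resolve_pairs(
    cands1: list[SplicedAlignment],
    cands2: list[SplicedAlignment],
    max_pair_distance: int = DEFAULT_MAX_PAIR_DISTANCE,
    max_secondary: int = DEFAULT_MAX_SECONDARY,
) -> tuple[ReadPlacement, ReadPlacement]:
    """Select the reported placements of a mate pair.

    The concordant combination with the maximal pair score (sum of mate
    scores) becomes the primary pair; both mates are then flagged proper.
    A mate ambiguous on its own but pinned down by its partner is reported
    unique at the partner-dictated site.  With no concordant combination
    (or an unmapped mate) the mates fall back to independent selection.
    """
    if not cands1 or not cands2:
        return (designate_primary(cands1, max_secondary),
                designate_primary(cands2, max_secondary))

    best_pair = None
    best_score = None
    n_best = 0
    for a in _sort_candidates(cands1):
        for b in _sort_candidates(cands2):
            if not _concordant(a, b, max_pair_distance):
                continue
            s = a.score + b.score
            if best_score is None or s > best_score:
                best_score, best_pair, n_best = s, (a, b), 1
            elif s == best_score:
                n_best += 1
    if best_pair is None:
        return (designate_primary(cands1, max_secondary),
                designate_primary(cands2, max_secondary))

    a, b = best_pair
    unique_pair = n_best == 1
    mapq = 60 if unique_pair else 0
    rep1 = ReadPlacement(
        [ReportedAlignment(a, True, False, mapq, proper_pair=True)], unique=unique_pair
    )
    rep2 = ReadPlacement(
        [ReportedAlignment(b, True, False, mapq, proper_pair=True)], unique=unique_pair
    )
    rep1.reported[0].mate = rep2.reported[0]
    rep2.reported[0].mate = rep1.reported[0]
    for place, cands, chosen in ((rep1, cands1, a), (rep2, cands2, b)):
        for c in _sort_candidates(cands):
            if c is chosen:
                continue
            if len(place.reported) > max_secondary:
                break
            place.reported.append(ReportedAlignment(c, False, True, 0))
    return rep1, rep2
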