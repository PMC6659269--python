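"""End-to-end alignment driver: batching, seeding, extension, chaining,
junction resolution and pair selection.

``align_batch`` is the library entry point; the command-line interface is a
thin wrapper around it.  Reads are processed in batches: a word lookup is
built over the batch (both orientations), repeat words are masked against
the reference, the reference plus strand is scanned once for seeds, seeds
are greedily extended into local alignments, collinear locals are chained
into spliced candidates, and the final placement of each read (or pair) is
the one maximising the (pair) alignment score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .greedy_extend import (
    DEFAULT_OPERATION_TABLE,
    LocalAlignment,
    OperationRule,
    ScoringScheme,
    greedy_extend,
)
from .pair_select import (
    DEFAULT_MAX_PAIR_DISTANCE,
    DEFAULT_MAX_SECONDARY,
    ReadPlacement,
    designate_primary,
    resolve_pairs,
)
from .seed_index import (
    DEFAULT_MAX_DB_WORD_COUNT,
    DEFAULT_SEED_LEN,
    DEFAULT_WORD_SIZE,
    ReadBatch,
    ReferenceSet,
    build_lookup,
    count_and_mask_repeats,
    revcomp,
    scan_reference,
)
from .splice_chain import (
    DEFAULT_MAX_INTRON,
    DEFAULT_MIN_INTRON,
    DEFAULT_MIN_SIDE_SCORE,
    DEFAULT_SHORT_READ_THRESHOLD,
    SplicedAlignment,
    apply_short_read_policy,
    chain_alignments,
    finalize_chain,
)


@dataclass
class AlignerParams:
    """All tunables of the alignment pipeline with their defaults."""

    word_size: int = DEFAULT_WORD_SIZE
    seed_len: int = DEFAULT_SEED_LEN
    max_db_word_count: int = DEFAULT_MAX_DB_WORD_COUNT
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    operation_table: tuple[OperationRule, ...] = DEFAULT_OPERATION_TABLE
    xdrop: int | None = None
    splice: bool = True
    min_side_score: int = DEFAULT_MIN_SIDE_SCORE
    min_intron: int = DEFAULT_MIN_INTRON
    max_intron: int = DEFAULT_MAX_INTRON
    short_read_threshold: int = DEFAULT_SHORT_READ_THRESHOLD
    max_pair_distance: int = DEFAULT_MAX_PAIR_DISTANCE
    max_secondary: int = DEFAULT_MAX_SECONDARY
    max_seeds_per_read: int = 50
    batch_size: int = 100_000


def candidates_for_read(
    read_seq: str,
    read_index: int,
    seeds,
    reference: ReferenceSet,
    params: AlignerParams,
) -> list[SplicedAlignment]:
    """Extend a read's seeds and chain them into spliced candidates.

    Seeds are grouped per (reference, strand); within a group, locals whose
    reference positions are within the maximum intron length of each other
    form a locus cluster, and each cluster contributes the candidates from
    its best chain.
    """
    by_orientation: dict[tuple[str, str], list] = {}
    for seed in seeds:
        by_orientation.setdefault((seed.ref_name, seed.strand), []).append(seed)

    candidates: list[SplicedAlignment] = []
    for (ref_name, strand), group in by_orientation.items():
        oriented = read_seq if strand == "+" else revcomp(read_seq)
        group = sorted(group, key=lambda s: -s.length)[: params.max_seeds_per_read]
        locals_: list[LocalAlignment] = []
        seen: set[tuple] = set()
        for seed in group:
            aln = greedy_extend(
                oriented, reference, seed,
                scheme=params.scheme, table=params.operation_table, xdrop=params.xdrop,
            )
            key = (aln.read_start, aln.read_end, aln.ref_start, aln.ref_end)
            if key in seen:
                continue
            seen.add(key)
            locals_.append(aln)
        for cluster in _locus_clusters(locals_, params.max_intron):
            if params.splice:
                chain = chain_alignments(
                    cluster, params.scheme,
                    min_intron=params.min_intron, max_intron=params.max_intron,
                )
                pieces = finalize_chain(
                    chain, reference, oriented, params.scheme,
                    min_side_score=params.min_side_score,
                    min_intron=params.min_intron, max_intron=params.max_intron,
                )
                chain_ids = {id(seg) for seg in chain}
            else:
                pieces = []
                chain_ids = set()
            final_pieces: list[SplicedAlignment] = []
            for piece in pieces:
                final_pieces.extend(
                    apply_short_read_policy(
                        piece, len(read_seq), params.short_read_threshold
                    )
                )
            # locals outside the best chain still stand as their own candidates
            for aln in cluster:
                if id(aln) not in chain_ids:
                    final_pieces.append(SplicedAlignment.single(aln))
            candidates.extend(final_pieces)
    return _dedupe(candidates)


def _locus_clusters(locals_: list[LocalAlignment], max_intron: int):
    """Group locals whose reference intervals lie within ``max_intron`` of
    each other; separate loci never chain."""
    clusters: list[list[LocalAlignment]] = []
    for aln in sorted(locals_, key=lambda a: a.ref_start):
        if clusters and aln.ref_start - clusters[-1][-1].ref_end <= max_intron:
            clusters[-1].append(aln)
        else:
            clusters.append([aln])
    return clusters


def _dedupe(cands: list[SplicedAlignment]) -> list[SplicedAlignment]:
    seen = set()
    out = []
    for c in cands:
        key = (
            c.ref_name, c.strand, c.read_start, c.read_end, c.ref_start, c.ref_end,
            tuple((i.start, i.end) for i in c.introns),
        )
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


def align_batch(
    reads: ReadBatch,
    reference: ReferenceSet,
    params: AlignerParams | None = None,
) -> dict[int, ReadPlacement]:
    """Align a read batch against a reference; returns per-read placements
    keyed by read index (reads with no placement are absent)."""
    if params is None:
        params = AlignerParams()
    lookup = build_lookup(reads, params.word_size)
    count_and_mask_repeats(lookup, reference, params.max_db_word_count)
    seeds = scan_reference(reference, lookup, params.seed_len, reads=reads)

    seeds_by_read: dict[int, list] = {}
    for seed in seeds:
        seeds_by_read.setdefault(seed.read_index, []).append(seed)

    cands: dict[int, list[SplicedAlignment]] = {}
    for idx, read in enumerate(reads):
        cands[idx] = (
            candidates_for_read(read.sequence, idx, seeds_by_read.get(idx, []), reference, params)
            if idx in seeds_by_read
            else []
        )

    placements: dict[int, ReadPlacement] = {}
    if reads.paired:
        by_fragment: dict[str, dict[int, int]] = {}
        for idx, read in enumerate(reads):
            by_fragment.setdefault(read.fragment_id, {})[read.mate] = idx
        for frag, mates in by_fragment.items():
            i1, i2 = mates[1], mates[2]
            p1, p2 = resolve_pairs(
                cands[i1], cands[i2],
                max_pair_distance=params.max_pair_distance,
                max_secondary=params.max_secondary,
            )
            placements[i1] = p1
            placements[i2] = p2
    else:
        for idx in cands:
            placements[idx] = designate_primary(cands[idx], params.max_secondary)
    return placements


def primary_alignments(placements: dict[int, ReadPlacement]) -> list[SplicedAlignment]:
    """The primary spliced alignment of every mapped read."""
    out = []
    for placement in placements.values():
        if placement.mapped:
            out.append(placement.primary.alignment)
    return out
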