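"""SAM and tabular output, plus SAM parsing for the evaluation tools.

SAM records are written as v1 text with CIGAR ops M, I, D, N and S; the
full read sequence is always preserved via soft clips, minus-strand records
carry the reverse-complemented sequence per the SAM specification, and every
record gets ``NM`` (edit distance against the reference, splice gaps
excluded) and ``AS`` (alignment score) tags.

The tabular format is a tab-delimited table in the spirit of the classic
BLAST hit tables: one row per alignment with identity, coordinates, strand,
score, edit distance, intron count and a btop-like edit string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .pair_select import ReadPlacement
from .seed_index import Read, ReadBatch, ReferenceSet, revcomp
from .splice_chain import SplicedAlignment

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_IN_PAIR = 0x40
FLAG_SECOND_IN_PAIR = 0x80
FLAG_SECONDARY = 0x100

TABULAR_COLUMNS = [
    "query", "reference", "pct_identity", "read_start", "read_end",
    "ref_start", "ref_end", "strand", "score", "edit_distance",
    "intron_count", "edit_string",
]


@dataclass
class SamRecord:
    """One parsed or constructed SAM alignment line."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost mapped base; 0 when unmapped
    mapq: int
    cigar: str
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: dict[str, int | str] = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_primary(self) -> bool:
        return not (self.flag & FLAG_SECONDARY)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    def cigar_ops(self) -> list[tuple[str, int]]:
        if self.cigar == "*":
            return []
        return [(op, int(n)) for n, op in re.findall(r"(\d+)([MIDNS])", self.cigar)]

    def aligned_length(self) -> int:
        """Read bases in aligned (M/I) state."""
        return sum(n for op, n in self.cigar_ops() if op in "MI")

    def to_line(self) -> str:
        fields = [
            self.qname, str(self.flag), self.rname, str(self.pos), str(self.mapq),
            self.cigar, self.rnext, str(self.pnext), str(self.tlen), self.seq, self.qual,
        ]
        for key, val in self.tags.items():
            typ = "i" if isinstance(val, int) else "Z"
            fields.append(f"{key}:{typ}:{val}")
        return "\t".join(fields)

    @classmethod
    def from_line(cls, line: str) -> "SamRecord":
        parts = line.rstrip("\n").split("\t")
        tags: dict[str, int | str] = {}
        for tag in parts[11:]:
            key, typ, val = tag.split(":", 2)
            tags[key] = int(val) if typ == "i" else val
        return cls(
            qname=parts[0], flag=int(parts[1]), rname=parts[2], pos=int(parts[3]),
            mapq=int(parts[4]), cigar=parts[5], rnext=parts[6], pnext=int(parts[7]),
            tlen=int(parts[8]), seq=parts[9], qual=parts[10], tags=tags,
        )


def _spliced_to_cigar(aln: SplicedAlignment, read_len: int) -> str:
    ops: list[tuple[str, int]] = []
    if aln.read_start > 0:
        ops.append(("S", aln.read_start))
    for op, n in aln.full_script():
        sam_op = "M" if op in ("=", "X") else op
        if ops and ops[-1][0] == sam_op:
            ops[-1] = (sam_op, ops[-1][1] + n)
        else:
            ops.append((sam_op, n))
    if read_len - aln.read_end > 0:
        ops.append(("S", read_len - aln.read_end))
    return "".join(f"{n}{op}" for op, n in ops)


def record_for_alignment(
    read: Read,
    aln: SplicedAlignment,
    mapq: int,
    *,
    secondary: bool = False,
    paired: bool = False,
    proper: bool = False,
    mate_info: tuple[str, int, str] | None = None,  # (rname, 1-based pos, strand)
    mate_unmapped: bool = False,
) -> SamRecord:
    """Build the SAM record of one reported alignment.

    Minus-strand alignments store the reverse-complemented sequence, so the
    alignment's read coordinates (which already refer to the oriented read)
    apply to ``seq`` directly.
    """
    flag = 0
    seq = read.sequence
    qual = read.qualities or "*"
    if aln.strand == "-":
        flag |= FLAG_REVERSE
        seq = revcomp(seq)
        qual = qual[::-1] if qual != "*" else "*"
    if secondary:
        flag |= FLAG_SECONDARY
    rnext, pnext = "*", 0
    if paired:
        flag |= FLAG_PAIRED
        flag |= FLAG_FIRST_IN_PAIR if read.mate == 1 else FLAG_SECOND_IN_PAIR
        if proper:
            flag |= FLAG_PROPER_PAIR
        if mate_unmapped:
            flag |= FLAG_MATE_UNMAPPED
        elif mate_info is not None:
            rnext = "=" if mate_info[0] == aln.ref_name else mate_info[0]
            pnext = mate_info[1]
            if mate_info[2] == "-":
                flag |= FLAG_MATE_REVERSE
    return SamRecord(
        qname=read.id,
        flag=flag,
        rname=aln.ref_name,
        pos=aln.ref_start + 1,
        mapq=mapq,
        cigar=_spliced_to_cigar(aln, len(read.sequence)),
        rnext=rnext,
        pnext=pnext,
        tlen=0,
        seq=seq,
        qual=qual,
        tags={"NM": aln.edit_distance, "AS": aln.score},
    )


def unmapped_record(read: Read, paired: bool = False, mate_unmapped: bool = False) -> SamRecord:
    flag = FLAG_UNMAPPED
    if paired:
        flag |= FLAG_PAIRED
        flag |= FLAG_FIRST_IN_PAIR if read.mate == 1 else FLAG_SECOND_IN_PAIR
        if mate_unmapped:
            flag |= FLAG_MATE_UNMAPPED
    return SamRecord(
        qname=read.id, flag=flag, rname="*", pos=0, mapq=0, cigar="*",
        seq=read.sequence, qual=read.qualities or "*",
    )


def records_for_placements(
    reads: ReadBatch,
    placements: dict[int, ReadPlacement],
) -> list[SamRecord]:
    """Turn per-read placements into SAM records (primary + secondaries,
    unmapped records for reads without placements)."""
    records: list[SamRecord] = []
    for idx, read in enumerate(reads):
        placement = placements.get(idx)
        if placement is None or not placement.mapped:
            mate_unmapped = False
            if reads.paired:
                mate_idx = _mate_index(reads, idx)
                mate_place = placements.get(mate_idx) if mate_idx is not None else None
                mate_unmapped = mate_place is None or not mate_place.mapped
            records.append(unmapped_record(read, reads.paired, mate_unmapped))
            continue
        for rep in placement.reported:
            mate_info = None
            mate_unmapped = False
            if reads.paired:
                if rep.mate is not None:
                    m = rep.mate.alignment
                    mate_info = (m.ref_name, m.ref_start + 1, m.strand)
                else:
                    mate_idx = _mate_index(reads, idx)
                    mate_place = placements.get(mate_idx) if mate_idx is not None else None
                    if mate_place is not None and mate_place.mapped:
                        m = mate_place.primary.alignment
                        mate_info = (m.ref_name, m.ref_start + 1, m.strand)
                    else:
                        mate_unmapped = True
            records.append(
                record_for_alignment(
                    read, rep.alignment, rep.mapq,
                    secondary=rep.is_secondary, paired=reads.paired,
                    proper=rep.proper_pair, mate_info=mate_info,
                    mate_unmapped=mate_unmapped,
                )
            )
    return records


def _mate_index(reads: ReadBatch, idx: int) -> int | None:
    read = reads.reads[idx]
    for j, other in enumerate(reads.reads):
        if j != idx and other.fragment_id == read.fragment_id:
            return j
    return None


def write_sam(
    records: Iterable[SamRecord],
    reference: ReferenceSet,
    stream: TextIO,
    sort: bool = False,
) -> None:
    """Write a SAM file with @SQ header lines for every reference record.

    A record naming an unknown reference is a hard error.  With ``sort``
    records are ordered by (reference, position, name); otherwise input
    order is kept.
    """
    stream.write("@HD\tVN:1.6\t" + ("SO:coordinate\n" if sort else "SO:unsorted\n"))
    for ref in reference:
        stream.write(f"@SQ\tSN:{ref.name}\tLN:{len(ref.sequence)}\n")
    stream.write("@PG\tID:splicemap\tPN:splicemap\n")
    records = list(records)
    for rec in records:
        if not rec.is_unmapped and rec.rname not in reference:
            raise ValueError(f"record {rec.qname!r} names unknown reference {rec.rname!r}")
    if sort:
        records.sort(key=lambda r: (r.rname == "*", r.rname, r.pos, r.qname))
    for rec in records:
        stream.write(rec.to_line() + "\n")


def read_sam(stream: TextIO) -> list[SamRecord]:
    """Parse the alignment lines of a SAM text stream."""
    out = []
    for line in stream:
        if line.startswith("@") or not line.strip():
            continue
        out.append(SamRecord.from_line(line))
    return out


def compute_nm(record: SamRecord, reference: ReferenceSet) -> int:
    """Recompute the NM edit distance of a record against the reference
    (substitutions + inserted + deleted bases; N gaps excluded)."""
    if record.is_unmapped:
        return 0
    ref = reference[record.rname]
    i = 0
    j = record.pos - 1
    nm = 0
    for op, n in record.cigar_ops():
        if op == "M":
            for k in range(n):
                if record.seq[i + k] != ref[j + k]:
                    nm += 1
            i += n
            j += n
        elif op == "I":
            nm += n
            i += n
        elif op == "D":
            nm += n
            j += n
        elif op == "N":
            j += n
        elif op == "S":
            i += n
    return nm


def _btop(aln: SplicedAlignment) -> str:
    """Compact btop-style edit string: match run lengths, substitution and
    gap columns as base pairs, '^' marking intron splits."""
    parts: list[str] = []
    for op, n in aln.full_script():
        if op == "=":
            parts.append(str(n))
        elif op == "X":
            parts.append(f"X{n}")
        elif op == "I":
            parts.append(f"I{n}")
        elif op == "D":
            parts.append(f"D{n}")
        elif op == "N":
            parts.append(f"^{n}^")
    return "".join(parts) or "0"


def percent_identity(aln: SplicedAlignment) -> float:
    """Matching columns over all aligned columns (gap bases count against)."""
    matches = sum(n for s in aln.segments for op, n in s.script if op == "=")
    columns = sum(n for s in aln.segments for op, n in s.script)
    return 100.0 * matches / columns if columns else 0.0


def write_tabular(
    alignments: Iterable[tuple[str, SplicedAlignment]],
    stream: TextIO,
) -> None:
    """Write (query id, alignment) pairs as a tab-delimited table; the
    header comment line documents the columns."""
    stream.write("# " + "\t".join(TABULAR_COLUMNS) + "\n")
    for qname, aln in alignments:
        row = [
            qname,
            aln.ref_name,
            f"{percent_identity(aln):.2f}",
            str(aln.read_start),
            str(aln.read_end),
            str(aln.ref_start),
            str(aln.ref_end),
            aln.strand,
            str(aln.score),
            str(aln.edit_distance),
            str(len(aln.introns)),
            _btop(aln),
        ]
        stream.write("\t".join(row) + "\n")
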