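"""Long-read alignment parsing and gap-spanning evidence extraction.

Two evidence pathways feed gap closure:

* **unsplit** — a read whose single alignment covers the gap plus at least
  ``flank`` aligned bases on both sides; the read subsequence between the
  lifted-over flank positions is extracted (so it carries read-derived
  flanks).
* **split** — a read the aligner reported as two parts, one ending near the
  left gap edge and one starting near the right edge (gaps >= 3 kb only);
  the read interval strictly between the parts — the unmapped middle — is
  extracted.

All reference and read coordinates are 0-based half-open.  Read coordinates
and ``read_seq`` are expressed in the original read orientation; extracted
sequences are always returned in reference orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from spanfill.assembly import GapRecord
from spanfill.errors import ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: CIGAR ops consuming the reference / the read.
REF_OPS = frozenset("M=XD")
READ_OPS = frozenset("M=XI")

_CIGAR_CODE = "MIDNSHP=X"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadAlignment:
    """One mapped SAM record in normalized coordinates.

    ``read_start``/``read_end`` delimit the aligned part of the read in
    original read orientation; ``read_seq`` is the full-length read in
    original orientation (may be empty when unavailable).
    """

    read_id: str
    scaffold_id: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    read_seq: str
    read_len: int
    is_split_part: bool = False

    @property
    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in READ_OPS)


@dataclass(frozen=True)
class SpanningEvidence:
    """One read's contribution to one gap."""

    gap_id: str
    read_id: str
    pathway: str  # 'unsplit' | 'split'
    extracted_seq: str
    left_anchor_bp: int
    right_anchor_bp: int


def _parse_record(rec: pysam.AlignedSegment) -> ReadAlignment:
    """Convert a mapped pysam record to normalized coordinates.

    ``read_seq`` is left empty here when the record itself cannot supply
    the full-length read (hard clips or '*'); the caller fills it from the
    primary record or the FASTQ side-channel.
    """
    cig = [(_CIGAR_CODE[op], n) for op, n in rec.cigartuples]
    clip_left = 0
    i = 0
    while i < len(cig) and cig[i][0] in "SH":
        clip_left += cig[i][1]
        i += 1
    clip_right = 0
    i = len(cig) - 1
    while i >= 0 and cig[i][0] in "SH":
        clip_right += cig[i][1]
        i -= 1
    qc = sum(n for op, n in cig if op in READ_OPS)
    read_len = clip_left + qc + clip_right
    strand = "-" if rec.is_reverse else "+"
    # read interval in original orientation
    if strand == "+":
        read_start = clip_left
    else:
        read_start = clip_right
    read_end = read_start + qc

    read_seq = ""
    stored = rec.query_sequence
    has_hard = any(op == "H" for op, _ in cig)
    if stored and not has_hard:
        read_seq = stored.upper()
        if strand == "-":
            read_seq = revcomp(read_seq)
    return ReadAlignment(
        read_id=rec.query_name,
        scaffold_id=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        read_start=read_start,
        read_end=read_end,
        strand=strand,
        cigar=cig,
        read_seq=read_seq,
        read_len=read_len,
    )


def _load_fastq(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fq:
        for entry in fq:
            seqs[entry.name] = entry.sequence.upper()
    return seqs


def read_alignments(
    path: str | Path, reads: str | Path | None = None
) -> dict[str, list[ReadAlignment]]:
    """Parse SAM/BAM into :class:`ReadAlignment` grouped by scaffold.

    Unmapped and secondary records are dropped; supplementary records are
    kept.  When one read contributes >= 2 mapped parts, all its parts are
    flagged ``is_split_part``.  *reads* is an optional FASTQ carrying
    sequences for hard-clipped records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    seq_by_read = _load_fastq(reads) if reads else {}

    parsed: list[ReadAlignment] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for rec in af:
                if rec.is_unmapped or rec.is_secondary:
                    continue
                if rec.cigartuples is None:
                    raise ValidationError(
                        f"mapped record {rec.query_name!r} without CIGAR"
                    )
                parsed.append(_parse_record(rec))
    finally:
        pysam.set_verbosity(save)

    # Fill sequences of hard-clipped/'*' records from the FASTQ side-channel
    # or from a sibling record of the same read that carries the full read.
    full_seq: dict[str, str] = dict(seq_by_read)
    for aln in parsed:
        if aln.read_seq and aln.read_id not in full_seq:
            full_seq[aln.read_id] = aln.read_seq
    kept: list[ReadAlignment] = []
    parts_per_read: dict[str, int] = {}
    for aln in parsed:
        if not aln.read_seq:
            aln.read_seq = full_seq.get(aln.read_id, "")
        if not aln.read_seq:
            logger.warning(
                "alignment for read %r has no recoverable sequence "
                "(hard-clipped or '*', absent from FASTQ); record skipped",
                aln.read_id,
            )
            continue
        if len(aln.read_seq) != aln.read_len:
            raise ValidationError(
                f"read {aln.read_id!r}: sequence length {len(aln.read_seq)} "
                f"does not match CIGAR-implied read length {aln.read_len}"
            )
        parts_per_read[aln.read_id] = parts_per_read.get(aln.read_id, 0) + 1
        kept.append(aln)

    by_scaffold: dict[str, list[ReadAlignment]] = {}
    for aln in kept:
        aln.is_split_part = parts_per_read[aln.read_id] >= 2
        by_scaffold.setdefault(aln.scaffold_id, []).append(aln)
    for alns in by_scaffold.values():
        alns.sort(key=lambda a: (a.ref_start, a.ref_end, a.read_id))
    return by_scaffold


def liftover_ref_to_read(aln: ReadAlignment, ref_pos: int) -> Optional[int]:
    """Map a reference coordinate to the read coordinate aligned to it.

    Returns the coordinate in original read orientation (so it decreases
    with ref_pos on '-' strand alignments).  A position inside a deletion
    maps to the read coordinate immediately right of the deletion (in
    aligned orientation).  Outside [ref_start, ref_end] returns None.
    """
    if ref_pos < aln.ref_start or ref_pos > aln.ref_end:
        return None
    rpos = aln.ref_start
    q = 0  # offset into the aligned part, aligned orientation
    if ref_pos < aln.ref_end:
        for op, n in aln.cigar:
            if op in "SH":
                continue
            if op in "M=X":
                if ref_pos < rpos + n:
                    q += ref_pos - rpos
                    break
                rpos += n
                q += n
            elif op == "I":
                q += n
            elif op == "D":
                if ref_pos < rpos + n:
                    break  # q already sits just after the deletion
                rpos += n
            else:
                raise ValidationError(f"unsupported CIGAR op {op!r}")
    else:
        q = aln.query_consumed
    if aln.strand == "+":
        return aln.read_start + q
    return aln.read_end - q


def _aligned_subseq(aln: ReadAlignment, ref_a: int, ref_b: int) -> str:
    """Read sequence aligned to reference interval [ref_a, ref_b), in
    reference orientation."""
    qa = liftover_ref_to_read(aln, ref_a)
    qb = liftover_ref_to_read(aln, ref_b)
    assert qa is not None and qb is not None
    if aln.strand == "+":
        return aln.read_seq[qa:qb]
    return revcomp(aln.read_seq[qb:qa])


def unsplit_spanning(
    alns: Iterable[ReadAlignment], gap: GapRecord, flank: int = 50
) -> list[SpanningEvidence]:
    """Evidence from non-split reads anchored >= *flank* bp on both sides.

    The extracted sequence runs from liftover(gap.start − flank) to
    liftover(gap.end + flank), i.e. it carries read-derived flanks.
    """
    out = []
    for aln in alns:
        if aln.is_split_part or aln.scaffold_id != gap.scaffold_id:
            continue
        if aln.ref_start <= gap.start - flank and aln.ref_end >= gap.end + flank:
            seq = _aligned_subseq(aln, gap.start - flank, gap.end + flank)
            out.append(
                SpanningEvidence(
                    gap_id=gap.gap_id,
                    read_id=aln.read_id,
                    pathway="unsplit",
                    extracted_seq=seq,
                    left_anchor_bp=gap.start - aln.ref_start,
                    right_anchor_bp=aln.ref_end - gap.end,
                )
            )
    return out


def split_groups(alns: Iterable[ReadAlignment]) -> dict[str, list[ReadAlignment]]:
    """Group split-part alignments by read id."""
    groups: dict[str, list[ReadAlignment]] = {}
    for aln in alns:
        if aln.is_split_part:
            groups.setdefault(aln.read_id, []).append(aln)
    return groups


def split_spanning(
    groups: Mapping[str, Sequence[ReadAlignment]],
    gap: GapRecord,
    min_split_gap: int = 3000,
    flank: int = 50,
    max_side_dist: int = 100,
) -> list[SpanningEvidence]:
    """Evidence from split reads bridging a large gap.

    A group qualifies when exactly one part ends within *max_side_dist* of
    the left gap edge and exactly one part starts within *max_side_dist* of
    the right edge, both parts on the same strand and in consistent read
    order.  The extracted sequence is the read interval strictly between
    the two parts (the unmapped middle), reference-oriented.  Gaps shorter
    than *min_split_gap* return an empty list by contract.
    """
    if gap.length < min_split_gap:
        return []
    out = []
    for read_id, parts in groups.items():
        lefts = [
            p
            for p in parts
            if p.scaffold_id == gap.scaffold_id
            and p.ref_start < gap.start
            and abs(p.ref_end - gap.start) <= max_side_dist
        ]
        rights = [
            p
            for p in parts
            if p.scaffold_id == gap.scaffold_id
            and p.ref_end > gap.end
            and abs(p.ref_start - gap.end) <= max_side_dist
        ]
        if not lefts or not rights:
            continue
        if len(lefts) > 1 or len(rights) > 1:
            logger.warning(
                "read %r: >2 candidate split parts around gap %s; skipped as "
                "ambiguous",
                read_id,
                gap.gap_id,
            )
            continue
        left, right = lefts[0], rights[0]
        if left is right or left.strand != right.strand:
            continue
        if left.strand == "+":
            if left.read_start > right.read_start:
                continue  # inconsistent read order
            a, b = left.read_end, right.read_start
            middle = left.read_seq[a:b] if b > a else ""
        else:
            if right.read_start > left.read_start:
                continue
            a, b = right.read_end, left.read_start
            middle = revcomp(left.read_seq[a:b]) if b > a else ""
        out.append(
            SpanningEvidence(
                gap_id=gap.gap_id,
                read_id=read_id,
                pathway="split",
                extracted_seq=middle,
                left_anchor_bp=gap.start - left.ref_start,
                right_anchor_bp=right.ref_end - gap.end,
            )
        )
    return out


def gather_evidence(
    alns_by_scaffold: Mapping[str, Sequence[ReadAlignment]],
    gaps: Iterable[GapRecord],
    flank: int = 50,
    min_split_gap: int = 3000,
    max_side_dist: int = 100,
) -> dict[str, list[SpanningEvidence]]:
    """Collect both evidence pathways for every gap.

    When one read yields both unsplit and split evidence for the same gap,
    the unsplit evidence wins and the split record is dropped with a
    warning.
    """
    evidence: dict[str, list[SpanningEvidence]] = {}
    for gap in gaps:
        alns = alns_by_scaffold.get(gap.scaffold_id, [])
        ev = unsplit_spanning(alns, gap, flank=flank)
        unsplit_reads = {e.read_id for e in ev}
        for e in split_spanning(
            split_groups(alns),
            gap,
            min_split_gap=min_split_gap,
            flank=flank,
            max_side_dist=max_side_dist,
        ):
            if e.read_id in unsplit_reads:
                logger.warning(
                    "read %r gave both pathways for gap %s; keeping unsplit",
                    e.read_id,
                    gap.gap_id,
                )
                continue
            ev.append(e)
        evidence[gap.gap_id] = ev
    return evidence


EVIDENCE_COLUMNS = [
    "gap_id",
    "read_id",
    "pathway",
    "left_anchor_bp",
    "right_anchor_bp",
    "extracted_len",
]


def evidence_rows(evidence: Mapping[str, Sequence[SpanningEvidence]]) -> list[dict]:
    """Flatten gathered evidence into TSV-report rows."""
    rows = []
    for gap_id in sorted(evidence):
        for e in evidence[gap_id]:
            rows.append(
                {
                    "gap_id": e.gap_id,
                    "read_id": e.read_id,
                    "pathway": e.pathway,
                    "left_anchor_bp": e.left_anchor_bp,
                    "right_anchor_bp": e.right_anchor_bp,
                    "extracted_len": len(e.extracted_seq),
                }
            )
    return rows
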