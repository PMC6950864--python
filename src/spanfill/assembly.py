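"""Assembly I/O, gap detection, and continuity statistics.

Scaffolds are plain upper-case nucleotide strings over {A,C,G,T,N}; gaps are
maximal N-runs.  Contigs are the pieces obtained by splitting scaffolds at
N-runs of at least ``contig_break_n`` bases.  All coordinates are 0-based,
half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from spanfill.errors import ValidationError

logger = logging.getLogger(__name__)

#: IUPAC one-letter nucleotide codes other than A/C/G/T/N; coerced to N on
#: input because downstream consensus only ever emits {A,C,G,T}.
AMBIGUOUS_IUPAC = frozenset("RYSWKMBDHVU")

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class Scaffold:
    """A named nucleotide sequence, possibly containing N-run gaps."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GapRecord:
    """One maximal N-run on a scaffold (0-based, half-open)."""

    gap_id: str
    scaffold_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    n_contigs: int
    total_bp: int
    total_N: int
    scaffold_n50: int
    contig_n50: int
    mean_contig: int
    n_gaps: int


def _normalize_seq(raw: str, record_id: str) -> tuple[str, int]:
    """Upper-case *raw*; map non-ACGTN IUPAC codes to N.

    Returns the cleaned sequence and the number of coerced characters.
    Characters outside the IUPAC alphabet are a fatal error.
    """
    seq = raw.upper()
    coerced = 0
    if set(seq) - _VALID:
        out = []
        for ch in seq:
            if ch in _VALID:
                out.append(ch)
            elif ch in AMBIGUOUS_IUPAC:
                out.append("N")
                coerced += 1
            else:
                raise ValidationError(
                    f"record {record_id!r}: non-IUPAC character {ch!r}"
                )
        seq = "".join(out)
    return seq, coerced


def read_fasta(path: str | Path) -> list[Scaffold]:
    """Read an assembly FASTA into a list of :class:`Scaffold`.

    Sequences are upper-cased and line-wrapping removed; ambiguity codes
    other than N are coerced to N (one warning reports the total count).
    Duplicate ids and empty sequences are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    n_coerced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq, coerced = _normalize_seq(str(rec.seq), rec.id)
        n_coerced += coerced
        if not seq:
            raise ValidationError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        scaffolds.append(Scaffold(id=rec.id, seq=seq))
    if not scaffolds:
        raise ValidationError(f"no FASTA records in {path}")
    if n_coerced:
        logger.warning(
            "%s: %d ambiguous IUPAC characters coerced to N", path, n_coerced
        )
    return scaffolds


def write_fasta(
    scaffolds: Sequence[Scaffold],
    path: str | Path,
    line_width: int = 60,
    first_record_comment: str | None = None,
) -> None:
    """Write scaffolds as FASTA with fixed line width.

    Round-trip property: ``read_fasta`` on the output reproduces ids and
    sequences exactly.  *first_record_comment*, if given, is appended to the
    first header as a description (ignored on re-read).
    """
    if not scaffolds:
        raise ValidationError("refusing to write an empty assembly")
    path = Path(path)
    records = []
    for i, sc in enumerate(scaffolds):
        desc = first_record_comment if (i == 0 and first_record_comment) else ""
        records.append(SeqRecord(Seq(sc.seq), id=sc.id, description=desc))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=line_width)
    writer.write_file(records)


_GAP_RE = re.compile(r"N+")


def find_gaps(scaffold: Scaffold, min_gap_length: int = 10) -> list[GapRecord]:
    """Locate maximal N-runs of length >= *min_gap_length*, sorted by start.

    Gap ids are ``<scaffold_id>:gap<k>`` with k the 0-based ordinal among
    the returned (qualifying) runs.
    """
    if min_gap_length < 1:
        raise ValidationError("min_gap_length must be >= 1")
    gaps = []
    k = 0
    for m in _GAP_RE.finditer(scaffold.seq):
        if m.end() - m.start() >= min_gap_length:
            gaps.append(
                GapRecord(
                    gap_id=f"{scaffold.id}:gap{k}",
                    scaffold_id=scaffold.id,
                    start=m.start(),
                    end=m.end(),
                )
            )
            k += 1
    return gaps


def n50(lengths: Iterable[int]) -> int:
    """N50 of a length multiset: the largest L such that lengths >= L sum
    to at least half the total."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValidationError("N50 of an empty length set is undefined")
    half = sum(ls) / 2
    acc = 0
    for L in ls:
        acc += L
        if acc >= half:
            return L
    return ls[-1]  # unreachable; appeases type checkers


def split_contigs(scaffold: Scaffold, contig_break_n: int = 10) -> list[str]:
    """Non-empty contig sequences obtained by splitting at N-runs of length
    >= *contig_break_n* (shorter N-runs stay inside contigs)."""
    pieces = []
    prev = 0
    for m in _GAP_RE.finditer(scaffold.seq):
        if m.end() - m.start() >= contig_break_n:
            if m.start() > prev:
                pieces.append(scaffold.seq[prev : m.start()])
            prev = m.end()
    if prev < len(scaffold.seq):
        pieces.append(scaffold.seq[prev:])
    return pieces


def assembly_stats(
    scaffolds: Sequence[Scaffold], contig_break_n: int = 10
) -> AssemblyStats:
    """Contig/scaffold continuity statistics for one assembly."""
    if not scaffolds:
        raise ValidationError("empty assembly")
    scaffold_lengths = [sc.length for sc in scaffolds]
    contig_lengths: list[int] = []
    total_N = 0
    n_gaps = 0
    for sc in scaffolds:
        total_N += sc.seq.count("N")
        n_gaps += len(find_gaps(sc, min_gap_length=contig_break_n))
        contig_lengths.extend(len(c) for c in split_contigs(sc, contig_break_n))
    return AssemblyStats(
        n_scaffolds=len(scaffolds),
        n_contigs=len(contig_lengths),
        total_bp=sum(scaffold_lengths),
        total_N=total_N,
        scaffold_n50=n50(scaffold_lengths),
        contig_n50=n50(contig_lengths),
        mean_contig=sum(contig_lengths) // len(contig_lengths),
        n_gaps=n_gaps,
    )


STATS_COLUMNS = [
    "assembly",
    "n_scaffolds",
    "n_contigs",
    "total_bp",
    "total_N",
    "scaffold_n50",
    "contig_n50",
    "mean_contig",
    "n_gaps",
]


def stats_row(name: str, stats: AssemblyStats) -> dict:
    """One TSV-report row (see :data:`STATS_COLUMNS`) for *stats*."""
    row = {"assembly": name}
    row.update({k: getattr(stats, k) for k in STATS_COLUMNS[1:]})
    return row
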