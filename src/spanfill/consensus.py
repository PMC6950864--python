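"""Per-gap consensus building and assembly patching.

Evidence sequences for a gap are pooled into a multiple sequence alignment
(center-star), a tie-dropping majority consensus is called, and the gap —
together with its reference flanks — is replaced by the consensus.  A gap
supported by a single read is filled with that read's raw sequence (the
single-read fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
from Bio import Align

from spanfill.assembly import GapRecord, Scaffold, assembly_stats
from spanfill.errors import ValidationError
from spanfill.evidence import SpanningEvidence

logger = logging.getLogger(__name__)

#: Alignment scores used when aligning evidence sequences to the center
#: sequence of the star: match, mismatch, gap open (first gap base), gap
#: extend (each further base).
DEFAULT_SCORES = {"match": 1, "mismatch": -1, "gap_open": -2, "gap_extend": -1}

#: Nominal gap sizes introduced by linked-read assemblers, used for report
#: binning.  Sizes within +/-10% of a nominal value fall in its bin.
SMALL_GAP_SIZES = (10, 100, 400)
LARGE_GAP_SIZES = (3000, 5000, 10000)


@dataclass(frozen=True)
class ConsensusResult:
    gap_id: str
    consensus_seq: str
    n_reads: int
    n_dropped_columns: int
    used_fallback: bool


@dataclass(frozen=True)
class PatchAction:
    """The closure decision for one gap.

    ``replace_start``/``replace_end`` delimit the interval on the pre-patch
    scaffold (gap plus reference flanks) that ``replacement_seq`` replaces
    when ``status == 'closed'``.
    """

    gap_id: str
    scaffold_id: str
    replace_start: int
    replace_end: int
    replacement_seq: str
    status: str  # 'closed' | 'uncovered' | 'ambiguous'
    coverage: int
    gap_length: int = 0
    pathway: str = "none"  # 'unsplit' | 'split' | 'mixed' | 'none'
    used_fallback: bool = False
    n_dropped_columns: int = 0


def _aligner(scores: Mapping[str, int]) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = scores["match"]
    al.mismatch_score = scores["mismatch"]
    al.open_gap_score = scores["gap_open"]
    al.extend_gap_score = scores["gap_extend"]
    return al


def _merge_into_star(
    master: str, rows: list[str], center_g: str, other_g: str
) -> tuple[str, list[str], str]:
    """Merge one pairwise alignment (center_g/other_g) into the star MSA.

    *master* is the center with all gaps accumulated so far; *rows* are the
    previously merged rows.  Gaps present in one version of the center but
    not the other are inserted into the lagging side ("once a gap, always a
    gap").  Returns the updated master, rows, and the gapped new row.
    """
    i = j = 0
    new_master: list[str] = []
    ins_old: list[tuple[int, int]] = []  # (position in old master, count)
    ins_new: list[tuple[int, int]] = []  # (position in center_g, count)
    while i < len(master) or j < len(center_g):
        a = master[i] if i < len(master) else None
        b = center_g[j] if j < len(center_g) else None
        if a == "-" and b == "-":
            new_master.append("-")
            i += 1
            j += 1
        elif a == "-":
            # gap already in master but not in this pairwise alignment
            new_master.append("-")
            ins_new.append((j, 1))
            i += 1
        elif b == "-":
            new_master.append("-")
            ins_old.append((i, 1))
            j += 1
        else:
            # same underlying center base
            new_master.append(a)
            i += 1
            j += 1

    def _apply(row: str, inserts: list[tuple[int, int]]) -> str:
        if not inserts:
            return row
        out = []
        prev = 0
        for pos, n in inserts:
            out.append(row[prev:pos])
            out.append("-" * n)
            prev = pos
        out.append(row[prev:])
        return "".join(out)

    rows = [_apply(r, ins_old) for r in rows]
    new_row = _apply(other_g, ins_new)
    return "".join(new_master), rows, new_row


def build_msa(
    seqs: Sequence[str],
    scores: Mapping[str, int] | None = None,
    center_candidates: Sequence[int] | None = None,
) -> list[str]:
    """Center-star multiple alignment of >= 2 non-empty sequences.

    The center is the candidate sequence with minimal summed edit distance
    to the others (lowest index on ties); every other sequence is globally
    aligned to it under :data:`DEFAULT_SCORES` and the pairwise alignments
    are merged under "once a gap, always a gap".  Removing '-' from row *i*
    reproduces ``seqs[i]``; all rows have equal length.

    *center_candidates* restricts which rows may serve as the center.
    Callers pooling short auxiliary rows (reference flank anchors) with
    full-length evidence must exclude the short rows: raw edit distance is
    length-biased, so a 50 bp anchor would otherwise look "closer" to
    every read than the reads are to each other and hijack the star.
    """
    if len(seqs) < 2:
        raise ValidationError("build_msa requires at least 2 sequences")
    if any(not s for s in seqs):
        raise ValidationError("build_msa sequences must be non-empty")
    scores = dict(DEFAULT_SCORES, **(scores or {}))
    k = len(seqs)
    candidates = list(center_candidates) if center_candidates else list(range(k))
    if not all(0 <= c < k for c in candidates):
        raise ValidationError("center_candidates out of range")
    dist = {c: 0 for c in candidates}
    for c in candidates:
        for j in range(k):
            if j != c:
                dist[c] += edlib.align(seqs[c], seqs[j], mode="NW")["editDistance"]
    center = min(candidates, key=lambda i: (dist[i], i))

    aligner = _aligner(scores)
    master = seqs[center]
    rows: list[str] = []
    order = [i for i in range(k) if i != center]
    for idx in order:
        aln = aligner.align(seqs[center], seqs[idx])[0]
        center_g, other_g = str(aln[0]), str(aln[1])
        master, rows, new_row = _merge_into_star(master, rows, center_g, other_g)
        rows.append(new_row)

    out_rows: list[str] = [""] * k
    out_rows[center] = master
    for slot, idx in enumerate(order):
        out_rows[idx] = rows[slot]
    return out_rows


def call_consensus(msa_rows: Sequence[str]) -> tuple[str, int]:
    """Tie-dropping plurality consensus over an MSA.

    Per column: the gap symbol suppresses emission only on strict
    plurality (gaps are not residues); otherwise the top-count base is
    emitted.  When two or more bases tie for the top count there is no
    highest-scoring residue, so the column is removed and counted in
    ``n_dropped_columns``.
    """
    if not msa_rows:
        raise ValidationError("empty MSA")
    width = len(msa_rows[0])
    if any(len(r) != width for r in msa_rows):
        raise ValidationError("MSA rows differ in length")
    out = []
    n_dropped = 0
    for col in range(width):
        counts: dict[str, int] = {}
        for row in msa_rows:
            ch = row[col]
            counts[ch] = counts.get(ch, 0) + 1
        gap_count = counts.pop("-", 0)
        if not counts:
            continue
        top = max(counts.values())
        if gap_count > top:
            continue  # strict gap plurality: nothing to emit
        winners = [ch for ch, c in counts.items() if c == top]
        if len(winners) == 1:
            out.append(winners[0])
        else:
            n_dropped += 1  # base-vs-base tie: column removed
    return "".join(out), n_dropped


def _resolve_pathways(evidence: Sequence[SpanningEvidence]) -> str:
    kinds = {e.pathway for e in evidence}
    if not kinds:
        return "none"
    if kinds == {"unsplit"}:
        return "unsplit"
    if kinds == {"split"}:
        return "split"
    return "mixed"


def close_gap(
    gap: GapRecord,
    evidence: Sequence[SpanningEvidence],
    ref_flank_left: str,
    ref_flank_right: str,
    scores: Mapping[str, int] | None = None,
) -> PatchAction:
    """Decide the patch for one gap from its pooled evidence.

    Coverage 0 leaves the gap ``uncovered``.  A single read fills the gap
    with its raw sequence (reference flanks are prepended/appended for the
    split pathway, whose middle carries no flanks).  With >= 2 reads an MSA
    is built — unsplit extracts plus the two reference flanks as separate
    anchor rows, split middles flank-augmented per row — and the consensus
    becomes the replacement.  A consensus shorter than the flanks plus one
    base marks the gap ``ambiguous`` and leaves it open.
    """
    fl, fr = ref_flank_left.upper(), ref_flank_right.upper()
    start = gap.start - len(fl)
    end = gap.end + len(fr)
    coverage = len(evidence)
    pathway = _resolve_pathways(evidence)

    def action(status: str, replacement: str, fallback=False, dropped=0) -> PatchAction:
        return PatchAction(
            gap_id=gap.gap_id,
            scaffold_id=gap.scaffold_id,
            replace_start=start,
            replace_end=end,
            replacement_seq=replacement,
            status=status,
            coverage=coverage,
            gap_length=gap.length,
            pathway=pathway,
            used_fallback=fallback,
            n_dropped_columns=dropped,
        )

    if coverage == 0:
        return action("uncovered", "")
    if coverage == 1:
        e = evidence[0]
        if e.pathway == "split":
            replacement = fl + e.extracted_seq + fr
        else:
            replacement = e.extracted_seq
        if not replacement:
            return action("ambiguous", "")
        return action("closed", replacement, fallback=True)

    rows_in: list[str] = []
    for e in evidence:
        if e.pathway == "split":
            rows_in.append(fl + e.extracted_seq + fr)
        elif e.extracted_seq:
            rows_in.append(e.extracted_seq)
    n_read_rows = len(rows_in)
    has_unsplit = any(e.pathway == "unsplit" for e in evidence)
    if has_unsplit:
        # reference flanks join as ordinary anchor rows, as in the pooled
        # per-gap fasta the method builds; they are never the star center
        if fl:
            rows_in.append(fl)
        if fr:
            rows_in.append(fr)
    if n_read_rows < 1 or len(rows_in) < 2:
        return action("ambiguous", "")
    msa = build_msa(rows_in, scores=scores, center_candidates=range(n_read_rows))
    cons, dropped = call_consensus(msa)
    if len(cons) < len(fl) + len(fr) + 1:
        return action("ambiguous", "", dropped=dropped)
    return action("closed", cons, dropped=dropped)


def ref_flanks(scaffold: Scaffold, gap: GapRecord, flank: int = 50) -> tuple[str, str]:
    """Up to *flank* bp of non-N assembly sequence on each side of a gap."""
    left = scaffold.seq[max(0, gap.start - flank) : gap.start]
    right = scaffold.seq[gap.end : gap.end + flank]
    # trim back to the nearest N so flanks never include a neighbouring gap
    if "N" in left:
        left = left[left.rfind("N") + 1 :]
    if "N" in right:
        right = right[: right.index("N")]
    return left, right


def close_all_gaps(
    scaffolds: Sequence[Scaffold],
    evidence: Mapping[str, Sequence[SpanningEvidence]],
    gaps: Iterable[GapRecord],
    flank: int = 50,
    scores: Mapping[str, int] | None = None,
) -> list[PatchAction]:
    """Run :func:`close_gap` for every gap, deriving reference flanks."""
    by_id = {sc.id: sc for sc in scaffolds}
    actions = []
    for gap in gaps:
        sc = by_id[gap.scaffold_id]
        fl, fr = ref_flanks(sc, gap, flank=flank)
        actions.append(
            close_gap(gap, evidence.get(gap.gap_id, []), fl, fr, scores=scores)
        )
    return actions


def size_class(length: int, tolerance: float = 0.10) -> str:
    """Bin a gap length against the fixed nominal sizes (+/- *tolerance*)."""
    for nominal in SMALL_GAP_SIZES + LARGE_GAP_SIZES:
        if abs(length - nominal) <= tolerance * nominal:
            return str(nominal)
    return "other"


def class_group(length: int) -> str:
    cls = size_class(length)
    if cls == "other":
        return "other"
    return "small" if int(cls) in SMALL_GAP_SIZES else "large"


REPORT_COLUMNS = [
    "gap_id",
    "scaffold",
    "class",
    "status",
    "pathway",
    "coverage",
    "old_len",
    "new_len",
]


def patch_assembly(
    scaffolds: Sequence[Scaffold],
    actions: Sequence[PatchAction],
    contig_break_n: int = 10,
) -> tuple[list[Scaffold], dict]:
    """Apply closed actions to the assembly and summarize the closure.

    Replacements on one scaffold are applied right-to-left so earlier
    coordinates stay valid.  Returns the patched scaffolds and a report
    with per-gap rows (:data:`REPORT_COLUMNS`) plus a summary block.
    """
    by_scaffold: dict[str, list[PatchAction]] = {}
    for act in actions:
        by_scaffold.setdefault(act.scaffold_id, []).append(act)

    known = {sc.id for sc in scaffolds}
    for sid, acts in by_scaffold.items():
        if sid not in known:
            raise ValidationError(f"action references unknown scaffold {sid!r}")
        closed = sorted(
            (a for a in acts if a.status == "closed"),
            key=lambda a: a.replace_start,
        )
        for prev, cur in zip(closed, closed[1:]):
            if cur.replace_start < prev.replace_end:
                raise ValidationError(
                    f"overlapping replace intervals on {sid}: "
                    f"{prev.gap_id} and {cur.gap_id}"
                )

    pre_stats = assembly_stats(scaffolds, contig_break_n)
    patched: list[Scaffold] = []
    touched = set()
    bp_change = 0
    rows = []
    for sc in scaffolds:
        acts = by_scaffold.get(sc.id, [])
        seq = sc.seq
        for act in sorted(acts, key=lambda a: -a.replace_start):
            old_len = act.replace_end - act.replace_start
            if act.status == "closed":
                seq = (
                    seq[: act.replace_start]
                    + act.replacement_seq
                    + seq[act.replace_end :]
                )
                bp_change += len(act.replacement_seq) - old_len
                touched.add(sc.id)
        patched.append(Scaffold(id=sc.id, seq=seq))

    for act in actions:
        old_len = act.replace_end - act.replace_start
        rows.append(
            {
                "gap_id": act.gap_id,
                "scaffold": act.scaffold_id,
                "class": class_group(act.gap_length),
                "status": act.status,
                "pathway": act.pathway,
                "coverage": act.coverage,
                "old_len": old_len,
                "new_len": len(act.replacement_seq)
                if act.status == "closed"
                else old_len,
            }
        )

    post_stats = assembly_stats(patched, contig_break_n)
    closed = [a for a in actions if a.status == "closed"]
    summary = {
        "n_gaps": len(actions),
        "n_closed": len(closed),
        "n_uncovered": sum(1 for a in actions if a.status == "uncovered"),
        "n_ambiguous": sum(1 for a in actions if a.status == "ambiguous"),
        "closed_by_class": _count_by_class(closed),
        "gaps_by_class": _count_by_class(actions),
        "mean_coverage_closed": (
            sum(a.coverage for a in closed) / len(closed) if closed else 0.0
        ),
        "n_fallback": sum(1 for a in closed if a.used_fallback),
        "scaffolds_touched": len(touched),
        "total_bp_change": bp_change,
        "pre_stats": pre_stats,
        "post_stats": post_stats,
    }
    return patched, {"rows": rows, "summary": summary}


def _count_by_class(actions: Iterable[PatchAction]) -> dict[str, int]:
    counts = {"small": 0, "large": 0, "other": 0}
    for act in actions:
        counts[class_group(act.gap_length)] += 1
    return counts
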