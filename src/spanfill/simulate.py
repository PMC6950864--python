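"""Synthetic fixture generation: truth genome, gapped assembly, noisy long
reads with truth alignments, and VCFs with planted ROH tracts.

The simulator emulates a linked-read draft assembly whose gaps have fixed
nominal sizes (10/100/400/3000/5000/10000 bp) and a long-read run with a
log-normal length distribution centered on a 6528 bp mean.  Truth
alignments are emitted directly (no external aligner): reads crossing a
gap smaller than 3 kb are written as single records whose CIGAR threads
through the N-run with M ops; reads crossing a gap of 3 kb or larger are
written as two split records (primary + supplementary) whose unaligned
middle holds the gap-spanning sequence.  All randomness flows from one
seeded generator, so outputs are byte-identical per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from spanfill.assembly import Scaffold, find_gaps, write_fasta
from spanfill.errors import ValidationError
from spanfill.evidence import revcomp

#: gaps at least this long are emitted as split alignments
SPLIT_THRESHOLD = 3000

#: alignments shorter than this are not emitted at all
MIN_SEGMENT = 30

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class SimConfig:
    """Study conditions for one synthetic fixture.

    Defaults describe the reference scenario used throughout the test
    suite: a 2 Mb diploid-agnostic genome in two scaffolds, ten gaps of
    each nominal size, 5x error-free long reads with the 6528 bp mean
    length, and a 1e-3/bp background heterozygosity.
    """

    seed: int = 42
    genome_bp: int = 2_000_000
    n_scaffolds: int = 2
    gc: float = 0.42
    gap_sizes: dict = field(
        default_factory=lambda: {10: 10, 100: 10, 400: 10, 3000: 10, 5000: 10, 10000: 10}
    )
    read_mean_len: int = 6528
    read_len_sd_log: float = 0.6
    depth: float = 5.0
    err_sub: float = 0.0
    err_ins: float = 0.0
    err_del: float = 0.0
    het_rate_bg: float = 1e-3
    roh_tracts: list = field(default_factory=list)  # (scaffold_id, start, end)
    flank: int = 50

    def validate(self) -> None:
        for name in ("err_sub", "err_ins", "err_del", "het_rate_bg"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(f"{name} must be in [0, 1), got {v}")
        if not (0.0 < self.gc < 1.0):
            raise ValidationError("gc must be in (0, 1)")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if self.genome_bp < 1 or self.n_scaffolds < 1:
            raise ValidationError("genome_bp and n_scaffolds must be positive")
        if any(int(s) < 1 or int(n) < 0 for s, n in self.gap_sizes.items()):
            raise ValidationError("gap sizes must be positive, counts non-negative")
        seen = []
        for sid, a, b in self.roh_tracts:
            if b <= a or a < 0:
                raise ValidationError(f"bad ROH tract ({sid},{a},{b})")
            for sid2, a2, b2 in seen:
                if sid == sid2 and a < b2 and a2 < b:
                    raise ValidationError("overlapping ROH tracts")
            seen.append((sid, a, b))


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    """Independent deterministic generator per pipeline stage."""
    return np.random.default_rng([cfg.seed, stream])


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _str_to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def make_genome(cfg: SimConfig) -> list[Scaffold]:
    """I.i.d. random scaffolds with P(G) + P(C) = gc, deterministic per seed."""
    cfg.validate()
    rng = _rng(cfg, 0)
    p = [(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2]
    per = cfg.genome_bp // cfg.n_scaffolds
    lengths = [per] * cfg.n_scaffolds
    lengths[-1] += cfg.genome_bp - per * cfg.n_scaffolds
    scaffolds = []
    for i, L in enumerate(lengths):
        codes = rng.choice(4, size=L, p=p).astype(np.uint8)
        scaffolds.append(Scaffold(id=f"scaf_{i + 1}", seq=_codes_to_str(codes)))
    return scaffolds


def make_gapped_assembly(
    truth: list[Scaffold], cfg: SimConfig
) -> tuple[list[Scaffold], pd.DataFrame]:
    """Plant the configured N-run gaps into copies of the truth scaffolds.

    Each gap replaces a truth segment of exactly its nominal size, so the
    gapped assembly has the same coordinates as the truth.  Gaps sit at
    least 2*flank from scaffold ends and at least 1 kb apart; placement
    failure after bounded retries is fatal.  Returns the gapped scaffolds
    and the truth table (gap_id, scaffold, start, end, length, truth_seq).
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    margin = 2 * cfg.flank
    min_dist = 1000
    wanted = []
    for size, count in sorted(cfg.gap_sizes.items(), reverse=True):
        wanted.extend([int(size)] * int(count))

    lengths = np.array([sc.length for sc in truth], dtype=float)
    placed: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(truth))}
    for size in wanted:
        ok = False
        for _ in range(2000):
            si = int(rng.choice(len(truth), p=lengths / lengths.sum()))
            L = truth[si].length
            lo, hi = margin, L - margin - size
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + size
            if all(
                start - e >= min_dist or s - end >= min_dist
                for s, e in placed[si]
            ):
                placed[si].append((start, end))
                ok = True
                break
        if not ok:
            raise ValidationError(
                f"could not place a {size} bp gap after bounded retries; "
                "genome too small for the requested gap set"
            )

    gapped = []
    for i, sc in enumerate(truth):
        seq = sc.seq
        for s, e in sorted(placed[i], reverse=True):
            seq = seq[:s] + "N" * (e - s) + seq[e:]
        gapped.append(Scaffold(id=sc.id, seq=seq))

    rows = []
    for i, sc in enumerate(gapped):
        for gap in find_gaps(sc, min_gap_length=min(cfg.gap_sizes, default=10)):
            rows.append(
                {
                    "gap_id": gap.gap_id,
                    "scaffold": gap.scaffold_id,
                    "start": gap.start,
                    "end": gap.end,
                    "length": gap.length,
                    "truth_seq": truth[i].seq[gap.start : gap.end],
                }
            )
    return gapped, pd.DataFrame(rows)


def _mutate_segment(
    codes: np.ndarray, rng: np.random.Generator, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply per-base substitution/insertion/deletion errors.

    Returns (read_codes, del_mask, ins_mask); masks index truth positions.
    Insertions are single random bases emitted after a kept truth base.
    """
    L = codes.size
    if cfg.err_sub == cfg.err_ins == cfg.err_del == 0.0:
        return codes.copy(), np.zeros(L, bool), np.zeros(L, bool)
    del_mask = rng.random(L) < cfg.err_del
    keep = ~del_mask
    sub_mask = (rng.random(L) < cfg.err_sub) & keep
    ins_mask = (rng.random(L) < cfg.err_ins) & keep

    mutated = codes.copy()
    idx = np.where(sub_mask)[0]
    if idx.size:
        mutated[idx] = (mutated[idx] + 1 + rng.integers(0, 3, idx.size)) % 4

    consumed = keep.astype(np.int64) + ins_mask.astype(np.int64)
    starts = np.concatenate(([0], np.cumsum(consumed)[:-1]))
    out = np.empty(int(consumed.sum()), dtype=np.uint8)
    out[starts[keep]] = mutated[keep]
    iidx = np.where(ins_mask)[0]
    if iidx.size:
        out[starts[iidx] + 1] = rng.integers(0, 4, iidx.size).astype(np.uint8)
    return out, del_mask, ins_mask


def _segment_cigar(
    a: int,
    b: int,
    del_mask: np.ndarray,
    ins_mask: np.ndarray,
    read_off: np.ndarray,
) -> tuple[list[tuple[str, int]], int, int, int, int]:
    """CIGAR for truth-relative interval [a, b) plus trimmed coordinates.

    Returns (cigar, ref_a, ref_b, read_a, read_b) where ref offsets are
    truth-relative and read offsets index the error-mutated read.  Leading
    and trailing D/I runs are trimmed into the flanking clips.
    """
    ev = np.where(del_mask[a:b] | ins_mask[a:b])[0] + a
    cig: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if cig and cig[-1][0] == op:
            cig[-1] = (op, cig[-1][1] + n)
        else:
            cig.append((op, n))

    prev = a
    for p in ev.tolist():
        push("M", p - prev)
        if del_mask[p]:
            push("D", 1)
        else:
            push("M", 1)
            push("I", 1)
        prev = p + 1
    push("M", b - prev)

    ref_a, ref_b = a, b
    read_a, read_b = int(read_off[a]), int(read_off[b])
    while cig and cig[0][0] in "DI":
        op, n = cig.pop(0)
        if op == "D":
            ref_a += n
        else:
            read_a += n
    while cig and cig[-1][0] in "DI":
        op, n = cig.pop()
        if op == "D":
            ref_b -= n
        else:
            read_b -= n
    return cig, ref_a, ref_b, read_a, read_b


def make_reads(
    truth: list[Scaffold],
    gapped: list[Scaffold],
    cfg: SimConfig,
    gap_table: pd.DataFrame | None = None,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Simulate long reads and their truth alignments to the gapped assembly.

    Returns (fastq_records, sam_records): fastq_records are (name, seq) in
    sequencing orientation; sam_records are dicts ready for SAM emission.
    Reads crossing a gap below :data:`SPLIT_THRESHOLD` stay single records
    (CIGAR M through the N-run); reads crossing a larger gap are split into
    primary + supplementary with the middle unaligned.  About half the
    reads are reverse-complemented.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    if gap_table is None:
        gap_table = pd.DataFrame(
            [
                {
                    "gap_id": g.gap_id,
                    "scaffold": g.scaffold_id,
                    "start": g.start,
                    "end": g.end,
                    "length": g.length,
                }
                for sc in gapped
                for g in find_gaps(sc)
            ]
        )
    large_gaps: dict[str, list[tuple[int, int]]] = {sc.id: [] for sc in truth}
    if len(gap_table):
        for _, row in gap_table.iterrows():
            if row["length"] >= SPLIT_THRESHOLD:
                large_gaps[row["scaffold"]].append((int(row["start"]), int(row["end"])))
    for v in large_gaps.values():
        v.sort()

    codes_by_scaffold = {sc.id: _str_to_codes(sc.seq) for sc in truth}
    lengths = np.array([sc.length for sc in truth], dtype=float)
    n_reads = max(1, int(round(cfg.depth * cfg.genome_bp / cfg.read_mean_len)))
    sigma = cfg.read_len_sd_log
    mu = np.log(cfg.read_mean_len) - sigma**2 / 2

    fastq: list[tuple[str, str]] = []
    sam: list[dict] = []
    for ridx in range(n_reads):
        name = f"read_{ridx + 1:06d}"
        si = int(rng.choice(len(truth), p=lengths / lengths.sum()))
        sc = truth[si]
        L = int(np.clip(np.round(rng.lognormal(mu, sigma)), 200, sc.length))
        s = int(rng.integers(0, sc.length - L + 1))
        e = s + L
        is_rev = bool(rng.random() < 0.5)

        seg_codes = codes_by_scaffold[sc.id][s:e]
        read_codes, del_mask, ins_mask = _mutate_segment(seg_codes, rng, cfg)
        read_fwd = _codes_to_str(read_codes)
        read_off = np.concatenate(
            ([0], np.cumsum((~del_mask).astype(np.int64) + ins_mask.astype(np.int64)))
        )
        fastq.append((name, revcomp(read_fwd) if is_rev else read_fwd))

        # mapped segments: read truth span minus large-gap intervals
        segments: list[tuple[int, int]] = []
        cur = s
        for gs, ge in large_gaps[sc.id]:
            if ge <= s or gs >= e:
                continue
            if gs > cur:
                segments.append((cur, gs))
            cur = max(cur, ge)
        if cur < e:
            segments.append((cur, e))
        segments = [(a, b) for a, b in segments if b - a >= MIN_SEGMENT]
        if not segments:
            continue

        parts = []
        for a, b in segments:
            cig, ref_a, ref_b, read_a, read_b = _segment_cigar(
                a - s, b - s, del_mask, ins_mask, read_off
            )
            if not cig or ref_b <= ref_a:
                continue
            parts.append(
                {
                    "ref_start": s + ref_a,
                    "cigar_core": cig,
                    "read_a": read_a,
                    "read_b": read_b,
                }
            )
        if not parts:
            continue
        primary_idx = max(range(len(parts)), key=lambda i: parts[i]["read_b"] - parts[i]["read_a"])
        read_len = len(read_fwd)
        for pi, part in enumerate(parts):
            is_primary = pi == primary_idx
            clip_l = part["read_a"]
            clip_r = read_len - part["read_b"]
            clip_op = "S" if is_primary else "H"
            cig = list(part["cigar_core"])
            if clip_l:
                cig.insert(0, (clip_op, clip_l))
            if clip_r:
                cig.append((clip_op, clip_r))
            seq = read_fwd if is_primary else read_fwd[part["read_a"] : part["read_b"]]
            flag = 0
            if is_rev:
                flag |= 0x10
            if not is_primary:
                flag |= 0x800
            sam.append(
                {
                    "name": name,
                    "flag": flag,
                    "scaffold": sc.id,
                    "pos": part["ref_start"],
                    "cigar": cig,
                    "seq": seq,
                }
            )
    return fastq, sam


def write_fastq(records: list[tuple[str, str]], path: str | Path, seed: int) -> None:
    with open(path, "w") as fh:
        for i, (name, seq) in enumerate(records):
            comment = f" seed={seed}" if i == 0 else ""
            fh.write(f"@{name}{comment}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sam(
    records: list[dict], gapped: list[Scaffold], path: str | Path, seed: int
) -> None:
    """Write truth alignments as coordinate-sorted SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": sc.id, "LN": sc.length} for sc in gapped],
        "CO": [f"spanfill_seed={seed}"],
    }
    tid = {sc.id: i for i, sc in enumerate(gapped)}
    code = {op: i for i, op in enumerate("MIDNSHP=X")}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (tid[r["scaffold"]], r["pos"], r["name"])):
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec["name"]
            a.flag = rec["flag"]
            a.reference_id = tid[rec["scaffold"]]
            a.reference_start = rec["pos"]
            a.mapping_quality = 60
            a.cigartuples = [(code[op], n) for op, n in rec["cigar"]]
            a.query_sequence = rec["seq"]
            out.write(a)


def make_vcf(
    scaffold_lengths: dict[str, int], cfg: SimConfig, path: str | Path
) -> None:
    """Write a single-sample VCF with planted het density and ROH tracts.

    Het sites occur at rate ``het_rate_bg`` per bp outside the configured
    tracts and never inside them; every genotype is 0/1 with constant
    depth and quality so default filters pass.  Byte-identical per seed.
    """
    cfg.validate()
    for sid, a, b in cfg.roh_tracts:
        if sid not in scaffold_lengths or b > scaffold_lengths[sid]:
            raise ValidationError(f"ROH tract ({sid},{a},{b}) outside scaffolds")
    rng = _rng(cfg, 3)
    header = pysam.VariantHeader()
    header.add_line(f"##spanfill_seed={cfg.seed}")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for sid, L in scaffold_lengths.items():
        header.add_line(f"##contig=<ID={sid},length={L}>")
    header.add_sample("sim")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for sid, L in scaffold_lengths.items():
            hits = np.where(rng.random(L) < cfg.het_rate_bg)[0]
            for sid2, a, b in cfg.roh_tracts:
                if sid2 == sid:
                    hits = hits[(hits < a) | (hits >= b)]
            for pos in hits.tolist():
                ref_i = int(rng.integers(0, 4))
                alt_i = (ref_i + 1 + int(rng.integers(0, 3))) % 4
                rec = out.new_record(
                    contig=sid,
                    start=pos,
                    stop=pos + 1,
                    alleles=("ACGT"[ref_i], "ACGT"[alt_i]),
                    qual=50,
                )
                rec.samples["sim"]["GT"] = (0, 1)
                rec.samples["sim"]["DP"] = 20
                out.write(rec)


def make_fixture(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full fixture file set under *out_dir*.

    Writes truth.fa, gapped.fa, gaps.tsv, reads.fastq, reads.sam,
    sites.vcf, and manifest.json; returns the path of each.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        name: out_dir / name
        for name in (
            "truth.fa",
            "gapped.fa",
            "gaps.tsv",
            "reads.fastq",
            "reads.sam",
            "sites.vcf",
            "manifest.json",
        )
    }
    truth = make_genome(cfg)
    gapped, gap_table = make_gapped_assembly(truth, cfg)
    write_fasta(truth, paths["truth.fa"], first_record_comment=f"seed={cfg.seed}")
    write_fasta(gapped, paths["gapped.fa"], first_record_comment=f"seed={cfg.seed}")
    with open(paths["gaps.tsv"], "w") as fh:
        fh.write(f"# spanfill_seed={cfg.seed}\n")
        gap_table.to_csv(fh, sep="\t", index=False)
    fastq, sam = make_reads(truth, gapped, cfg, gap_table)
    write_fastq(fastq, paths["reads.fastq"], cfg.seed)
    write_sam(sam, gapped, paths["reads.sam"], cfg.seed)
    make_vcf({sc.id: sc.length for sc in truth}, cfg, paths["sites.vcf"])
    from spanfill import __version__

    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "files": sorted(p.name for p in paths.values()),
        "tool_version": __version__,
    }
    with open(paths["manifest.json"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return paths
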