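"""Windowed heterozygosity and runs-of-homozygosity summaries.

Heterozygous sites are counted in fixed-width bins (default 1 Mb) across
each scaffold; the per-kb het frequency of low-het bin runs serves as a
proxy for runs of homozygosity.  ROH segment tables in the BCFtools-RoH
"RG"-line dialect are parsed and summarized into the three conventional
length classes: short (10-100 kb), medium (100 kb-1 Mb), long (>= 1 Mb);
segments under 10 kb are reported separately as 'sub'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from spanfill.errors import ValidationError

logger = logging.getLogger(__name__)

BIN_SIZE_DEFAULT = 1_000_000

#: length-class boundaries, half-open on the right: [low, high)
LENGTH_CLASSES = {
    "sub": (0, 10_000),
    "short": (10_000, 100_000),
    "medium": (100_000, 1_000_000),
    "long": (1_000_000, None),
}


@dataclass(frozen=True)
class HetWindow:
    scaffold_id: str
    bin_start: int
    bin_end: int
    het_count: int

    @property
    def het_per_kb(self) -> float:
        return self.het_count / ((self.bin_end - self.bin_start) / 1000.0)


def length_class(length: int) -> str:
    for name, (lo, hi) in LENGTH_CLASSES.items():
        if length >= lo and (hi is None or length < hi):
            return name
    raise ValidationError(f"negative segment length {length}")


@dataclass(frozen=True)
class RohSegment:
    scaffold_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_class(self) -> str:
        return length_class(self.length)


def _is_snp_genotype(ref: str, alts: Sequence[str], gt: Sequence[int]) -> bool:
    """True when every allele the genotype calls is a single base."""
    alleles = [ref] + list(alts or [])
    for a in gt:
        if a >= len(alleles) or alleles[a] is None or len(alleles[a]) != 1:
            return False
    return True


def read_het_sites(
    vcf_path: str | Path,
    sample: str,
    min_dp: int | None = None,
    min_qual: float | None = None,
    include_indels: bool = False,
) -> dict[str, np.ndarray]:
    """Per-scaffold sorted 0-based positions of heterozygous genotypes.

    A site is heterozygous iff the sample GT carries two called, distinct
    alleles (phased or unphased); missing and homozygous genotypes are
    excluded, multi-allelic hets included, indel records excluded unless
    *include_indels*.  Optional depth/quality filters mirror the usual
    ``DP > x & QUAL > y`` site filtering applied before ROH analysis.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(f"VCF not found: {vcf_path}")
    save = pysam.set_verbosity(0)
    try:
        vf = pysam.VariantFile(str(vcf_path))
    finally:
        pysam.set_verbosity(save)
    if sample not in list(vf.header.samples):
        raise ValidationError(f"sample {sample!r} absent from {vcf_path}")
    positions: dict[str, list[int]] = {}
    with vf:
        for rec in vf:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                continue
            if gt[0] == gt[1]:
                continue
            if min_qual is not None and (rec.qual is None or rec.qual <= min_qual):
                continue
            if min_dp is not None:
                dp = call.get("DP")
                if dp is None or dp <= min_dp:
                    continue
            if not include_indels and not _is_snp_genotype(rec.ref, rec.alts, gt):
                continue
            positions.setdefault(rec.chrom, []).append(rec.pos - 1)
    return {
        chrom: np.asarray(sorted(pos), dtype=np.int64)
        for chrom, pos in positions.items()
    }


def het_windows(
    het_positions: Mapping[str, np.ndarray],
    scaffold_lengths: Mapping[str, int],
    bin_size: int = BIN_SIZE_DEFAULT,
) -> list[HetWindow]:
    """Tile each scaffold with *bin_size* windows and count het sites.

    The last bin is truncated to the scaffold end and normalized by its
    true width.  A position at or beyond the scaffold length is fatal.
    """
    if bin_size < 1:
        raise ValidationError("bin_size must be >= 1")
    windows: list[HetWindow] = []
    for sid in scaffold_lengths:
        length = scaffold_lengths[sid]
        pos = np.asarray(het_positions.get(sid, np.empty(0, dtype=np.int64)))
        if pos.size and int(pos.max()) >= length:
            raise ValidationError(
                f"het position {int(pos.max())} >= scaffold length {length} on {sid}"
            )
        n_bins = max(1, -(-length // bin_size))
        counts = np.bincount(pos // bin_size, minlength=n_bins) if pos.size else np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            windows.append(
                HetWindow(
                    scaffold_id=sid,
                    bin_start=b * bin_size,
                    bin_end=min((b + 1) * bin_size, length),
                    het_count=int(counts[b]),
                )
            )
    return windows


def het_histogram(
    windows: Sequence[HetWindow], breaks: Sequence[float] | None = None
) -> pd.DataFrame:
    """Frequency of bins by het sites per kb over half-open intervals.

    *breaks* are the left edges (default 0.0, 0.2, ... 2.0); the last
    interval is open-ended.
    """
    if breaks is None:
        breaks = [round(0.2 * i, 10) for i in range(11)]
    edges = list(breaks) + [float("inf")]
    vals = [w.het_per_kb for w in windows]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        n = sum(1 for v in vals if lo <= v < hi)
        rows.append(
            {
                "het_per_kb_min": lo,
                "het_per_kb_max": hi,
                "n_bins": n,
                "frequency": n / len(vals) if vals else 0.0,
            }
        )
    return pd.DataFrame(rows)


def read_roh_segments(
    path: str | Path, dialect: str = "bcftools_rg"
) -> list[RohSegment]:
    """Parse BCFtools-RoH output, keeping the RG (region) lines.

    Input coordinates are 1-based inclusive and converted to 0-based
    half-open; the file's length column is checked against the coordinates
    (warning on mismatch).  Overlapping segments are kept with a warning.
    """
    if dialect != "bcftools_rg":
        raise ValidationError(f"unknown ROH table dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROH table not found: {path}")
    segments: list[RohSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("RG"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                chrom = fields[2]
                start1, end1 = int(fields[3]), int(fields[4])
                file_len = int(fields[5]) if len(fields) > 5 else None
            except (IndexError, ValueError) as exc:
                raise ValidationError(
                    f"{path}:{lineno}: unparsable RG line: {line!r}"
                ) from exc
            start, end = start1 - 1, end1  # to 0-based half-open
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: non-positive ROH interval [{start1},{end1}]"
                )
            if file_len is not None and file_len != end - start:
                logger.warning(
                    "%s:%d: length column %d != coordinate span %d",
                    path,
                    lineno,
                    file_len,
                    end - start,
                )
            segments.append(RohSegment(scaffold_id=chrom, start=start, end=end))
    segments.sort(key=lambda s: (s.scaffold_id, s.start, s.end))
    for a, b in zip(segments, segments[1:]):
        if a.scaffold_id == b.scaffold_id and b.start < a.end:
            logger.warning(
                "overlapping ROH segments on %s: [%d,%d) and [%d,%d)",
                a.scaffold_id,
                a.start,
                a.end,
                b.start,
                b.end,
            )
    return segments


def roh_summary(segments: Iterable[RohSegment], genome_size: int) -> pd.DataFrame:
    """Count, total bp, and genome fraction per ROH length class.

    The 'sub' class (< 10 kb) is reported separately and excluded from the
    three conventional classes.
    """
    if genome_size <= 0:
        raise ValidationError("genome_size must be positive")
    rows = []
    segs = list(segments)
    for name in ("short", "medium", "long", "sub"):
        in_class = [s for s in segs if s.length_class == name]
        bp = sum(s.length for s in in_class)
        rows.append(
            {
                "class": name,
                "count": len(in_class),
                "bp": bp,
                "fraction": bp / genome_size,
            }
        )
    return pd.DataFrame(rows)


def proxy_roh_from_windows(
    windows: Sequence[HetWindow], max_het_per_kb: float = 0.1
) -> list[RohSegment]:
    """Merge maximal runs of low-heterozygosity bins into ROH segments.

    Consecutive bins on one scaffold with ``het_per_kb <= max_het_per_kb``
    become one segment.  This is the windowed proxy for ROH, not an HMM
    segmentation; the threshold is a tuning knob.
    """
    segments: list[RohSegment] = []
    by_scaffold: dict[str, list[HetWindow]] = {}
    for w in windows:
        by_scaffold.setdefault(w.scaffold_id, []).append(w)
    for sid, ws in by_scaffold.items():
        ws = sorted(ws, key=lambda w: w.bin_start)
        run_start = None
        prev_end = None
        for w in ws:
            low = w.het_per_kb <= max_het_per_kb
            contiguous = prev_end is not None and w.bin_start == prev_end
            if low and run_start is not None and contiguous:
                prev_end = w.bin_end
            elif low:
                if run_start is not None:
                    segments.append(RohSegment(sid, run_start, prev_end))
                run_start, prev_end = w.bin_start, w.bin_end
            else:
                if run_start is not None:
                    segments.append(RohSegment(sid, run_start, prev_end))
                    run_start = None
                prev_end = w.bin_end
        if run_start is not None:
            segments.append(RohSegment(sid, run_start, prev_end))
    segments.sort(key=lambda s: (s.scaffold_id, s.start))
    return segments


def windows_frame(windows: Sequence[HetWindow]) -> pd.DataFrame:
    """Windows as a TSV-ready DataFrame."""
    return pd.DataFrame(
        {
            "scaffold": [w.scaffold_id for w in windows],
            "bin_start": [w.bin_start for w in windows],
            "bin_end": [w.bin_end for w in windows],
            "het_count": [w.het_count for w in windows],
            "het_per_kb": [w.het_per_kb for w in windows],
        }
    )
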