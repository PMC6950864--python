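# Methods

## Gap model and coordinates

A *gap* is a maximal run of `N` of length ≥ `min_gap_length` (default 10,
the smallest nominal gap size linked-read assemblers introduce; shorter
N-runs are treated as sequence ambiguity, not as joins). All coordinates
are 0-based, half-open everywhere in the library; SAM's 1-based positions
are converted at the parser boundary, which keeps the CIGAR arithmetic
free of off-by-one cases. *Contigs* are the pieces obtained by splitting
scaffolds at N-runs of length ≥ `contig_break_n` (default 10,
configurable because Assemblathon-style scripts use other cutoffs);
shorter N-runs remain inside contigs, so the mass balance is
`contig bp + N bp in break-length runs = total bp`, while `total_N`
counts every `N`. N50 is the largest length L such that members ≥ L sum
to at least half the total; the same rule serves scaffolds and contigs.

Input FASTA is upper-cased; IUPAC ambiguity codes other than `N` are
coerced to `N` with a counted warning rather than rejected, because the
consensus stage only ever emits `{A,C,G,T}` and a draft assembly with a
scattering of `R`/`Y` codes should not abort a run.

## Evidence pathways

Each gap can be supported through two routes, mirroring how an aligner
actually reports gap-crossing long reads:

* **unsplit** — one alignment record covering
  `[gap.start − flank, gap.end + flank]` with `flank = 50` bp. The
  extracted sequence is the read interval between the lifted-over flank
  positions, so its ends are read-derived flank copies. Liftover walks
  the CIGAR; a reference position inside a deletion maps to the read
  coordinate immediately after the deletion, and `ref_end` maps to the
  end of the aligned read interval.
* **split** (gaps ≥ `min_split_gap` = 3000 bp) — a read reported as ≥ 2
  records whose parts bracket the gap: one part ends within
  `max_side_dist` (default 100 bp) of the left gap edge, another starts
  within `max_side_dist` of the right edge, both on the same strand and
  in consistent read order. The *unmapped middle* — the read interval
  strictly between the parts — is the evidence. `max_side_dist` is a
  tolerance for noisy alignment ends, not a biological quantity; split
  parts of error-free alignments end exactly at the gap edges. Groups
  offering more than one candidate part per side are skipped as
  ambiguous rather than guessed. Parts that overlap on the read yield an
  empty middle (clamped, never negative).

All read coordinates and sequences are normalized to the original read
orientation at parse time; every extracted sequence is returned in
reference orientation (reverse-complemented for `−` strand), the only
convention under which flank concatenation is well defined. Hard-clipped
supplementary records recover their full-length sequence from the
primary record of the same read, or from an optional FASTQ side-channel;
records whose sequence cannot be recovered are skipped with a warning.
When one read yields both pathway types for a gap, the unsplit evidence
wins (it carries verified flank anchoring on both sides).

## Consensus and patching

With one spanning read the gap is filled with that read's raw sequence
(split middles get the reference flanks prepended/appended; unsplit
extracts already carry read flanks). With ≥ 2 reads the pooled per-gap
sequences go through a center-star multiple alignment:

* Rows: unsplit extracts as-is plus the two ≤ 50 bp reference flanks as
  separate anchor rows; split middles are flank-augmented per row
  (`left + middle + right`) before alignment.
* The center is the evidence row with minimal summed edit distance to all
  rows (lowest index on ties). Anchor rows are never center candidates:
  raw edit distance is length-biased, so a 50 bp anchor would otherwise
  look "closer" to every read than the reads are to each other and
  collapse the star. Edit distances come from banded
  Needleman–Wunsch (edlib), which is effectively linear for near-identical
  reads; the summed-score and summed-distance rankings agree in that
  regime, and the distance form keeps 10 kb gaps tractable.
* Every other row is globally aligned to the center with match +1,
  mismatch −1, gap open −2, gap extend −1 (Needleman–Wunsch with affine
  ends, Biopython's pairwise aligner), and the pairwise alignments are
  merged under "once a gap, always a gap".

Consensus is per-column plurality over the rows. Gaps are not residues:
the gap symbol suppresses emission only on a strict plurality; otherwise
the top-count base is emitted, and a base-vs-base tie for the top count
removes the column (counted in `n_dropped_columns`). This residue-based
reading is what makes the method self-consistent at coverage 2: with two
agreeing reads plus the two anchor rows, every gap-interior column is two
bases against two gaps, and a gap-vetoing rule would erase the entire
interior.

The replacement interval is the gap plus its reference flanks, i.e. the
assembly flanks are themselves replaced by the (flank-anchored) consensus
ends; a consensus shorter than the flanks plus one base marks the gap
`ambiguous` and leaves it open. Replacements on one scaffold are applied
right-to-left so earlier coordinates stay valid, and overlapping
replacement intervals are rejected. No minimum-coverage filter beyond ≥ 1
read is imposed — per-gap coverage is an outcome, reported per gap and
summarized by size class (nominal sizes matched with ±10% tolerance so
real data bins sensibly).

## Heterozygosity windows and ROH

A site is heterozygous iff the sample's GT carries two called, distinct
alleles (phased or unphased); missing and homozygous genotypes are
excluded, multi-allelic heterozygotes included, and indel records
excluded by default (genotype calls at indels are error-enriched).
Optional `DP > x` / `QUAL > y` site filters mirror the usual pre-ROH VCF
filtering. Sites are counted in `bin_size` windows (default 1 Mb, an
intermediate ROH length scale); the final truncated bin is kept and
normalized by its true width. Maximal runs of consecutive bins with
`het/kb ≤ max_het_per_kb` (default 0.1, a tuning knob with no canonical
value) merge into proxy ROH segments — a visual-scale segmentation, not
an HMM, so tracts shorter than a bin are invisible to it and tract edges
are resolved only to bin precision.

ROH segment tables in the BCFtools/RoH `RG`-line dialect are parsed
(1-based inclusive → 0-based half-open; the file's length column is
cross-checked, mismatches warn; overlaps are kept with a warning). The
HMM that produced them is out of scope. Length classes are half-open:
`sub < 10 kb ≤ short < 100 kb ≤ medium < 1 Mb ≤ long`; the boundary
assignment (exactly 100 kb → medium) is this package's convention, stated
in the report header, and the `sub` class is reported separately so the
three conventional classes match the usual presentation. Fractions are
`class bp / genome_size`.

## Synthetic data generator

The generator emulates the study conditions end to end with a single
seeded RNG per stage (so every output file is byte-identical per seed):

* **Genome** — i.i.d. bases at configurable GC (default 0.42, a typical
  mammalian composition), split into equal scaffolds.
* **Gapped assembly** — each requested gap replaces a truth segment of
  exactly its nominal size ({10, 100, 400, 3000, 5000, 10000} bp, ten of
  each by default), ≥ 2×flank from scaffold ends and ≥ 1 kb apart, so
  assembly and truth share coordinates and every closure can be scored
  against the hidden sequence.
* **Reads** — log-normal lengths (σ_log 0.6) with mean 6528 bp, uniform
  starts, per-base substitution/insertion/deletion errors, ~50%
  reverse-complemented. Truth alignments are emitted directly instead of
  running an aligner: reads crossing a gap < 3 kb stay single records
  whose CIGAR threads the N-run with `M` ops (fixed-size gap estimates
  let real aligners thread through the same way); reads crossing a gap
  ≥ 3 kb become primary + supplementary split records whose clips encode
  the unaligned middle; reads falling entirely within a large gap's
  hidden segment are unmappable and emit no record. Alignments shorter
  than 30 bp are suppressed.
* **VCF** — heterozygous sites at a background per-bp rate (default
  1e-3) outside planted ROH tracts and zero inside, GT `0/1` with
  constant DP/QUAL.

What the generator does *not* emulate: homopolymer-biased nanopore error
profiles, quality-score variation, chimeric reads, mapping ambiguity in
repeats, genotyping error inside ROH. Passing tests therefore demonstrate
the correctness of the coordinate arithmetic, evidence classification,
consensus logic, and patch bookkeeping under realistic coverage and error
rates — not robustness to alignment artifacts of repeat-rich real
genomes.

## Problem sizes and defaults

The reference test conditions are a 2 Mb genome in two scaffolds with 60
gaps (ten per size class): large enough that every pathway, coverage
regime (including single-read fallbacks and uncovered 10 kb gaps at 5×),
and both strands are exercised, while a full simulate → close → verify
cycle stays in the tens of seconds. The het/ROH analyses run at 10 Mb
with planted tracts of 50 kb / 500 kb / 2 Mb, spanning all three length
classes around the 1 Mb bin scale. `scripts/acceptance.py` re-runs these
conditions from scratch and reports the measured quantities.

## Known limitations

* Closure quality at coverage 2 is the weak spot: disagreeing columns
  are ties, so errors drop columns rather than being outvoted, and
  measured identity of coverage-2 patches of 5–10 kb gaps is ~92–95%
  versus ~98%+ at coverage ≥ 3.
* The proxy ROH caller cannot see sub-bin tracts and is threshold-dependent;
  use real BCFtools/RoH output where genotype likelihoods are available.
* PAF input is not supported; alignments must be SAM/BAM. The package
  never computes alignments to a reference itself.
* The patched assembly is not re-polished: sequence outside replacement
  intervals is untouched by design, and no iterative re-mapping rounds
  are performed.
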