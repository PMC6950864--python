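# spanfill

Close N-run gaps in draft genome assemblies from spanning long reads, and
profile heterozygosity and runs of homozygosity (ROH) — the downstream
finishing and population-genetic summaries typically applied to
linked-read + Hi-C mammalian assemblies polished with a modest amount of
nanopore data.

## The problem

Linked-read assemblers join contigs into scaffolds with runs of `N` whose
lengths are drawn from a fixed menu (10, 100, 400 bp for short joins;
3000, 5000, 10000 bp for long ones). Even low-coverage long reads can
recover the missing sequence:

* **Unsplit pathway** — a read whose single alignment covers a gap *and*
  at least *f* = 50 aligned bases on both sides. The read subsequence
  between the lifted-over positions of `gap.start − f` and `gap.end + f`
  is extracted (CIGAR-walk coordinate liftover), so it carries
  read-derived flanks.
* **Split pathway** (gaps ≥ 3 kb) — a read the aligner reported as two
  parts, one ending near the left gap edge and one starting near the
  right edge, same strand, consistent read order. The read interval
  strictly between the parts — the unmapped middle — bridges the gap.

Per gap, all extracted sequences are pooled into a center-star multiple
alignment (match +1, mismatch −1, gap open −2, gap extend −1) together
with ≤ 50 bp reference flanks, and a plurality consensus is called: a
column emits its top base; columns where two bases tie are removed; a gap
majority emits nothing. The gap plus its reference flanks is then
replaced by the consensus. A gap spanned by a single read is filled with
that read's raw sequence (single-read fallback). Continuity is reported
before and after patching (N50: the largest L such that sequences ≥ L
cover half the assembly).

For inbreeding profiles, heterozygous sites from a VCF are counted in
1 Mb bins (het/kb per bin), low-het bin runs give a proxy ROH
segmentation, and ROH segments — proxy-derived or parsed from
BCFtools/RoH `RG` tables — are summarized into the conventional length
classes: 10–100 kb, 100 kb–1 Mb, and ≥ 1 Mb, with the genome fraction in
each.

A fully synthetic fixture generator (truth genome → gapped assembly →
noisy reads with truth alignments → planted-ROH VCFs) makes every stage
testable end to end without any external data or aligner.

## Worked example

```sh
spanfill simulate --out-dir demo --seed 7 --genome-bp 500000 \
    --gaps-per-size 2 --depth 8
spanfill close --assembly demo/gapped.fa --alignments demo/reads.sam \
    --out-dir demo_closed
spanfill stats demo/gapped.fa demo_closed/patched.fa
```

The `close` step logs

```
closed 11/12 gaps (uncovered 1, ambiguous 0); contig N50 51680 -> 250000
```

and `stats` prints one row per assembly:

```
assembly     n_scaffolds  n_contigs  total_bp  total_N  scaffold_n50  contig_n50  mean_contig  n_gaps
gapped.fa    2            14         500000    37020    250000        51680       33070        12
patched.fa   2            3          500000    10000    250000        250000      163333       1
```

Eleven of the twelve planted gaps were closed (the twelfth, a 10 kb gap,
happened to attract no spanning read at 8× coverage, so it stays open
rather than being guessed): 27 kb of `N` was replaced by read-derived
sequence, the contig count dropped from 14 to 3, and contig N50 rose from
52 kb to the 250 kb scaffold size. `demo_closed/closure_report.tsv` holds
the per-gap detail (status, pathway, coverage, lengths), e.g.

```
gap_id       scaffold  class  status     pathway  coverage  old_len  new_len
scaf_1:gap0  scaf_1    large  uncovered  none     0         10100    10100
scaf_1:gap1  scaf_1    small  closed     unsplit  3         500      500
scaf_1:gap2  scaf_1    large  closed     split    8         3100     3100
...
```

For the variant side:

```sh
spanfill hetwin --vcf demo/sites.vcf --sample sim --out-dir demo_het
spanfill rohclass --vcf demo/sites.vcf --sample sim --out-dir demo_roh
spanfill rohclass --roh bcftools_roh_output.txt --genome-size 2400000000 \
    --out-dir roh_classes   # RG-line dialect
```

## Layout

| module               | contents                                                          |
| -------------------- | ----------------------------------------------------------------- |
| `spanfill.assembly`  | FASTA I/O, gap detection, contig/scaffold continuity statistics   |
| `spanfill.evidence`  | SAM parsing, CIGAR liftover, unsplit/split spanning evidence      |
| `spanfill.consensus` | center-star MSA, tie-dropping consensus, gap closure and patching |
| `spanfill.hetroh`    | het windows, ROH table parsing, length classes, proxy ROH caller  |
| `spanfill.simulate`  | synthetic genomes, gapped assemblies, reads + truth SAM, VCFs     |
| `spanfill.cli`       | `spanfill` subcommands: stats, close, hetwin, rohclass, simulate  |

Design notes, parameter defaults, and known limitations are documented in
[docs/methods.md](docs/methods.md).
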