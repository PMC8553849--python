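# Methods

## The rewrite model

`bamscrub` treats genotype removal as a coordinate-geometry problem. Each
mapped record's CIGAR is resolved into a `ResolvedLayout`: an ordered list
of reference *match blocks* `(ref_start, length)` separated by splice
gaps, plus a possibly adjusted start position. The output record is then
fully determined: its sequence is the concatenated reference over the
blocks, its CIGAR alternates M and N, its MD (when the input carried one)
is the total matched length, and its edit distance is zero.

Layout resolution applies these rules jointly:

1. M/=/X consume query and reference 1:1 and form blocks ("=" and X carry
   no information once everything is reference; both become M).
2. I schedules a 3′ extension of its length; D adds its reference span to
   the current block and schedules an equal 3′ trim. P is dropped.
3. N closes the current block and opens the next at the skipped position;
   gap coordinates are untouched.
4. A leading S/H run of combined length *k* (treated as one unit,
   outermost first) shifts the start to `pos − k` for single-end records;
   for paired records the start is pinned and *k* joins the 3′ extension.
   Trailing clips always extend the 3′ end. Hard clips additionally
   materialize previously unstored bases.
5. The net extension/trim is applied at the rightmost reference
   coordinate of the layout — reference orientation, regardless of the
   strand flag, because shifting at a reversed read's biological 5′ end
   would move the mapping position. A trim that consumes an entire
   terminal exon deletes that exon's splice gap and continues leftward.
6. Total block length always equals stored-sequence length plus hard-clip
   length (asserted internally).

A trim can never consume the whole layout for a structurally valid CIGAR:
the deletion that schedules the trim first contributes an equal reference
span to the blocks, so at least the M bases survive. The degenerate branch
remains as defensive code, reachable only for pathological inputs (e.g. a
CIGAR with no M/=/X op, such as a fully soft-clipped `100S` record), which
are discarded.

Records whose resolved layout would start before position 0 or run past
the contig end are discarded and counted (`out_of_range`), not truncated:
truncation would break length conservation and leave a detectable scar.

## Field and tag policy

Edit distances (NM, nM) are set to 0 where present; alignment-description
tags (MC, XN, XM, XO, XG) are dropped. Strict mode additionally sets MAPQ
to 255, AS/MQ to the final read length, NH to 1, and drops
HI/IH/H1/H2/OA/OC/OP/OQ/SA/SM/XA/XS. Tags are rewritten only when already
present — adding a tag the input lacked would itself be a detectable
artifact. Everything else (barcodes, UMIs, gene tags, read groups, custom
flags) passes through untouched; the policy is idempotent and
property-tested against randomized tag dictionaries.

Base qualities are passed through unchanged. Resolving an indel therefore
leaves qualities out of phase with the rewritten bases; editing them to
"match" would advertise exactly where variation was removed. Bases
materialized from hard clips receive a configurable fill quality
(default `#`, Phred 2) on the side of the stored sequence where they
appear: the 5′ side for a single-end leading hard clip, the 3′ side
otherwise.

TLEN and PNEXT are passed through unchanged. The paired-end clip rule
exists precisely so mate bookkeeping stays valid; a mate-resolution pass
is out of scope, and mate-end drift caused by 3′ extension is accepted.

## Streaming, sorting, determinism

Processing is single-stream and order-preserving. Output is re-sorted by
coordinate (single-end leading-clip resolution can move positions
leftward) with samtools' stable sort, suppressing its @PG line so repeated
runs are byte-identical; ties keep the deterministic input order. A @PG
entry for this tool (name, version, command line) is appended to the
header chain. Records on contigs present in the BAM header but absent
from the reference FASTA are a hard error before any output is written —
passing such reads through would leak unmatchable donor sequence.

## The synthetic study

The simulator is the package's test bed and stands in for real donor
data. It emulates:

* an i.i.d.-uniform random genome (default: one contig of 100 kb);
* a donor haplotype with 60 SNPs, 20 insertions, and 20 deletions of
  1–10 bp, anchors spaced ≥ 2 read lengths apart so each read meets at
  most one variant, with every ref allele read back from the reference;
* 2,000 reads of 100 bp sampled uniformly: ~20% spliced (one intron of
  60–200 bp with exact known coordinates), ~15% clipped (soft or hard,
  5–15 bp, random adapter-like bases), 1% unmapped, 2% duplicated as
  secondary alignments, paired by default with mates ~200–500 bp apart;
* aligner-faithful records: CIGARs carry the exact I/D/N/S/H implied by
  the variants and shapes, and MD/NM are computed against the reference
  (verified record-for-record against `samtools calmd` in the suite).

Aligner end behavior is mimicked at the 3′ end: an indel whose breakpoint
falls within 5 bp of the read's 3′ end is reported as a soft clip of
donor sequence instead of an indel operator; read starts are resampled so
no indel breakpoint sits in the first 5 bp. Secondary alignments are
same-locus flagged copies of their primary — this exercises multimapping
flag handling fully while keeping the raw-fixture pileup audit an exact
function of the planted truth (a random genome has no true repeats to
host a faithful distant multimapper).

What the simulator does **not** model: sequencing errors, quality
calibration, PCR duplicates, barcode structure, soft-masked or ambiguous
reference bases, translocations, or multi-intron reads. Passing tests
therefore demonstrate the correctness of the rewrite arithmetic and the
absoluteness of allele removal on clean alignments; they do not measure
robustness to pathologically malformed third-party BAMs.

## The auditor

The residual-variation audit is an independent check, not a restatement:
per-column coordinates come from pysam's own CIGAR walk
(`get_aligned_pairs`), with no code shared with the rewrite engine. Every
covered position accumulates A/C/G/T/N counts from M-type columns;
deletions count as evidence across their deleted reference span,
insertions at the anchor base before the insert; soft clips and N gaps
contribute nothing. Any position where any non-reference allele has read
support ≥ 1 is residual — no quality or depth threshold, because the
claim being checked is absolute absence, not statistical depletion. The
layout arithmetic itself is additionally checked against a brute-force
per-base CIGAR walker on 10,000 randomized programs per run.

## Numerical and design choices

* Coordinates are 0-based half-open internally; 1-based only in report
  TSVs (audit) and at SAM-text boundaries. The truth TSV keeps 0-based
  positions, labelled `pos0`.
* IUPAC ambiguity codes and N in the reference are copied into reads
  verbatim: they come from the assembly, not the donor.
* Combined leading clips (`3H5S92M`) resolve as a single unit.
* MD/NM are never added to records that lacked them.
* The problem sizes above (100 kb / 100 variants / 2,000 reads; twenty
  30 kb fixtures for the multi-seed suites) were chosen as the smallest
  study at which every read shape and rule fires many times per run.

## Known limitations

* Keeping secondary/supplementary alignments (`--keep-secondary`) cannot
  fully protect against genotype inference from the multimapping
  structure itself.
* Unmapped mates kept with `--keep-unmapped` retain donor sequence; the
  default discards them.
* Mate TLEN/PNEXT drift after clip resolution is not repaired (by
  design, see above).
* CRAM and SAM-text output, region-restricted processing, and an
  allow-list of permitted variant positions are not implemented.
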