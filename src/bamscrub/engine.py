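"""Core read-rewriting engine: turn an aligned record into reference sequence.

Every mapped read is rewritten so its stored sequence is exactly the
reference genome at its aligned location. This removes all donor genotype
information (SNPs, insertions, deletions, and variant sequence hidden in
soft/hard-clipped read ends) while preserving what downstream tools rely on:
5' mapping positions, splice-junction coordinates, read length, and all
non-alignment metadata.

The transformation is a pure geometry problem. A read's CIGAR is resolved
into an ordered set of reference *match blocks* separated by splice gaps
(:class:`ResolvedLayout`); the output sequence is the concatenated reference
over those blocks and the output CIGAR contains only M and N operators.

Resolution rules, applied jointly:

* M/=/X segments map query to reference 1:1 and become match blocks.
* An insertion (I) deletes its query bases; the read is re-extended by the
  same length at the 3' end so length is conserved and the 5' position
  stays put.
* A deletion (D) materializes the missing reference span inside the block;
  the same number of bases is trimmed back off the 3' end.
* N gaps (introns) split blocks and their reference coordinates are kept.
* A leading soft/hard clip of length k is resolved by shifting the mapping
  position k bases left on single-end data; on paired-end data the position
  must not move (it would corrupt TLEN/PNEXT), so the k bases are appended
  at the 3' end instead. Trailing clips always extend the 3' end.
* Hard-clipped bases are re-materialized from the reference, so the output
  length equals input stored length plus input hard-clip length.
* A 3' trim that consumes the whole terminal exon removes that splice
  junction and continues into the previous block.

The 3' end is always the rightmost *reference* coordinate, regardless of
the strand flag: shifting at the reversed read's 5' would move mapping
positions this tool promises to keep intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pysam

from .reference import GenomeReference
from .tags import apply_tag_policy

CIGAR_CODES = "MIDNSHP=X"
_CODE_OF = {op: i for i, op in enumerate(CIGAR_CODES)}
_QUERY_OPS = frozenset("MIS=X")
_ALIGN_OPS = frozenset("M=X")
_CLIP_OPS = frozenset("SH")

CigarOps = list[tuple[str, int]]


class MalformedCigarError(ValueError):
    """CIGAR violates structural rules (clips inside the alignment, etc.)."""


class DegenerateReadError(Exception):
    """The resolved read would have no aligned bases left."""


class LayoutOutOfRangeError(Exception):
    """The resolved layout extends before position 0 or past the contig end."""


class ReferenceMismatchError(Exception):
    """A record maps to a contig that the supplied reference does not contain."""


@dataclass(frozen=True)
class SanitizeOptions:
    """Behavioral switches for the sanitizer.

    strict
        Additionally neutralize alignment-score-like tags and mapping
        quality (see :mod:`bamscrub.tags`).
    keep_secondary
        Emit secondary and supplementary alignments instead of discarding
        them. Keeping them weakens the privacy guarantee for multimapping
        loci.
    keep_unmapped
        Pass unmapped records through. They cannot be reverted to reference
        sequence (there is no aligned location), so by default they are
        discarded.
    hard_clip_quality_fill
        Quality character assigned to bases re-materialized from hard
        clips; defaults to ``#`` (Phred 2), low enough to advertise the
        synthetic origin without breaking parsers.
    """

    strict: bool = False
    keep_secondary: bool = False
    keep_unmapped: bool = False
    hard_clip_quality_fill: str = "#"


@dataclass(frozen=True)
class ResolvedLayout:
    """Post-sanitization geometry of one read.

    ``blocks`` are (ref_start, length) reference-match blocks, strictly
    increasing and non-overlapping; consecutive blocks imply an N gap of
    ``next.ref_start - (prev.ref_start + prev.length)``. ``fill_front`` /
    ``fill_back`` count quality placeholders needed for bases materialized
    from hard clips at each end of the stored sequence.
    """

    new_pos: int
    blocks: tuple[tuple[int, int], ...]
    total_query_len: int
    removed_splice: bool
    hard_clip_added: int
    fill_front: int
    fill_back: int

    @property
    def end(self) -> int:
        start, length = self.blocks[-1]
        return start + length


@dataclass(frozen=True)
class Discard:
    """Outcome for a record that is dropped rather than rewritten."""

    reason: str  # unmapped | secondary | supplementary | out_of_range | degenerate


def parse_cigar(text: str) -> CigarOps:
    """Parse a CIGAR string like ``"5S95M"`` into [(op, length), ...]."""
    ops: CigarOps = []
    num = ""
    for ch in text:
        if ch.isdigit():
            num += ch
        elif ch in _CODE_OF:
            if not num:
                raise MalformedCigarError(f"missing length before {ch!r} in {text!r}")
            ops.append((ch, int(num)))
            num = ""
        else:
            raise MalformedCigarError(f"bad CIGAR character {ch!r} in {text!r}")
    if num:
        raise MalformedCigarError(f"trailing digits in {text!r}")
    return ops


def cigar_to_string(ops: CigarOps) -> str:
    return "".join(f"{length}{op}" for op, length in ops)


def _split_clips(ops: CigarOps) -> tuple[CigarOps, CigarOps, CigarOps]:
    """Split into (leading clips, core, trailing clips), validating placement."""
    i = 0
    while i < len(ops) and ops[i][0] in _CLIP_OPS:
        i += 1
    j = len(ops)
    while j > i and ops[j - 1][0] in _CLIP_OPS:
        j -= 1
    leading, core, trailing = ops[:i], ops[i:j], ops[j:]
    if any(op in _CLIP_OPS for op, _ in core):
        raise MalformedCigarError("clip operator inside the aligned portion")
    # H may only sit at the extreme ends (outside any S)
    for k, (op, _) in enumerate(leading):
        if op == "H" and k != 0:
            raise MalformedCigarError("H clip not at the extreme read end")
    for k, (op, _) in enumerate(trailing):
        if op == "H" and k != len(trailing) - 1:
            raise MalformedCigarError("H clip not at the extreme read end")
    return leading, core, trailing


def resolve_layout(cigar: CigarOps, pos: int, paired: bool) -> ResolvedLayout:
    """Resolve a CIGAR at ``pos`` into reference-match blocks.

    ``paired`` selects the leading-clip rule: single-end reads shift their
    start left, paired reads keep the start and grow at the 3' end.

    Raises :class:`DegenerateReadError` if the net 3' trim consumes the
    whole read, and :class:`LayoutOutOfRangeError` if the layout would
    start before position 0 (the caller checks the contig end, which this
    function does not know).
    """
    ops = [(op, length) for op, length in cigar if op != "P"]
    for op, length in ops:
        if op not in _CODE_OF:
            raise MalformedCigarError(f"unknown CIGAR op {op!r}")
        if length <= 0:
            raise MalformedCigarError(f"non-positive length for {op}")
    leading, core, trailing = _split_clips(ops)
    if not any(op in _ALIGN_OPS for op, _ in core):
        raise DegenerateReadError("no aligned bases in CIGAR")

    query_len = sum(length for op, length in ops if op in _QUERY_OPS)
    hard_len = sum(length for op, length in ops if op == "H")

    blocks: list[list[int]] = []  # [ref_start, length]
    cur_start = pos
    cur_len = 0
    ref = pos
    extend = 0
    trim = 0
    for op, length in core:
        if op in _ALIGN_OPS:
            cur_len += length
            ref += length
        elif op == "I":
            extend += length
        elif op == "D":
            cur_len += length
            ref += length
            trim += length
        elif op == "N":
            if cur_len > 0:
                blocks.append([cur_start, cur_len])
            ref += length
            cur_start = ref
            cur_len = 0
    if cur_len > 0:
        blocks.append([cur_start, cur_len])

    lead_len = sum(length for _, length in leading)
    lead_hard = sum(length for op, length in leading if op == "H")
    trail_len = sum(length for _, length in trailing)
    trail_hard = sum(length for op, length in trailing if op == "H")

    fill_front = 0
    fill_back = trail_hard
    if lead_len:
        if paired:
            extend += lead_len
            fill_back += lead_hard
        else:
            blocks[0][0] -= lead_len
            blocks[0][1] += lead_len
            fill_front = lead_hard
    extend += trail_len

    removed_splice = False
    net = extend - trim
    if net > 0:
        blocks[-1][1] += net
    elif net < 0:
        remaining = -net
        while remaining > 0:
            if remaining < blocks[-1][1]:
                blocks[-1][1] -= remaining
                remaining = 0
            else:
                remaining -= blocks[-1][1]
                blocks.pop()
                if blocks:
                    removed_splice = True
                else:
                    raise DegenerateReadError("3' trim consumed the whole read")

    new_pos = blocks[0][0]
    if new_pos < 0:
        raise LayoutOutOfRangeError("layout starts before position 0")
    total = sum(length for _, length in blocks)
    if total != query_len + hard_len:
        raise AssertionError(
            f"length conservation violated: {total} != {query_len}+{hard_len}"
        )
    return ResolvedLayout(
        new_pos=new_pos,
        blocks=tuple((s, l) for s, l in blocks),
        total_query_len=total,
        removed_splice=removed_splice,
        hard_clip_added=hard_len,
        fill_front=fill_front,
        fill_back=fill_back,
    )


def rebuild_sequence(layout: ResolvedLayout, ref: GenomeReference, contig: str) -> str:
    """Concatenated reference sequence over the layout's match blocks."""
    if layout.new_pos < 0 or layout.end > ref.contig_length(contig):
        raise LayoutOutOfRangeError(
            f"layout {contig}:{layout.new_pos}-{layout.end} outside contig"
        )
    return "".join(ref.fetch(contig, s, s + l) for s, l in layout.blocks)


def build_cigar(layout: ResolvedLayout) -> CigarOps:
    """M/N-only CIGAR for the layout: M per block, N per inter-block gap."""
    ops: CigarOps = []
    prev_end: Optional[int] = None
    for start, length in layout.blocks:
        if prev_end is not None:
            ops.append(("N", start - prev_end))
        ops.append(("M", length))
        prev_end = start + length
    return ops


def build_md(layout: ResolvedLayout) -> str:
    """MD tag for an error-free alignment: the total matched length.

    N gaps do not appear in MD, so a spliced 50M200N50M read yields "100".
    """
    return str(layout.total_query_len)


def rebuild_quals(
    quals: Optional[Sequence[int]],
    layout: ResolvedLayout,
    options: SanitizeOptions,
) -> Optional[list[int]]:
    """Carry base qualities through unchanged, padding for hard-clip fills.

    Indel resolution deliberately leaves qualities out of phase with the
    rewritten bases — editing them would itself leak where variation was
    removed. Bases materialized from hard clips get the fill quality.
    An unavailable quality string stays unavailable.
    """
    if quals is None:
        return None
    fill = ord(options.hard_clip_quality_fill) - 33
    if not 0 <= fill <= 93:
        raise ValueError("hard-clip quality fill must be a printable Phred+33 char")
    return [fill] * layout.fill_front + list(quals) + [fill] * layout.fill_back


def sanitize_record(
    record: pysam.AlignedSegment,
    ref: GenomeReference,
    options: SanitizeOptions = SanitizeOptions(),
) -> pysam.AlignedSegment | Discard:
    """Rewrite one record in place to pure reference sequence.

    Returns the (mutated) record on success or a :class:`Discard` naming
    the reason. A record mapped to a contig absent from the reference is a
    hard :class:`ReferenceMismatchError`: silently passing such reads
    through would leak unmatchable donor sequence.
    """
    if record.is_unmapped:
        if options.keep_unmapped:
            apply_tag_policy(record, options.strict, record.query_length or 0)
            return record
        return Discard("unmapped")
    if record.is_secondary and not options.keep_secondary:
        return Discard("secondary")
    if record.is_supplementary and not options.keep_secondary:
        return Discard("supplementary")

    contig = record.reference_name
    if contig is None or not ref.has_contig(contig):
        raise ReferenceMismatchError(
            f"record {record.query_name!r} maps to contig {contig!r} "
            "which is absent from the reference FASTA"
        )

    cigar = [(CIGAR_CODES[code], length) for code, length in record.cigartuples]
    try:
        layout = resolve_layout(cigar, record.reference_start, record.is_paired)
    except DegenerateReadError:
        return Discard("degenerate")
    except LayoutOutOfRangeError:
        return Discard("out_of_range")
    if layout.end > ref.contig_length(contig):
        return Discard("out_of_range")

    seq = rebuild_sequence(layout, ref, contig)
    new_quals = rebuild_quals(record.query_qualities, layout, options)
    had_md = record.has_tag("MD")

    record.reference_start = layout.new_pos
    record.query_sequence = seq  # resets stored qualities
    record.query_qualities = new_quals
    record.cigartuples = [(_CODE_OF[op], length) for op, length in build_cigar(layout)]
    if had_md:
        record.set_tag("MD", build_md(layout), "Z")
    apply_tag_policy(record, options.strict, len(seq))
    return record
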