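"""Independent residual-variation auditor.

Tabulates, for every covered reference position, the read bases observed in
M-type alignment columns plus insertion and deletion evidence, and reports
every position where any non-reference allele has read support. On a
correctly sanitized BAM the report is empty — the claim is absolute absence
of donor alleles, so no base-quality or depth threshold is applied.

Deliberately shares no rewrite code with :mod:`bamscrub.engine`: column
coordinates come from pysam's own CIGAR walk (``get_aligned_pairs``), so
this module is a genuine cross-check, not a restatement of the sanitizer.

Evidence conventions: a deletion counts as non-reference evidence at every
position of its deleted reference span; an insertion is anchored at the
reference base immediately before the inserted sequence. Soft-clipped bases
and N gaps contribute nothing.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pysam

from .reference import GenomeReference

_OP_ALIGN = {0, 7, 8}  # M, =, X
_OP_INS = 1
_OP_DEL = 2

DEL_KEY = "del"
INS_KEY = "ins"


@dataclass
class PileupTable:
    """Per-position allele counts plus per-read alt-carrier tallies."""

    counts: dict[tuple[str, int], Counter] = field(default_factory=dict)
    reads_total: int = 0
    reads_with_alt: int = 0

    def add(self, contig: str, pos: int, key: str, n: int = 1) -> None:
        site = self.counts.setdefault((contig, pos), Counter())
        site[key] += n

    @property
    def positions_checked(self) -> int:
        return len(self.counts)


@dataclass
class ResidualReport:
    """Outcome of an audit run.

    ``residual_positions`` holds (contig, pos, ref_base, allele, count)
    for every site with non-reference read support; empty if and only if
    every audited base agrees with the reference.
    """

    positions_checked: int
    residual_positions: list[tuple[str, int, str, str, int]]
    reads_with_alt: int
    reads_total: int

    @property
    def alt_read_fraction(self) -> float:
        if self.reads_total == 0:
            return 0.0
        return self.reads_with_alt / self.reads_total

    @property
    def residual_position_count(self) -> int:
        return len({(c, p) for c, p, _, _, _ in self.residual_positions})

    def write_tsv(self, path: str | os.PathLike) -> None:
        """Report with 1-based positions, one row per residual allele."""
        with open(path, "w") as handle:
            handle.write("contig\tpos\tref\tallele\tcount\n")
            for contig, pos, ref_base, allele, count in self.residual_positions:
                handle.write(f"{contig}\t{pos + 1}\t{ref_base}\t{allele}\t{count}\n")


def pileup_counts(bam: str | os.PathLike, ref: GenomeReference) -> PileupTable:
    """Tally per-position base/indel counts over all mapped records.

    Unmapped records carry no alignment columns and contribute nothing;
    ``reads_total`` counts the mapped records actually audited.
    """
    table = PileupTable()
    with pysam.AlignmentFile(os.fspath(bam), "rb") as handle:
        for record in handle.fetch(until_eof=True):
            if record.is_unmapped:
                continue
            contig = record.reference_name
            if not ref.has_contig(contig):
                raise ValueError(f"BAM contig {contig!r} absent from reference")
            table.reads_total += 1
            seq = record.query_sequence or ""
            carries_alt = False
            last_ref: Optional[int] = None
            ins_run = 0
            for qpos, rpos, op in record.get_aligned_pairs(with_cigar=True):
                if op in _OP_ALIGN and qpos is not None and rpos is not None:
                    if ins_run and last_ref is not None:
                        table.add(contig, last_ref, INS_KEY, ins_run)
                        carries_alt = True
                    ins_run = 0
                    base = seq[qpos].upper()
                    table.add(contig, rpos, base)
                    if base != ref.fetch(contig, rpos, rpos + 1):
                        carries_alt = True
                    last_ref = rpos
                elif op == _OP_DEL and rpos is not None:
                    table.add(contig, rpos, DEL_KEY)
                    carries_alt = True
                    last_ref = rpos
                elif op == _OP_INS:
                    ins_run += 1
            if ins_run and last_ref is not None:
                table.add(contig, last_ref, INS_KEY, ins_run)
                carries_alt = True
            if carries_alt:
                table.reads_with_alt += 1
    return table


def residual_variant_positions(
    table: PileupTable, ref: GenomeReference
) -> ResidualReport:
    """Extract every position where a non-reference allele has support."""
    residual: list[tuple[str, int, str, str, int]] = []
    for (contig, pos), site in sorted(table.counts.items()):
        ref_base = ref.fetch(contig, pos, pos + 1)
        for allele, count in sorted(site.items()):
            if count > 0 and allele != ref_base:
                residual.append((contig, pos, ref_base, allele, count))
    return ResidualReport(
        positions_checked=table.positions_checked,
        residual_positions=residual,
        reads_with_alt=table.reads_with_alt,
        reads_total=table.reads_total,
    )


def audit_bam(bam: str | os.PathLike, ref: GenomeReference) -> ResidualReport:
    """Pileup + residual extraction in one call."""
    return residual_variant_positions(pileup_counts(bam, ref), ref)


def verify_sequence_identity(
    record: pysam.AlignedSegment, ref: GenomeReference
) -> bool:
    """True iff the record's sequence equals the reference over its M blocks.

    A record whose CIGAR contains anything beyond M/=/X and N is by
    definition not sanitized and returns False.
    """
    if record.is_unmapped or record.cigartuples is None:
        return False
    if any(code not in (0, 3, 7) for code, _ in record.cigartuples):
        return False
    seq = record.query_sequence
    if seq is None:
        return False
    contig = record.reference_name
    qpos = 0
    rpos = record.reference_start
    for code, length in record.cigartuples:
        if code == 3:
            rpos += length
            continue
        if seq[qpos : qpos + length].upper() != ref.fetch(contig, rpos, rpos + length):
            return False
        qpos += length
        rpos += length
    return qpos == len(seq)


def structural_errors(bam: str | os.PathLike) -> list[str]:
    """Record-level SAM-structure check of a (sorted) BAM file.

    Verifies that every record parses, that stored sequence/quality/CIGAR
    lengths are mutually consistent, that flag combinations are legal, that
    MD (when present) is a pure match count and NM/nM are zero, and that
    records appear in coordinate order. Returns a list of human-readable
    problems; an empty list means the file is structurally clean.
    """
    problems: list[str] = []
    last_key: Optional[tuple[int, int]] = None
    with pysam.AlignmentFile(os.fspath(bam), "rb") as handle:
        sort_order = handle.header.to_dict().get("HD", {}).get("SO")
        for i, rec in enumerate(handle.fetch(until_eof=True)):
            where = f"record {i} ({rec.query_name})"
            seq = rec.query_sequence
            quals = rec.query_qualities
            if seq is not None and quals is not None and len(seq) != len(quals):
                problems.append(f"{where}: SEQ/QUAL length mismatch")
            if not rec.is_unmapped:
                if rec.cigartuples is None:
                    problems.append(f"{where}: mapped record without CIGAR")
                else:
                    qlen = sum(
                        l for code, l in rec.cigartuples if code in (0, 1, 4, 7, 8)
                    )
                    if seq is not None and qlen != len(seq):
                        problems.append(f"{where}: CIGAR query length != SEQ length")
                if rec.reference_start < 0:
                    problems.append(f"{where}: mapped record with negative POS")
                key = (rec.reference_id, rec.reference_start)
                if sort_order == "coordinate" and last_key is not None:
                    if key < last_key:
                        problems.append(f"{where}: breaks coordinate sort order")
                last_key = key
            if rec.is_secondary and rec.is_supplementary:
                problems.append(f"{where}: both secondary and supplementary")
            if rec.has_tag("MD") and not str(rec.get_tag("MD")).isdigit():
                problems.append(f"{where}: MD tag is not a pure match count")
            for tag in ("NM", "nM"):
                if rec.has_tag(tag) and rec.get_tag(tag) != 0:
                    problems.append(f"{where}: nonzero {tag} after sanitization")
    return problems
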