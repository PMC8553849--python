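"""Streaming BAM driver: read, sanitize record-by-record, write sorted output.

Single-stream and order-preserving so runs are byte-for-byte reproducible;
multithreading, when requested, is confined to BGZF (de)compression in the
final sort. Output is re-sorted by coordinate because resolving a leading
clip on single-end data can shift a mapping position leftward past its
neighbors.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Optional

import pysam

from . import __version__
from .engine import (
    Discard,
    ReferenceMismatchError,
    SanitizeOptions,
    sanitize_record,
)
from .reference import GenomeReference, load_reference

_PG_ID = "bamscrub"
_REFSKIP = 3  # BAM numeric code for the N operator


@dataclass
class SummaryStats:
    """Per-run accounting; records_in == records_out + sum of discards."""

    records_in: int = 0
    records_out: int = 0
    discarded_by_reason: dict[str, int] = field(default_factory=dict)
    splices_removed: int = 0
    positions_shifted: int = 0

    def discard(self, reason: str) -> None:
        self.discarded_by_reason[reason] = self.discarded_by_reason.get(reason, 0) + 1

    def as_tsv(self) -> str:
        lines = [
            f"records_in\t{self.records_in}",
            f"records_out\t{self.records_out}",
        ]
        for reason in sorted(self.discarded_by_reason):
            lines.append(f"discarded.{reason}\t{self.discarded_by_reason[reason]}")
        lines.append(f"splices_removed\t{self.splices_removed}")
        lines.append(f"positions_shifted\t{self.positions_shifted}")
        return "\n".join(lines)


def build_output_header(header: pysam.AlignmentHeader, invocation: str) -> dict:
    """Copy the input header, appending a @PG line for this run.

    @SQ lines are preserved verbatim. If a @PG chain exists, the new entry's
    PP points at the previous tail. A header with no @SQ lines is an error:
    no mapped record can exist against an empty reference set.
    """
    head = header.to_dict()
    if not head.get("SQ"):
        raise ValueError("BAM header has no @SQ lines; nothing can be sanitized")
    pg_chain = list(head.get("PG", []))
    existing_ids = {pg.get("ID") for pg in pg_chain}
    pg_id = _PG_ID
    suffix = 0
    while pg_id in existing_ids:
        suffix += 1
        pg_id = f"{_PG_ID}.{suffix}"
    entry = {"ID": pg_id, "PN": "bamscrub", "VN": __version__, "CL": invocation}
    if pg_chain:
        # tail of the chain = a PG no other PG points to via PP
        pointed_to = {pg.get("PP") for pg in pg_chain if pg.get("PP")}
        tails = [pg["ID"] for pg in pg_chain if pg.get("ID") not in pointed_to]
        entry["PP"] = tails[-1] if tails else pg_chain[-1].get("ID")
    pg_chain.append(entry)
    head["PG"] = pg_chain
    return head


def stream_sanitize(
    in_bam: str | os.PathLike,
    reference: str | os.PathLike | GenomeReference,
    out_bam: str | os.PathLike,
    options: Optional[SanitizeOptions] = None,
    threads: int = 1,
    sort: bool = True,
    invocation: Optional[str] = None,
) -> SummaryStats:
    """Sanitize every record of ``in_bam`` against ``reference``.

    The BAM header's contigs must be a subset of the reference's contigs —
    all of them, not only main chromosomes — checked up front so a
    mismatched reference fails before any output is written. The output is
    coordinate-sorted (unless ``sort=False``) and indexed.
    """
    options = options or SanitizeOptions()
    in_bam = os.fspath(in_bam)
    out_bam = os.fspath(out_bam)
    owns_ref = not isinstance(reference, GenomeReference)
    ref = load_reference(reference) if owns_ref else reference

    stats = SummaryStats()
    try:
        with pysam.AlignmentFile(in_bam, "rb", check_sq=False) as bam_in:
            missing = [
                name for name in bam_in.references if not ref.has_contig(name)
            ]
            if missing:
                raise ReferenceMismatchError(
                    "BAM header contigs absent from the reference FASTA: "
                    + ", ".join(missing)
                )
            head = build_output_header(
                bam_in.header, invocation or f"bamscrub sanitize {in_bam}"
            )
            if sort:
                head.setdefault("HD", {"VN": "1.6"})
            fd, tmp_path = tempfile.mkstemp(
                suffix=".unsorted.bam", dir=os.path.dirname(out_bam) or "."
            )
            os.close(fd)
            try:
                with pysam.AlignmentFile(tmp_path, "wb", header=head) as bam_out:
                    for record in bam_in.fetch(until_eof=True):
                        stats.records_in += 1
                        pos_before = record.reference_start
                        gaps_before = _n_gap_count(record)
                        result = sanitize_record(record, ref, options)
                        if isinstance(result, Discard):
                            stats.discard(result.reason)
                            continue
                        stats.records_out += 1
                        if not result.is_unmapped:
                            if result.reference_start != pos_before:
                                stats.positions_shifted += 1
                            gaps_after = _n_gap_count(result)
                            if gaps_after < gaps_before:
                                stats.splices_removed += gaps_before - gaps_after
                        bam_out.write(result)
                if sort:
                    pysam.sort(
                        "--no-PG", "-@", str(max(0, threads - 1)),
                        "-o", out_bam, tmp_path,
                    )
                    pysam.index(out_bam)
                else:
                    os.replace(tmp_path, out_bam)
            finally:
                if os.path.exists(tmp_path):
                    os.remove(tmp_path)
    finally:
        if owns_ref:
            ref.close()
    return stats


def _n_gap_count(record: pysam.AlignedSegment) -> int:
    if record.cigartuples is None:
        return 0
    return sum(1 for code, _ in record.cigartuples if code == _REFSKIP)
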