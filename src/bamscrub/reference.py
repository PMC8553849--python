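"""Indexed, uppercase access to a reference genome assembly.

All coordinates in this package are 0-based half-open; conversion to the
1-based convention of SAM text happens only at I/O boundaries. The reference
is the single source of every base written into a sanitized read, so fetches
are strict: out-of-bounds requests raise instead of silently clamping.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pyfaidx import Fasta, FastaIndexingError


class ReferenceStoreError(Exception):
    """Raised for unreadable, malformed, or inconsistent reference input."""


@dataclass
class GenomeReference:
    """Contig-addressable view of a FASTA assembly.

    Bases are served uppercased, so soft-masked (lowercase) reference
    regions are indistinguishable from unmasked ones in the output.
    IUPAC ambiguity codes present in the assembly (including N) are
    served verbatim: they originate from the assembly, not the donor.
    """

    contigs: list[tuple[str, int]]
    _fasta: Fasta
    _lengths: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._lengths = dict(self.contigs)

    @property
    def contig_names(self) -> list[str]:
        return [name for name, _ in self.contigs]

    def has_contig(self, contig: str) -> bool:
        return contig in self._lengths

    def contig_length(self, contig: str) -> int:
        try:
            return self._lengths[contig]
        except KeyError:
            raise ReferenceStoreError(f"unknown contig: {contig!r}") from None

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return reference sequence for [start, end) on ``contig``.

        Strict bounds: 0 <= start <= end <= contig length, else
        :class:`ReferenceStoreError`. ``fetch(c, s, s)`` is the empty string.
        """
        length = self.contig_length(contig)
        if not (0 <= start <= end <= length):
            raise ReferenceStoreError(
                f"region {contig}:{start}-{end} outside contig bounds [0, {length})"
            )
        if start == end:
            return ""
        return str(self._fasta[contig][start:end])

    def close(self) -> None:
        self._fasta.close()

    def __enter__(self) -> "GenomeReference":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def load_reference(path: str | os.PathLike) -> GenomeReference:
    """Open a FASTA assembly, building the .fai index sidecar if absent.

    Raises :class:`ReferenceStoreError` on a missing file, a malformed
    record, or duplicate contig names.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ReferenceStoreError(f"reference FASTA not found: {path}")
    try:
        fasta = Fasta(path, sequence_always_upper=True, as_raw=True)
    except (FastaIndexingError, ValueError) as exc:
        raise ReferenceStoreError(f"could not index {path}: {exc}") from exc
    names = list(fasta.keys())
    if len(set(names)) != len(names):
        raise ReferenceStoreError(f"duplicate contig names in {path}")
    contigs = [(name, len(fasta[name])) for name in names]
    return GenomeReference(contigs=contigs, _fasta=fasta)


def write_fasta(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    path: str | os.PathLike,
    line_width: int = 60,
) -> None:
    """Write (name, sequence) records to ``path`` with wrapped lines."""
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    with open(path, "w") as handle:
        for name, seq in items:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                handle.write(seq[i : i + line_width] + "\n")
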