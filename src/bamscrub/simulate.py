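"""Synthetic fixtures: reference, donor haplotype, and aligner-faithful reads.

Generates everything needed to exercise and audit the sanitizer without any
external dataset: an i.i.d.-uniform random genome, a donor haplotype with
planted SNPs and short indels at known positions, and BAM records whose
CIGAR/MD/NM are exactly what an aligner would report for a read sampled
from that donor — including spliced reads (known intron coordinates),
soft/hard-clipped reads, proper pairs, unmapped reads, and secondary
alignments.

Reads are sampled along the donor and expressed in reference coordinates.
Mimicking aligner behavior at read ends, an indel whose breakpoint falls
within 5 bp of the read's 3' end is reported as a soft clip of donor
sequence rather than an indel operator; read starts are shifted so no
indel breakpoint falls inside the first 5 bp. Variant anchors are spaced
at least two read lengths apart so each read meets at most one variant.

Everything is reproducible: the same :class:`SimParams` (including seed)
yields byte-identical FASTA, BAM, and truth TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .reference import GenomeReference, load_reference, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_END_GUARD = 5  # bp: indel breakpoints closer than this to a read end clip instead


@dataclass(frozen=True)
class SimParams:
    """Shape of a synthetic study.

    Defaults model a desk-scale version of a short-read experiment: one
    100 kb contig, 100 planted variants (60 SNPs, 20 insertions, 20
    deletions of 1-10 bp), and 2,000 paired 100 bp reads of which ~20%
    are spliced, ~15% clipped, 1% unmapped and 2% duplicated as secondary
    alignments.
    """

    seed: int = 0
    n_contigs: int = 1
    contig_len: int = 100_000
    n_snps: int = 60
    n_insertions: int = 20
    n_deletions: int = 20
    indel_len: tuple[int, int] = (1, 10)
    read_len: int = 100
    n_reads: int = 2_000
    paired: bool = True
    fraction_spliced: float = 0.2
    fraction_clipped: float = 0.15
    clip_len: tuple[int, int] = (5, 15)
    intron_len: tuple[int, int] = (60, 200)
    fraction_unmapped: float = 0.01
    fraction_secondary: float = 0.02

    def validate(self) -> None:
        if self.n_contigs < 1 or self.contig_len < 1:
            raise ValueError("need at least one contig of positive length")
        if self.read_len < 20:
            raise ValueError("read_len too short to carry the simulated shapes")
        for frac in (
            self.fraction_spliced,
            self.fraction_clipped,
            self.fraction_unmapped,
            self.fraction_secondary,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_snps, self.n_insertions, self.n_deletions, self.n_reads) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant in VCF-like normalized form (0-based anchor).

    For indels the anchor is the shared reference base before the event:
    an insertion adds ``alt_allele[1:]`` after ``pos``; a deletion removes
    ``ref_allele[1:]`` (reference positions pos+1 .. pos+len-1).
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    kind: str  # SNP | insertion | deletion

    def footprint(self) -> set[int]:
        """Reference positions where a read carrying this variant leaves
        non-reference pileup evidence."""
        if self.kind == "SNP":
            return {self.pos}
        if self.kind == "insertion":
            return {self.pos}  # anchored at the base before the insert
        return set(range(self.pos + 1, self.pos + len(self.ref_allele)))


@dataclass
class Fixture:
    """Paths and in-memory objects for one generated dataset."""

    params: SimParams
    fasta: Path
    bam: Path
    truth_tsv: Path
    truth: list[TruthVariant]
    donor: dict[str, str]
    reference: GenomeReference = field(repr=False)


def generate_reference(
    params: SimParams, fasta_path: str | os.PathLike
) -> GenomeReference:
    """Write a seeded random FASTA and load it back as a GenomeReference."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    records = []
    for i in range(params.n_contigs):
        seq = rng.choice(_BASES, size=params.contig_len)
        records.append((f"chr{i + 1}", seq.tobytes().decode()))
    write_fasta(records, fasta_path)
    return load_reference(fasta_path)


def plant_variants(
    ref: GenomeReference, params: SimParams
) -> tuple[dict[str, str], list[TruthVariant]]:
    """Place SNPs and indels on the reference; return donor haplotype + truth.

    Anchors are kept at least ``2 * read_len`` apart (plus indel slack) so
    no read spans two variants; the density is validated and an infeasible
    request raises ValueError. Every ref_allele is read back from the
    reference, so the truth table is self-verifying.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    n_total = params.n_snps + params.n_insertions + params.n_deletions
    kinds = (
        ["SNP"] * params.n_snps
        + ["insertion"] * params.n_insertions
        + ["deletion"] * params.n_deletions
    )
    rng.shuffle(kinds)

    # grid step leaves >= 2*read_len between anchors even after jitter
    jitter = params.read_len // 2
    spacing = 2 * params.read_len + params.indel_len[1] + 10 + jitter
    margin = 3 * params.read_len
    truth: list[TruthVariant] = []
    donor: dict[str, str] = {}

    # spread variants over contigs as evenly as possible
    per_contig = [n_total // params.n_contigs] * params.n_contigs
    for i in range(n_total % params.n_contigs):
        per_contig[i] += 1
    kind_iter = iter(kinds)

    for (contig, length), n_here in zip(ref.contigs, per_contig):
        grid = np.arange(margin, length - margin, spacing)
        if len(grid) < n_here:
            raise ValueError(
                f"variant density infeasible on {contig}: "
                f"{n_here} variants need {n_here * spacing} bp, have {length}"
            )
        anchors = np.sort(rng.choice(grid, size=n_here, replace=False))
        contig_seq = ref.fetch(contig, 0, length)
        for anchor in anchors:
            anchor = int(anchor) + int(rng.integers(0, jitter)) if jitter else int(anchor)
            kind = next(kind_iter)
            ref_base = contig_seq[anchor]
            if kind == "SNP":
                alt = str(
                    rng.choice([b for b in "ACGT" if b != ref_base])
                )
                truth.append(TruthVariant(contig, anchor, ref_base, alt, "SNP"))
            elif kind == "insertion":
                ins_len = int(rng.integers(params.indel_len[0], params.indel_len[1] + 1))
                ins = "".join(rng.choice(list("ACGT"), size=ins_len))
                truth.append(
                    TruthVariant(contig, anchor, ref_base, ref_base + ins, "insertion")
                )
            else:
                del_len = int(rng.integers(params.indel_len[0], params.indel_len[1] + 1))
                removed = contig_seq[anchor : anchor + 1 + del_len]
                truth.append(
                    TruthVariant(contig, anchor, removed, ref_base, "deletion")
                )
        # donor sequence: apply this contig's variants right-to-left
        donor_seq = contig_seq
        for var in sorted(
            (v for v in truth if v.contig == contig), key=lambda v: -v.pos
        ):
            if var.kind == "SNP":
                donor_seq = (
                    donor_seq[: var.pos] + var.alt_allele + donor_seq[var.pos + 1 :]
                )
            elif var.kind == "insertion":
                donor_seq = (
                    donor_seq[: var.pos + 1]
                    + var.alt_allele[1:]
                    + donor_seq[var.pos + 1 :]
                )
            else:
                donor_seq = (
                    donor_seq[: var.pos + 1]
                    + donor_seq[var.pos + len(var.ref_allele) :]
                )
        donor[contig] = donor_seq
    return donor, truth


def _build_core(
    contig_seq: str,
    start: int,
    n_query: int,
    var_at: dict[int, TruthVariant],
    intron: Optional[tuple[int, int]],
) -> tuple[str, list[tuple[str, int]]]:
    """Walk the reference from ``start`` emitting ``n_query`` donor bases.

    Returns (sequence, cigar ops). Ops may end in a soft clip when an
    indel breakpoint falls within the 3' end guard; the clipped bases are
    donor sequence, exactly what an aligner would leave unaligned.
    """
    seq: list[str] = []
    ops: list[tuple[str, int]] = []

    def emit(op: str, length: int) -> None:
        if length <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + length)
        else:
            ops.append((op, length))

    qpos = 0
    rpos = start
    intron_start, intron_len = intron if intron else (-1, 0)
    intron_pending = intron is not None
    while qpos < n_query:
        if intron_pending and rpos >= intron_start:
            emit("N", intron_len)
            rpos += intron_len
            intron_pending = False
            continue
        var = var_at.get(rpos)
        if var is None:
            seq.append(contig_seq[rpos])
            emit("M", 1)
            qpos += 1
            rpos += 1
        elif var.kind == "SNP":
            seq.append(var.alt_allele)
            emit("M", 1)
            qpos += 1
            rpos += 1
        elif var.kind == "insertion":
            seq.append(contig_seq[rpos])  # shared anchor base
            emit("M", 1)
            qpos += 1
            rpos += 1
            ins = var.alt_allele[1:]
            remaining = n_query - qpos
            if remaining <= 0:
                break
            if remaining < len(ins) + _END_GUARD:
                # breakpoint too close to the 3' end: aligner soft-clips
                tail = (ins + contig_seq[rpos:])[:remaining]
                seq.append(tail)
                emit("S", len(tail))
                qpos = n_query
            else:
                seq.append(ins)
                emit("I", len(ins))
                qpos += len(ins)
        else:  # deletion
            seq.append(contig_seq[rpos])
            emit("M", 1)
            qpos += 1
            rpos += 1
            del_len = len(var.ref_allele) - 1
            remaining = n_query - qpos
            if remaining <= 0:
                break
            if remaining < _END_GUARD:
                tail = contig_seq[rpos + del_len : rpos + del_len + remaining]
                seq.append(tail)
                emit("S", len(tail))
                qpos = n_query
            else:
                emit("D", del_len)
                rpos += del_len
    return "".join(seq), ops


def compute_md_nm(
    seq: str, cigar: list[tuple[str, int]], contig_seq: str, pos: int
) -> tuple[str, int]:
    """MD tag and NM edit distance for an alignment against the reference.

    Standard MD grammar: match counts, mismatched reference bases, and
    ``^``-prefixed deleted reference runs (a 0 separates adjacent events).
    NM counts mismatches plus inserted plus deleted bases; clipped bases
    do not contribute.
    """
    md: list[str] = []
    run = 0
    nm = 0
    qpos = 0
    rpos = pos
    for op, length in cigar:
        if op in "M=X":
            for _ in range(length):
                if seq[qpos] == contig_seq[rpos]:
                    run += 1
                else:
                    md.append(str(run))
                    md.append(contig_seq[rpos])
                    run = 0
                    nm += 1
                qpos += 1
                rpos += 1
        elif op == "I":
            nm += length
            qpos += length
        elif op == "D":
            md.append(str(run))
            md.append("^" + contig_seq[rpos : rpos + length])
            run = 0
            nm += length
            rpos += length
        elif op == "N":
            rpos += length
        elif op == "S":
            qpos += length
        # H, P: nothing stored, nothing consumed here
    md.append(str(run))
    return "".join(md), nm


def simulate_alignments(
    ref: GenomeReference,
    donor: dict[str, str],
    truth: list[TruthVariant],
    params: SimParams,
    bam_path: str | os.PathLike,
    truth_tsv: Optional[str | os.PathLike] = None,
) -> list[pysam.AlignedSegment]:
    """Simulate reads from the donor and write a sorted, indexed BAM.

    Mapped records carry the exact CIGAR an aligner would assign given the
    planted variants plus the requested splice/clip shapes, and MD/NM
    computed against the reference. Secondary records are flagged copies
    of their primary alignment; unmapped records carry random sequence and
    no coordinates.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": length} for name, length in ref.contigs],
        }
    )
    tid_of = {name: i for i, (name, _) in enumerate(ref.contigs)}
    contig_seqs = {name: ref.fetch(name, 0, length) for name, length in ref.contigs}
    var_index: dict[str, dict[int, TruthVariant]] = {name: {} for name, _ in ref.contigs}
    for var in truth:
        var_index[var.contig][var.pos] = var

    records: list[pysam.AlignedSegment] = []
    read_idx = 0
    while len(records) < params.n_reads:
        name = f"read{read_idx:06d}"
        if rng.random() < params.fraction_unmapped:
            records.append(_make_unmapped(name, params, rng, header))
            read_idx += 1
            continue
        contig = ref.contig_names[int(rng.integers(0, params.n_contigs))]
        made = _make_mapped(
            name, contig, contig_seqs[contig], var_index[contig],
            params, rng, header, tid_of[contig],
        )
        if made is None:
            continue  # infeasible placement; resample under the same name
        read_idx += 1
        records.extend(made)
        if rng.random() < params.fraction_secondary:
            records.append(_as_secondary(made[0], header))

    records = records[: params.n_reads]
    records.sort(
        key=lambda r: (
            r.reference_id if r.reference_id >= 0 else 1 << 30,
            r.reference_start if r.reference_start >= 0 else 1 << 30,
            r.query_name,
            r.flag,
        )
    )
    bam_path = os.fspath(bam_path)
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(bam_path)

    if truth_tsv is not None:
        with open(truth_tsv, "w") as handle:
            handle.write("contig\tpos0\tref\talt\tkind\n")
            for var in sorted(truth, key=lambda v: (v.contig, v.pos)):
                handle.write(
                    f"{var.contig}\t{var.pos}\t{var.ref_allele}\t"
                    f"{var.alt_allele}\t{var.kind}\n"
                )
    return records


def _random_quals(rng: np.random.Generator, n: int) -> list[int]:
    return [int(q) for q in rng.integers(30, 41, size=n)]


def _make_unmapped(
    name: str, params: SimParams, rng: np.random.Generator,
    header: pysam.AlignmentHeader,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = 4
    rec.reference_id = -1
    rec.reference_start = -1
    rec.mapping_quality = 0
    rec.query_sequence = "".join(
        rng.choice(list("ACGT"), size=params.read_len)
    )
    rec.query_qualities = _random_quals(rng, params.read_len)
    return rec


def _indel_near(
    var_at: dict[int, TruthVariant], lo: int, hi: int, reach: int = 12
) -> bool:
    """True if an indel anchor sits in [lo - reach, hi).

    Used to keep read starts and intron boundaries clear of indel events
    (``reach`` covers the longest deletion span plus its anchor base).
    """
    for p in range(lo - reach, hi):
        var = var_at.get(p)
        if var is not None and var.kind != "SNP":
            return True
    return False


def _make_mapped(
    name: str,
    contig: str,
    contig_seq: str,
    var_at: dict[int, TruthVariant],
    params: SimParams,
    rng: np.random.Generator,
    header: pysam.AlignmentHeader,
    tid: int,
) -> Optional[list[pysam.AlignedSegment]]:
    """Build one mapped read (or a proper pair). Returns None to resample."""
    span_budget = params.read_len + params.intron_len[1] + 500
    max_start = len(contig_seq) - span_budget - params.read_len
    if max_start <= params.read_len:
        raise ValueError("contig too short for the requested read shapes")
    start = int(rng.integers(params.read_len, max_start))
    if _indel_near(var_at, start, start + _END_GUARD):
        return None

    spliced = rng.random() < params.fraction_spliced
    intron = None
    if spliced:
        q_break = int(rng.integers(20, params.read_len - 20))
        intron_len = int(rng.integers(params.intron_len[0], params.intron_len[1] + 1))
        intron_pos = start + q_break
        if _indel_near(var_at, intron_pos, intron_pos + _END_GUARD):
            return None
        intron = (intron_pos, intron_len)

    clip_op = None
    clip_len = 0
    clip_side = None
    if rng.random() < params.fraction_clipped:
        clip_op = "S" if rng.random() < 0.75 else "H"
        clip_len = int(rng.integers(params.clip_len[0], params.clip_len[1] + 1))
        clip_side = "left" if rng.random() < 0.5 else "right"

    aligned_query = params.read_len - (clip_len if clip_op else 0)
    seq, core_ops = _build_core(contig_seq, start, aligned_query, var_at, intron)
    if len(seq) != aligned_query:
        return None  # walked off some edge; resample

    cigar = list(core_ops)
    if clip_op:
        clip_seq = "".join(rng.choice(list("ACGT"), size=clip_len))
        if clip_side == "left":
            cigar = [(clip_op, clip_len)] + cigar
            if clip_op == "S":
                seq = clip_seq + seq
        else:
            # avoid S-after-S merges with a core that already soft-clipped
            if cigar[-1][0] == "S":
                cigar[-1] = ("S", cigar[-1][1] + clip_len) if clip_op == "S" else cigar[-1]
                if clip_op == "H":
                    cigar = cigar + [("H", clip_len)]
            else:
                cigar = cigar + [(clip_op, clip_len)]
            if clip_op == "S":
                seq = seq + clip_seq

    md, nm = compute_md_nm(seq, cigar, contig_seq, start)
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.reference_id = tid
    rec.reference_start = start
    rec.mapping_quality = 60
    rec.cigartuples = [("MIDNSHP=X".index(op), l) for op, l in cigar]
    rec.query_sequence = seq
    rec.query_qualities = _random_quals(rng, len(seq))
    rec.set_tag("NM", nm, "i")
    rec.set_tag("MD", md, "Z")
    rec.set_tag("nM", nm, "i")

    if not params.paired:
        rec.flag = 16 if rng.random() < 0.5 else 0
        return [rec]

    # proper pair: mate 2 downstream on the reverse strand, no splice
    frag = int(rng.integers(2 * params.read_len, 2 * params.read_len + 300))
    mate_start = start + frag - params.read_len
    if _indel_near(var_at, mate_start, mate_start + _END_GUARD):
        return None
    mseq, mops = _build_core(contig_seq, mate_start, params.read_len, var_at, None)
    if len(mseq) != params.read_len:
        return None
    mate = pysam.AlignedSegment(header)
    mate.query_name = name
    mate.reference_id = tid
    mate.reference_start = mate_start
    mate.mapping_quality = 60
    mate.cigartuples = [("MIDNSHP=X".index(op), l) for op, l in mops]
    mate.query_sequence = mseq
    mate.query_qualities = _random_quals(rng, len(mseq))
    mmd, mnm = compute_md_nm(mseq, mops, contig_seq, mate_start)
    mate.set_tag("NM", mnm, "i")
    mate.set_tag("MD", mmd, "Z")
    mate.set_tag("nM", mnm, "i")

    rec.flag = 1 | 2 | 32 | 64
    mate.flag = 1 | 2 | 16 | 128
    rec.next_reference_id = tid
    mate.next_reference_id = tid
    rec.next_reference_start = mate_start
    mate.next_reference_start = start
    tlen = (mate.reference_end or mate_start) - start
    rec.template_length = tlen
    mate.template_length = -tlen
    return [rec, mate]


def _as_secondary(
    primary: pysam.AlignedSegment, header: pysam.AlignmentHeader
) -> pysam.AlignedSegment:
    """Secondary alignment: same locus and sequence, flagged and demoted."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = primary.query_name
    rec.flag = primary.flag | 256
    rec.reference_id = primary.reference_id
    rec.reference_start = primary.reference_start
    rec.mapping_quality = 0
    rec.cigartuples = primary.cigartuples
    rec.query_sequence = primary.query_sequence
    rec.query_qualities = primary.query_qualities
    for tag in ("NM", "MD", "nM"):
        if primary.has_tag(tag):
            value = primary.get_tag(tag)
            rec.set_tag(tag, value, "Z" if tag == "MD" else "i")
    if primary.is_paired:
        rec.next_reference_id = primary.next_reference_id
        rec.next_reference_start = primary.next_reference_start
        rec.template_length = primary.template_length
    return rec


def make_fixture(params: SimParams, out_dir: str | os.PathLike) -> Fixture:
    """Generate reference + variants + BAM + truth TSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "reference.fa"
    bam = out_dir / "reads.bam"
    tsv = out_dir / "truth.tsv"
    ref = generate_reference(params, fasta)
    donor, truth = plant_variants(ref, params)
    simulate_alignments(ref, donor, truth, params, bam, tsv)
    (out_dir / "params.txt").write_text(repr(params) + "\n")
    return Fixture(
        params=params, fasta=fasta, bam=bam, truth_tsv=tsv,
        truth=truth, donor=donor, reference=ref,
    )
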