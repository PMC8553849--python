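"""Shared fixtures: small synthetic datasets and record builders."""

from __future__ import annotations

import dataclasses

import pysam
import pytest

from bamscrub.simulate import SimParams, make_fixture


SMALL_PARAMS = SimParams(
    seed=0,
    contig_len=30_000,
    n_snps=18,
    n_insertions=6,
    n_deletions=6,
    n_reads=400,
)


@pytest.fixture(scope="session")
def fixture_factory(tmp_path_factory):
    """Build (and cache per seed) a small synthetic dataset."""
    cache = {}

    def build(seed: int, **overrides):
        key = (seed, tuple(sorted(overrides.items())))
        if key not in cache:
            params = dataclasses.replace(SMALL_PARAMS, seed=seed, **overrides)
            out = tmp_path_factory.mktemp(f"fix_s{seed}")
            cache[key] = make_fixture(params, out)
        return cache[key]

    return build


@pytest.fixture(scope="session")
def small_fixture(fixture_factory):
    return fixture_factory(0)


TOY_LEN = 5_000


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    """A single 5 kb contig named chrT with a seeded random sequence."""
    import numpy as np

    from bamscrub.reference import load_reference, write_fasta

    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=TOY_LEN))
    path = tmp_path_factory.mktemp("toyref") / "toy.fa"
    write_fasta({"chrT": seq}, path)
    return load_reference(path)


@pytest.fixture()
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrT", "LN": TOY_LEN}]}
    )


def make_record(
    header: pysam.AlignmentHeader,
    *,
    name: str = "r1",
    flag: int = 0,
    pos: int = 1000,
    cigar: str | None = "100M",
    seq: str | None = None,
    quals: list[int] | None = None,
    mapq: int = 60,
    tags: dict | None = None,
) -> pysam.AlignedSegment:
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    if flag & 4:
        rec.reference_id = -1
        rec.reference_start = -1
    else:
        rec.reference_id = 0
        rec.reference_start = pos
        rec.cigarstring = cigar
    rec.mapping_quality = mapq
    if seq is not None:
        rec.query_sequence = seq
        rec.query_qualities = quals if quals is not None else [30] * len(seq)
    for tag, value in (tags or {}).items():
        rec.set_tag(tag, value)
    return rec
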