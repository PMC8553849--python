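"""Layout resolution: worked cases, degenerate inputs, and oracle equivalence."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from bamscrub.engine import (
    DegenerateReadError,
    LayoutOutOfRangeError,
    MalformedCigarError,
    build_cigar,
    build_md,
    cigar_to_string,
    parse_cigar,
    resolve_layout,
)
from naive_oracle import (
    OracleDegenerate,
    OracleOutOfRange,
    naive_layout,
    random_cigar,
)


# The seven canonical rewrite shapes: plain match, insertion, deletion,
# leading clip on single-end vs paired data, spliced read with insertion,
# and a deletion long enough to erase the last exon's splice junction.
WORKED_CASES = [
    ("100M", 1000, False, 1000, [(1000, 100)], False),
    ("50M2I48M", 1000, False, 1000, [(1000, 100)], False),
    ("50M2D50M", 1000, False, 1000, [(1000, 100)], False),
    ("5S95M", 1000, False, 995, [(995, 100)], False),
    ("5S95M", 1000, True, 1000, [(1000, 100)], False),
    ("30M1I20M200N49M", 1000, True, 1000, [(1000, 50), (1250, 50)], False),
    ("50M5D43M100N2M", 1000, True, 1000, [(1000, 95)], True),
]


@pytest.mark.parametrize("cigar,pos,paired,new_pos,blocks,removed", WORKED_CASES)
def test_worked_rewrite_cases(cigar, pos, paired, new_pos, blocks, removed):
    layout = resolve_layout(parse_cigar(cigar), pos, paired)
    assert layout.new_pos == new_pos
    assert list(layout.blocks) == blocks
    assert layout.removed_splice is removed


@pytest.mark.parametrize(
    "cigar,pos,paired",
    [
        ("3H5S92M", 1000, False),  # combined S+H leading clip acts as one unit
        ("3H5S92M", 1000, True),
        ("92M5S3H", 1000, False),
        ("10M30N10M80S", 500, True),
        ("20M5I30M100N45M", 2000, False),
        ("1M", 0, False),
    ],
)
def test_mixed_clip_cases_match_oracle(cigar, pos, paired):
    layout = resolve_layout(parse_cigar(cigar), pos, paired)
    new_pos, blocks = naive_layout(parse_cigar(cigar), pos, paired)
    assert layout.new_pos == new_pos
    assert list(layout.blocks) == blocks


def test_length_conservation_includes_hard_clips():
    layout = resolve_layout(parse_cigar("3H5S92M"), 1000, False)
    assert layout.total_query_len == 100
    assert layout.hard_clip_added == 3
    assert layout.fill_front == 3  # single-end leading clip materializes at 5'
    layout_pe = resolve_layout(parse_cigar("3H5S92M"), 1000, True)
    assert layout_pe.fill_front == 0 and layout_pe.fill_back == 3


def test_huge_deletion_shrinks_read_but_keeps_aligned_bases():
    # the deleted reference span joins the block before the 3' trim removes
    # it again, so a trim can never consume the query bases themselves
    layout = resolve_layout(parse_cigar("2M200D2M"), 1000, False)
    assert list(layout.blocks) == [(1000, 4)]
    assert layout.total_query_len == 4


def test_all_clip_cigar_is_degenerate():
    with pytest.raises(DegenerateReadError):
        resolve_layout(parse_cigar("100S"), 1000, False)


def test_leading_clip_before_contig_start_is_out_of_range():
    with pytest.raises(LayoutOutOfRangeError):
        resolve_layout(parse_cigar("10S90M"), 5, False)


def test_clip_inside_alignment_is_malformed():
    with pytest.raises(MalformedCigarError):
        resolve_layout(parse_cigar("10M5S10M"), 100, False)


def test_padding_is_dropped_and_equals_treated_as_match():
    layout = resolve_layout(parse_cigar("50=1P2X48M"), 1000, False)
    assert list(layout.blocks) == [(1000, 100)]


def test_cigar_serialization_alternates_match_and_skip():
    layout = resolve_layout(parse_cigar("50M200N50M"), 1000, True)
    assert cigar_to_string(build_cigar(layout)) == "50M200N50M"
    assert build_md(layout) == "100"


def test_randomized_cigars_match_per_base_oracle():
    """Engine block arithmetic equals the naive per-base walk on 10^4
    random CIGAR programs, including exception outcomes."""
    rng = random.Random(20240915)
    checked = 0
    outcomes = {"ok": 0, "degenerate": 0, "out_of_range": 0}
    while checked < 10_000:
        cigar, pos, paired = random_cigar(rng)
        checked += 1
        try:
            expected = naive_layout(list(cigar), pos, paired)
        except OracleDegenerate:
            expected = "degenerate"
        except OracleOutOfRange:
            expected = "out_of_range"
        try:
            layout = resolve_layout(list(cigar), pos, paired)
            got = (layout.new_pos, list(layout.blocks))
        except DegenerateReadError:
            got = "degenerate"
        except LayoutOutOfRangeError:
            got = "out_of_range"
        if isinstance(expected, tuple):
            exp_pos, exp_blocks = expected
            assert got == (exp_pos, exp_blocks), (cigar, pos, paired)
            outcomes["ok"] += 1
        else:
            assert got == expected, (cigar, pos, paired)
            outcomes[expected] += 1
    assert outcomes["ok"] > 9_000  # exceptions should be the rare path


@st.composite
def cigar_programs(draw):
    ops = []
    if draw(st.booleans()):
        ops.append(("H", draw(st.integers(1, 8))))
    if draw(st.booleans()):
        ops.append(("S", draw(st.integers(1, 12))))
    n = draw(st.integers(1, 4))
    for k in range(n):
        ops.append(("M", draw(st.integers(1, 25))))
        if k < n - 1:
            ops.append(
                (
                    draw(st.sampled_from("IDN")),
                    draw(st.integers(1, 15)),
                )
            )
    if draw(st.booleans()):
        ops.append(("S", draw(st.integers(1, 12))))
    return ops


@given(cigar=cigar_programs(), pos=st.integers(50, 5000), paired=st.booleans())
@settings(max_examples=300, derandomize=True)
def test_layout_invariants_hold_for_arbitrary_programs(cigar, pos, paired):
    """Blocks strictly increase, length is conserved, and the first block
    starts at the resolved position."""
    try:
        layout = resolve_layout(list(cigar), pos, paired)
    except (DegenerateReadError, LayoutOutOfRangeError):
        return
    assert layout.blocks[0][0] == layout.new_pos
    for (s1, l1), (s2, _) in zip(layout.blocks, layout.blocks[1:]):
        assert s1 + l1 < s2  # strictly increasing with positive gap
    query = sum(l for op, l in cigar if op in "MIS=X")
    hard = sum(l for op, l in cigar if op == "H")
    assert layout.total_query_len == query + hard
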