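"""Record-level sanitization: sequence replacement, discards, qualities."""

import pytest

from bamscrub.engine import (
    Discard,
    ReferenceMismatchError,
    SanitizeOptions,
    parse_cigar,
    rebuild_quals,
    rebuild_sequence,
    resolve_layout,
    sanitize_record,
)
from conftest import make_record


def _ref_seq(ref, pos, length):
    return ref.fetch("chrT", pos, pos + length)


def test_snp_read_rewritten_to_reference(toy_ref, header):
    ref100 = _ref_seq(toy_ref, 1000, 100)
    mutated = ref100[:37] + ("A" if ref100[37] != "A" else "C") + ref100[38:]
    rec = make_record(
        header, pos=1000, cigar="100M", seq=mutated,
        tags={"MD": f"37{ref100[37]}62", "NM": 1},
    )
    out = sanitize_record(rec, toy_ref)
    assert out.query_sequence == ref100
    assert out.cigarstring == "100M"
    assert out.reference_start == 1000
    assert out.get_tag("MD") == "100"
    assert out.get_tag("NM") == 0


def test_insertion_read_extended_at_three_prime(toy_ref, header):
    # 50M2I48M: 98 ref bases covered in input, 100 after resolution
    seq = _ref_seq(toy_ref, 1000, 50) + "NN" + _ref_seq(toy_ref, 1050, 48)
    rec = make_record(header, pos=1000, cigar="50M2I48M", seq=seq)
    out = sanitize_record(rec, toy_ref)
    assert out.query_sequence == _ref_seq(toy_ref, 1000, 100)
    assert out.cigarstring == "100M"
    assert out.reference_start == 1000


def test_paired_leading_softclip_keeps_position(toy_ref, header):
    seq = "TTTTT" + _ref_seq(toy_ref, 1000, 95)
    rec = make_record(header, flag=1 | 2 | 64, pos=1000, cigar="5S95M", seq=seq)
    out = sanitize_record(rec, toy_ref)
    assert out.reference_start == 1000
    assert out.query_sequence == _ref_seq(toy_ref, 1000, 100)


def test_single_end_leading_softclip_shifts_position(toy_ref, header):
    seq = "TTTTT" + _ref_seq(toy_ref, 1000, 95)
    rec = make_record(header, pos=1000, cigar="5S95M", seq=seq)
    out = sanitize_record(rec, toy_ref)
    assert out.reference_start == 995
    assert out.query_sequence == _ref_seq(toy_ref, 995, 100)


def test_hard_clip_materialized_with_fill_quality(toy_ref, header):
    seq = _ref_seq(toy_ref, 1000, 95)
    rec = make_record(header, pos=1000, cigar="5H95M", seq=seq, quals=[40] * 95)
    out = sanitize_record(rec, toy_ref)
    assert len(out.query_sequence) == 100
    assert out.query_sequence == _ref_seq(toy_ref, 995, 100)
    assert list(out.query_qualities) == [2] * 5 + [40] * 95


def test_unmapped_discarded_by_default(toy_ref, header):
    rec = make_record(header, flag=4, seq="A" * 50)
    assert sanitize_record(rec, toy_ref) == Discard("unmapped")


def test_unmapped_kept_on_request(toy_ref, header):
    rec = make_record(header, flag=4, seq="A" * 50, tags={"NM": 3})
    out = sanitize_record(rec, toy_ref, SanitizeOptions(keep_unmapped=True))
    assert out.is_unmapped
    assert out.get_tag("NM") == 0


@pytest.mark.parametrize(
    "flag,reason", [(256, "secondary"), (2048, "supplementary")]
)
def test_non_primary_discarded_by_default(toy_ref, header, flag, reason):
    rec = make_record(header, flag=flag, pos=1000, cigar="50M",
                      seq="A" * 50)
    assert sanitize_record(rec, toy_ref) == Discard(reason)
    out = sanitize_record(
        make_record(header, flag=flag, pos=1000, cigar="50M", seq="A" * 50),
        toy_ref,
        SanitizeOptions(keep_secondary=True),
    )
    assert out.query_sequence == _ref_seq(toy_ref, 1000, 50)


def test_read_past_contig_end_discarded(toy_ref, header):
    rec = make_record(header, pos=4950, cigar="100M", seq="A" * 100)
    assert sanitize_record(rec, toy_ref) == Discard("out_of_range")


def test_leading_clip_before_origin_discarded(toy_ref, header):
    # single-end leading-clip shift would move the start before position 0
    rec = make_record(header, pos=3, cigar="10S90M", seq="A" * 100)
    assert sanitize_record(rec, toy_ref) == Discard("out_of_range")


def test_unknown_contig_is_hard_error(toy_ref):
    import pysam

    other = pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": "chrZ", "LN": 1000}]}
    )
    rec = make_record(other, pos=10, cigar="50M", seq="A" * 50)
    with pytest.raises(ReferenceMismatchError):
        sanitize_record(rec, toy_ref)


def test_sanitize_is_idempotent_per_record(toy_ref, header):
    seq = "GGGGG" + _ref_seq(toy_ref, 1000, 90) + "TTTTT"
    rec = make_record(header, pos=1000, cigar="5S90M5S", seq=seq,
                      tags={"MD": "90", "NM": 0})
    once = sanitize_record(rec, toy_ref)
    snapshot = once.to_string()
    twice = sanitize_record(once, toy_ref)
    assert twice.to_string() == snapshot


def test_md_only_written_when_input_had_md(toy_ref, header):
    rec = make_record(header, pos=1000, cigar="50M", seq="A" * 50)
    out = sanitize_record(rec, toy_ref)
    assert not out.has_tag("MD")
    assert not out.has_tag("NM")


def test_unavailable_qualities_stay_unavailable(toy_ref, header):
    rec = make_record(header, pos=1000, cigar="50M", seq="A" * 50)
    rec.query_qualities = None
    out = sanitize_record(rec, toy_ref)
    assert out.query_qualities is None


def test_rebuild_quals_passthrough_and_fill():
    layout = resolve_layout(parse_cigar("3H97M"), 1000, False)
    quals = [30 + (i % 10) for i in range(97)]
    out = rebuild_quals(quals, layout, SanitizeOptions())
    assert out == [2, 2, 2] + quals
    assert rebuild_quals(None, layout, SanitizeOptions()) is None


def test_rebuild_sequence_is_block_concatenation(toy_ref):
    layout = resolve_layout(parse_cigar("3M7N2M"), 0, True)
    assert rebuild_sequence(layout, toy_ref, "chrT") == (
        toy_ref.fetch("chrT", 0, 3) + toy_ref.fetch("chrT", 10, 12)
    )
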