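"""Auxiliary-field sanitization policy.

After the sequence itself is reverted to reference, alignment-derived
fields can still reveal that variation was removed: a nonzero edit
distance, a mate-CIGAR, or aligner-specific mismatch counters. The default
policy zeroes edit distances and drops alignment-description tags; strict
mode additionally neutralizes score/quality/multimapping signals. Every
other tag — cell barcodes, UMIs, gene assignments, read groups, custom
flags — is preserved byte-identically.
"""

from __future__ import annotations

import pysam

# Edit distance to the reference (aligner-dependent spelling): forced to 0.
ZERO_TAGS = ("NM", "nM")

# Tags describing the (now rewritten) alignment: dropped in all modes.
DROP_TAGS = ("MC", "XN", "XM", "XO", "XG")

# Extra signal carriers dropped only under --strict.
STRICT_DROP_TAGS = (
    "HI", "IH", "H1", "H2", "OA", "OC", "OP", "OQ", "SA", "SM", "XA", "XS",
)

# Under --strict, rewritten (only when already present; adding a tag the
# input lacked would itself be a detectable scar).
STRICT_READLEN_TAGS = ("AS", "MQ")


def apply_tag_policy(
    record: pysam.AlignedSegment, strict: bool, final_read_len: int
) -> pysam.AlignedSegment:
    """Apply the tag policy in place and return the record.

    Idempotent: applying twice equals applying once. ``final_read_len`` is
    the length of the sanitized stored sequence, used for AS/MQ in strict
    mode.
    """
    for tag in ZERO_TAGS:
        if record.has_tag(tag):
            record.set_tag(tag, 0, "i")
    for tag in DROP_TAGS:
        if record.has_tag(tag):
            record.set_tag(tag, None)
    if strict:
        record.mapping_quality = 255
        for tag in STRICT_READLEN_TAGS:
            if record.has_tag(tag):
                record.set_tag(tag, final_read_len, "i")
        if record.has_tag("NH"):
            record.set_tag("NH", 1, "i")
        for tag in STRICT_DROP_TAGS:
            if record.has_tag(tag):
                record.set_tag(tag, None)
    return record
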