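"""Brute-force per-base layout oracle, independent of the engine.

Walks a CIGAR one base at a time, recording the reference position each
final query base will occupy, then applies the net 3' extension/trim by
literally appending/popping positions and regroups consecutive runs into
blocks. Deliberately naive: no block arithmetic shared with
``bamscrub.engine.resolve_layout``.
"""

from __future__ import annotations


class OracleDegenerate(Exception):
    pass


class OracleOutOfRange(Exception):
    pass


def naive_layout(cigar: list[tuple[str, int]], pos: int, paired: bool):
    """Return (new_pos, blocks) the slow way."""
    ops = [(op, length) for op, length in cigar if op != "P"]
    i = 0
    while i < len(ops) and ops[i][0] in "SH":
        i += 1
    j = len(ops)
    while j > i and ops[j - 1][0] in "SH":
        j -= 1
    leading, core, trailing = ops[:i], ops[i:j], ops[j:]
    if not any(op in "M=X" for op, _ in core):
        raise OracleDegenerate

    positions: list[int] = []
    extend = 0
    trim = 0
    ref = pos
    for op, length in core:
        if op in "M=X":
            positions.extend(range(ref, ref + length))
            ref += length
        elif op == "I":
            extend += length
        elif op == "D":
            positions.extend(range(ref, ref + length))
            ref += length
            trim += length
        elif op == "N":
            ref += length

    lead = sum(length for _, length in leading)
    trail = sum(length for _, length in trailing)
    if lead:
        if paired:
            extend += lead
        else:
            positions = list(range(positions[0] - lead, positions[0])) + positions
    extend += trail

    net = extend - trim
    if net > 0:
        positions.extend(range(positions[-1] + 1, positions[-1] + 1 + net))
    elif net < 0:
        if -net >= len(positions):
            raise OracleDegenerate
        positions = positions[:net]

    if positions[0] < 0:
        raise OracleOutOfRange

    blocks = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
        else:
            blocks.append((start, prev - start + 1))
            start = prev = p
    blocks.append((start, prev - start + 1))
    return positions[0], blocks


def random_cigar(rng) -> tuple[list[tuple[str, int]], int, bool]:
    """Random small CIGAR program with clips, indels, and splices."""
    ops: list[tuple[str, int]] = []
    if rng.random() < 0.25:
        ops.append(("H", rng.randint(1, 10)))
    if rng.random() < 0.35:
        ops.append(("S", rng.randint(1, 15)))
    n_core = rng.randint(1, 6)
    for k in range(n_core):
        ops.append(("M", rng.randint(1, 30)))
        if k < n_core - 1:
            roll = rng.random()
            if roll < 0.3:
                ops.append(("I", rng.randint(1, 12)))
            elif roll < 0.6:
                ops.append(("D", rng.randint(1, 12)))
            elif roll < 0.9:
                ops.append(("N", rng.randint(20, 200)))
            # else: adjacent M runs merge implicitly
    if rng.random() < 0.35:
        ops.append(("S", rng.randint(1, 15)))
    if rng.random() < 0.25:
        ops.append(("H", rng.randint(1, 10)))
    pos = rng.randint(0, 2000)
    paired = rng.random() < 0.5
    return ops, pos, paired
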