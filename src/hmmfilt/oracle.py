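"""Naive sequential DP oracles for the three filter scores.

These are deliberately plain two-loop dynamic programs over the *sequential*
state layout — no striping, no lane shifts, no Lazy-F — operating on the same
quantized integers as the striped engines.  They exist purely as the
equivalence baseline: with ``saturating=True`` every arithmetic step clamps in
exactly the same order as the engine (saturation is not associative, so the
clipping order is part of the contract), and the striped engines must
reproduce their scores bit-exactly.

With ``saturating=False`` the same recurrences run in unbounded integers with
a true −inf floor (quantized sentinels are mapped back to −inf), yielding the
exact optimum over alignment paths on the quantized score system; this mode
backs the structural inequalities (e.g. SSV ≤ MSV) that clipping could mask.
"""

from __future__ import annotations

from hmmfilt.filters import FilterConstants, make_constants
from hmmfilt.model_io import (
    NEG_INF_INT,
    DigitizedSequence,
    QuantizedScores,
    width_bounds,
)

__all__ = ["naive_ssv", "naive_msv", "naive_viterbi", "UNBOUNDED_FLOOR"]

#: −inf stand-in for unsaturated (unbounded-integer) evaluation.
UNBOUNDED_FLOOR = -(2**40)


def _ops(width: str, saturating: bool, floor_value: int):
    """Return (clamp, floor) for the requested arithmetic mode."""
    if saturating:
        lo, hi, _ = width_bounds(width)

        def clamp(v: int) -> int:
            return lo if v < lo else hi if v > hi else v

        return clamp, floor_value
    return (lambda v: v), UNBOUNDED_FLOOR


def _emission(scores: QuantizedScores, k: int, a: int, saturating: bool) -> int:
    """Net emission delta of state k (1-based) for residue code a."""
    v = int(scores.values[k - 1, a])
    if scores.cost_form:
        net = scores.bias - v  # cost byte -> score delta
        if not saturating and v == 255:
            return UNBOUNDED_FLOOR
        return net
    if not saturating and v == scores.sentinel:
        return UNBOUNDED_FLOOR
    return v


def _const(c: FilterConstants, name: str, saturating: bool) -> int:
    v = getattr(c, name)
    if not saturating and v == NEG_INF_INT:
        return UNBOUNDED_FLOOR
    return v


def naive_ssv(
    seq: DigitizedSequence,
    scores: QuantizedScores,
    c: FilterConstants | None = None,
    saturating: bool = True,
) -> int:
    """Single ungapped segment score by the O(L·len) sequential DP.

    8-bit signed scheme: −128 is the −inf floor.  ``M[i][k] = max(M[i-1][k-1],
    entry) + e[k][a_i]`` with constant entry ``tmove + tbm``; the row maximum
    feeds the C accumulator (decay ``tloop`` per row, arrival cost ``tec``)
    and the final score adds the C→T move.
    """
    L = scores.L
    if c is None:
        c = make_constants(L, len(seq), scores.scale)
    clamp, floor = _ops("8s", saturating, width_bounds("8s")[2])
    tloop = _const(c, "tloop", saturating)
    tmove = _const(c, "tmove", saturating)
    tbm = _const(c, "tbm", saturating)
    tec = _const(c, "tec", saturating)

    entry = clamp(clamp(0 + tmove) + tbm)
    m_prev = [floor] * L
    xC = floor
    for a in seq.residues:
        a = int(a)
        m_row = [0] * L
        xE = floor
        for k in range(1, L + 1):
            diag = m_prev[k - 2] if k >= 2 else floor
            sv = clamp(max(diag, entry) + _emission(scores, k, a, saturating))
            m_row[k - 1] = sv
            if sv > xE:
                xE = sv
        m_prev = m_row
        xC = max(clamp(xC + tloop), clamp(xE + tec))
    return clamp(xC + tmove)


def naive_msv(
    seq: DigitizedSequence,
    scores: QuantizedScores,
    c: FilterConstants | None = None,
    saturating: bool = True,
) -> int:
    """Multiple ungapped segment score by the sequential DP.

    8-bit unsigned base-offset scheme (cost-form emissions): a cell is
    ``clamp(clamp(max(diag, xB + tbm) + bias) - cost)``; after each row the J
    and B specials update from the row maximum.  The returned raw score sits
    on the ``base`` offset; 0 is the −inf floor.
    """
    L = scores.L
    if c is None:
        c = make_constants(L, len(seq), scores.scale)
    if not scores.cost_form and saturating:
        raise ValueError("saturating MSV requires cost-form 8u scores")
    clamp, floor = _ops("8u", saturating, 0)
    tloop = _const(c, "tloop", saturating)
    tmove = _const(c, "tmove", saturating)
    tbm = _const(c, "tbm", saturating)
    tec = _const(c, "tec", saturating)

    xJ = floor
    xB = clamp(c.base + tmove)
    m_prev = [floor] * L
    for a in seq.residues:
        a = int(a)
        xBv = clamp(xB + tbm)
        m_row = [0] * L
        xE = floor
        for k in range(1, L + 1):
            diag = m_prev[k - 2] if k >= 2 else floor
            sv = max(diag, xBv)
            if saturating:
                sv = clamp(clamp(sv + scores.bias) - int(scores.values[k - 1, a]))
            else:
                sv = sv + _emission(scores, k, a, saturating)
            m_row[k - 1] = sv
            if sv > xE:
                xE = sv
        m_prev = m_row
        xJ = max(clamp(xJ + tloop), clamp(xE + tec))
        xB = max(clamp(c.base + tmove), clamp(xJ + tmove))
    return clamp(xJ + tmove)


def naive_viterbi(
    seq: DigitizedSequence,
    scores: QuantizedScores,
    c: FilterConstants | None = None,
    saturating: bool = True,
) -> int:
    """Full Plan-7 filter score with the D chain computed strictly
    sequentially in k — the reference the Lazy-F engine must match.

    16-bit signed scheme; insert emissions are 0; E collects from match
    states only (uniform zero-cost exit); specials N/B/E/C/J update once per
    row in the fixed documented order.
    """
    L = scores.L
    if scores.transitions is None:
        raise ValueError("viterbi oracle requires quantized transitions")
    if c is None:
        c = make_constants(L, len(seq), scores.scale)
    clamp, floor = _ops("16s", saturating, width_bounds("16s")[2])
    tloop = _const(c, "tloop", saturating)
    tmove = _const(c, "tmove", saturating)
    tbm = _const(c, "tbm", saturating)
    tec = _const(c, "tec", saturating)

    def tr(key: str, k: int) -> int:
        """Transition out of source state k (1-based)."""
        v = int(scores.transitions[key][k - 1])
        if not saturating and v == NEG_INF_INT:
            return UNBOUNDED_FLOOR
        return v

    xN, xJ, xC = 0, floor, floor
    xB = clamp(xN + tmove)
    m_prev = [floor] * (L + 1)  # 1-based indexing; slot 0 unused
    i_prev = [floor] * (L + 1)
    d_prev = [floor] * (L + 1)
    for a in seq.residues:
        a = int(a)
        entry = clamp(xB + tbm)
        m_row = [floor] * (L + 1)
        i_row = [floor] * (L + 1)
        d_row = [floor] * (L + 1)
        xE = floor
        for k in range(1, L + 1):
            if k >= 2:
                cand = max(
                    clamp(m_prev[k - 1] + tr("MM", k - 1)),
                    clamp(i_prev[k - 1] + tr("IM", k - 1)),
                    clamp(d_prev[k - 1] + tr("DM", k - 1)),
                    entry,
                )
            else:
                cand = entry
            sv = clamp(cand + _emission(scores, k, a, saturating))
            m_row[k] = sv
            if sv > xE:
                xE = sv
            i_row[k] = max(
                clamp(m_prev[k] + tr("MI", k)), clamp(i_prev[k] + tr("II", k))
            )
            if k >= 2:
                d_row[k] = max(
                    clamp(m_row[k - 1] + tr("MD", k - 1)),
                    clamp(d_row[k - 1] + tr("DD", k - 1)),
                )
        m_prev, i_prev, d_prev = m_row, i_row, d_row
        xJ = max(clamp(xJ + tloop), clamp(xE + tec))
        xC = max(clamp(xC + tloop), clamp(xE + tec))
        xN = clamp(xN + tloop)
        xB = max(clamp(xN + tmove), clamp(xJ + tmove))
    return clamp(xC + tmove)
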