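"""The three heuristic filter kernels on the striped lane engine.

``ssv_score``  — best single ungapped diagonal segment (8-bit signed lanes,
                 −128 sentinel, the 0x80 shift-in pattern).
``msv_score``  — best chain of ungapped segments rejoined through the J state
                 (8-bit unsigned lanes with a base offset; emissions are held
                 in biased-cost form, added as ``+bias`` then ``−cost``, so
                 padding with the maximal cost 255 floors cleanly — the
                 vaddus/vsubus instruction pair of the MSV inner loop).
``viterbi_score`` — full Plan-7 optimal-alignment filter (16-bit signed lanes)
                 with the Delete-Delete chain resolved by Lazy-F carry passes.

All three walk the DP matrix row by row (one row per residue); each row is
evaluated in Q lane-wide steps over the striped profile, with one closed-cycle
lane shift per row to satisfy the diagonal dependency.  Scores are integers in
the quantized scheme of the striped profile; ``FilterRecord.real_score``
de-quantizes to bits.

Score semantics follow the three filter models: uniform entry B→Mk with cost
``tbm``, uniform zero-cost exit Mk→E, E→J/C cost ``tec``, J/C/N self-loop
cost ``tloop`` per emitted residue and N→B / J→B / C→T move cost ``tmove``.
``tloop`` and ``tmove`` depend on the target sequence length and are
recomputed per sequence (:func:`make_constants`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from hmmfilt.model_io import (
    DEFAULT_SCALE,
    NEG_INF,
    NEG_INF_INT,
    DigitizedSequence,
    ProfileModel,
    quantize,
    quantize_msv_costs,
    width_bounds,
)
from hmmfilt.lane_engine import reorder_array, sat_add_arrays, sat_sub_arrays
from hmmfilt.striping import LaneGeometry, StripedProfile, stripe

__all__ = [
    "DEFAULT_BASE",
    "FilterConstants",
    "FilterRecord",
    "LazyFError",
    "make_constants",
    "build_filter_profile",
    "ssv_score",
    "msv_score",
    "viterbi_score",
]

#: Default base offset of the 8-bit unsigned (MSV) scoring scheme.
DEFAULT_BASE = 190

_STAGE_WIDTH = {"ssv": "8s", "msv": "8u", "vit": "16s"}
_STAGE_ALPHA = {"ssv": 4, "msv": 4, "vit": 2}


class LazyFError(RuntimeError):
    """Lazy-F failed to reach a fixpoint within the pass cap (internal bug)."""


@dataclass(frozen=True)
class FilterConstants:
    """Quantized special-transition costs shared by engine and oracle.

    All costs are integers at ``scale`` units per bit, ≤ 0 (``NEG_INF_INT``
    for −inf), applied with saturating adds.  ``base`` is the unsigned-byte
    offset of the MSV scheme.  The integer costs are width-independent so the
    SSV and MSV stages of one search share identical constants.
    """

    scale: float
    base: int
    tloop: int
    tmove: int
    tbm: int
    tec: int

    def replace(self, **kw) -> "FilterConstants":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


def _q(bits: float, scale: float) -> int:
    if not math.isfinite(bits):
        return NEG_INF_INT
    return int(np.rint(scale * bits))


def make_constants(
    L: int,
    seq_len: int,
    scale: float = DEFAULT_SCALE,
    base: int = DEFAULT_BASE,
    overrides: dict[str, float] | None = None,
) -> FilterConstants:
    """Special-transition costs for a model of L states vs one target sequence.

    Defaults follow the length-conditioned multihit-local parameterization:
    ``tloop = log2(n/(n+3))`` and ``tmove = log2(3/(n+3))`` for a target of n
    residues, ``tbm = log2(2/(L(L+1)))`` (uniform entry over states and
    segment lengths) and ``tec = log2(1/2)``.  ``overrides`` (in bits) replace
    individual defaults, e.g. from :attr:`ProfileModel.special_params`.
    """
    n = seq_len
    vals = {
        "tloop": math.log2(n / (n + 3.0)) if n > 0 else NEG_INF,
        "tmove": math.log2(3.0 / (n + 3.0)),
        "tbm": math.log2(2.0 / (L * (L + 1.0))),
        "tec": math.log2(0.5),
    }
    if overrides:
        vals.update({k: v for k, v in overrides.items() if v is not None})
    return FilterConstants(
        scale=scale,
        base=base,
        tloop=_q(vals["tloop"], scale),
        tmove=_q(vals["tmove"], scale),
        tbm=_q(vals["tbm"], scale),
        tec=_q(vals["tec"], scale),
    )


@dataclass
class FilterRecord:
    """Per-sequence, per-stage filter output."""

    seq_id: str
    stage: str
    raw_score: int
    real_score: float
    saturated: bool
    passed: bool
    lazy_passes: int | None = None


def build_filter_profile(
    model: ProfileModel,
    stage: str,
    geometry: LaneGeometry | None = None,
    scale: float = DEFAULT_SCALE,
    bias: int | None = None,
    Q: int | None = None,
) -> StripedProfile:
    """Quantize and stripe a profile for one filter stage.

    ``stage`` is ``"ssv"``, ``"msv"`` or ``"vit"``.  The default geometry is a
    32-thread warp with 4 sub-lanes per thread for the 8-bit stages and 2 for
    the 16-bit Viterbi stage.
    """
    if stage not in _STAGE_WIDTH:
        raise ValueError(f"unknown stage {stage!r}")
    if geometry is None:
        geometry = LaneGeometry(s_warp=32, alpha=_STAGE_ALPHA[stage])
    if stage == "msv":
        scores = quantize_msv_costs(model, scale=scale, bias=bias)
    elif stage == "ssv":
        scores = quantize(model, "8s", scale=scale, bias=0)
    else:
        if model.transitions is None:
            raise ValueError("the Viterbi filter requires transition scores")
        scores = quantize(model, "16s", scale=scale, bias=0)
    return stripe(scores, geometry, name=model.name, Q=Q)


def _sclamp(v: int, lo: int, hi: int) -> int:
    return lo if v < lo else hi if v > hi else v


def _record(
    seq: DigitizedSequence,
    stage: str,
    raw: int,
    bits: float,
    saturated: bool,
    threshold: float | None,
    lazy_passes: int | None = None,
) -> FilterRecord:
    # A clipped score is a lower bound, so saturation always promotes.
    passed = bool(saturated or threshold is None or bits >= threshold)
    return FilterRecord(
        seq_id=seq.id,
        stage=stage,
        raw_score=int(raw),
        real_score=bits,
        saturated=bool(saturated),
        passed=passed,
        lazy_passes=lazy_passes,
    )


# ---------------------------------------------------------------------------
# SSV
# ---------------------------------------------------------------------------


def ssv_score(
    seq: DigitizedSequence,
    sp: StripedProfile,
    c: FilterConstants | None = None,
    threshold: float | None = None,
) -> FilterRecord:
    """Best single ungapped diagonal segment, on 8-bit signed striped lanes.

    Entry into any match state carries the constant cost ``tmove + tbm``; the
    row maximum feeds a C-state accumulator that decays by ``tloop`` per
    subsequent residue, and the final score adds the E→C and C→T costs.  There
    is no J state, so no per-row xJ/xB work — the stripped-down inner loop
    that makes SSV the cheapest stage.
    """
    if sp.width != "8s":
        raise ValueError("ssv_score requires an 8s striped profile")
    if c is None:
        c = make_constants(sp.L, len(seq), sp.scale)
    lo, hi, sent = width_bounds("8s")
    Q, lanes = sp.Q, sp.geometry.lanes
    entry = _sclamp(_sclamp(0 + c.tmove, lo, hi) + c.tbm, lo, hi)

    m_prev = [np.full(lanes, sent, dtype=np.int64) for _ in range(Q)]
    xC = sent
    saturated = False
    for a in seq.residues:
        em = sp.emissions[a]
        mpv = reorder_array(m_prev[Q - 1], sent)
        x_ev = np.full(lanes, sent, dtype=np.int64)
        m_new = []
        for q in range(Q):
            sv = np.maximum(mpv, entry)
            sv = sat_add_arrays(sv, em[q], "8s")
            m_new.append(sv)
            x_ev = np.maximum(x_ev, sv)
            mpv = m_prev[q]
        m_prev = m_new
        xE = int(x_ev.max())
        if xE == hi:
            saturated = True
        xC = max(_sclamp(xC + c.tloop, lo, hi), _sclamp(xE + c.tec, lo, hi))
    raw = _sclamp(xC + c.tmove, lo, hi)
    bits = NEG_INF if raw == sent else raw / sp.scale
    return _record(seq, "ssv", raw, bits, saturated, threshold)


# ---------------------------------------------------------------------------
# MSV
# ---------------------------------------------------------------------------


def msv_score(
    seq: DigitizedSequence,
    sp: StripedProfile,
    c: FilterConstants | None = None,
    threshold: float | None = None,
) -> FilterRecord:
    """Multiple ungapped segment score on 8-bit unsigned striped lanes.

    Row recurrence per striped step: ``sv = ((max(diag, xBv) +sat bias) −sat
    cost)``; the row maximum xE feeds the J-state rejoin ``xJ = max(xJ +
    tloop, xE + tec)`` and the next row's begin value ``xB = max(base + tmove,
    xJ + tmove)``.  Scores sit on the ``base`` offset (0 is the −inf floor).
    """
    if sp.width != "8u" or not sp.cost_form:
        raise ValueError("msv_score requires a cost-form 8u striped profile")
    if c is None:
        c = make_constants(sp.L, len(seq), sp.scale)
    lo, hi, _ = width_bounds("8u")
    floor = 0
    Q, lanes = sp.Q, sp.geometry.lanes
    bias = sp.bias

    xJ = floor
    xB = _sclamp(c.base + c.tmove, lo, hi)
    m_prev = [np.full(lanes, floor, dtype=np.int64) for _ in range(Q)]
    saturated = False
    for a in seq.residues:
        cost = sp.emissions[a]
        xBv = _sclamp(xB + c.tbm, lo, hi)
        mpv = reorder_array(m_prev[Q - 1], floor)
        x_ev = np.full(lanes, floor, dtype=np.int64)
        m_new = []
        for q in range(Q):
            sv = np.maximum(mpv, xBv)
            sv = sat_add_arrays(sv, bias, "8u")
            sv = sat_sub_arrays(sv, cost[q], "8u")
            m_new.append(sv)
            x_ev = np.maximum(x_ev, sv)
            mpv = m_prev[q]
        m_prev = m_new
        xE = int(x_ev.max())
        if xE == hi:
            saturated = True
        xJ = max(_sclamp(xJ + c.tloop, lo, hi), _sclamp(xE + c.tec, lo, hi))
        xB = max(_sclamp(c.base + c.tmove, lo, hi), _sclamp(xJ + c.tmove, lo, hi))
    raw = _sclamp(xJ + c.tmove, lo, hi)
    bits = NEG_INF if raw == floor else (raw - c.base) / sp.scale
    return _record(seq, "msv", raw, bits, saturated, threshold)


# ---------------------------------------------------------------------------
# P7Viterbi with Lazy-F
# ---------------------------------------------------------------------------


def viterbi_score(
    seq: DigitizedSequence,
    sp: StripedProfile,
    c: FilterConstants | None = None,
    threshold: float | None = None,
) -> FilterRecord:
    """Full Plan-7 filter score on 16-bit signed striped lanes.

    Match/Insert rows follow the previous-row dependencies directly; the
    within-row Delete chain is evaluated lazily: the main striped pass carries
    a per-lane D carry ``dcv``, the end-of-row carry is shifted across lanes
    once, and further carry-propagation sweeps run only until a sweep changes
    nothing — at which point the row equals the strict sequential D recursion.
    The sweep count is capped at ``lanes + 1``; exceeding the cap indicates an
    internal error, as each sweep extends chain influence by at least one lane.
    """
    if sp.width != "16s" or sp.transitions is None:
        raise ValueError("viterbi_score requires a 16s striped profile with transitions")
    if c is None:
        c = make_constants(sp.L, len(seq), sp.scale)
    lo, hi, sent = width_bounds("16s")
    Q, lanes = sp.Q, sp.geometry.lanes
    tr = sp.transitions
    tmm_in, tim_in, tdm_in = tr["MM_in"], tr["IM_in"], tr["DM_in"]
    tmi, tii, tmd, tdd = tr["MI"], tr["II"], tr["MD"], tr["DD"]

    def sadd(arr, delta):
        return sat_add_arrays(arr, delta, "16s")

    xN, xJ, xC = 0, sent, sent
    xB = _sclamp(xN + c.tmove, lo, hi)
    m_prev = [np.full(lanes, sent, dtype=np.int64) for _ in range(Q)]
    i_prev = [np.full(lanes, sent, dtype=np.int64) for _ in range(Q)]
    d_prev = [np.full(lanes, sent, dtype=np.int64) for _ in range(Q)]
    saturated = False
    max_lazy = 0
    for a in seq.residues:
        em = sp.emissions[a]
        entry = _sclamp(xB + c.tbm, lo, hi)
        mpv = reorder_array(m_prev[Q - 1], sent)
        ipv = reorder_array(i_prev[Q - 1], sent)
        dpv = reorder_array(d_prev[Q - 1], sent)
        dcv = np.full(lanes, sent, dtype=np.int64)
        x_ev = np.full(lanes, sent, dtype=np.int64)
        m_new, i_new, d_new = [], [], []
        for q in range(Q):
            cand = np.maximum(
                np.maximum(sadd(mpv, tmm_in[q]), sadd(ipv, tim_in[q])),
                np.maximum(sadd(dpv, tdm_in[q]), entry),
            )
            sv = sadd(cand, em[q])
            m_new.append(sv)
            x_ev = np.maximum(x_ev, sv)
            d_new.append(dcv)
            dcv = np.maximum(sadd(sv, tmd[q]), sadd(dcv, tdd[q]))
            i_new.append(
                np.maximum(sadd(m_prev[q], tmi[q]), sadd(i_prev[q], tii[q]))
            )
            mpv, ipv, dpv = m_prev[q], i_prev[q], d_prev[q]

        # Lazy-F: push the end-of-row carry across the lane boundary once,
        # then sweep carry propagation until a full sweep changes nothing.
        dcv = reorder_array(dcv, sent)
        d_new[0] = np.maximum(d_new[0], dcv)
        passes = 0
        while True:
            passes += 1
            if passes > lanes + 1:
                raise LazyFError("Lazy-F exceeded its pass cap")
            changed = False
            for q in range(1, Q):
                dcv = sadd(dcv, tdd[q - 1])
                cand = np.maximum(d_new[q], dcv)
                if np.any(cand != d_new[q]):
                    d_new[q] = cand
                    changed = True
            if not changed:
                break
            dcv = sadd(dcv, tdd[Q - 1])
            dcv = reorder_array(dcv, sent)
            cand = np.maximum(d_new[0], dcv)
            if np.any(cand != d_new[0]):
                d_new[0] = cand
        max_lazy = max(max_lazy, passes)

        m_prev, i_prev, d_prev = m_new, i_new, d_new
        xE = int(x_ev.max())
        if xE == hi:
            saturated = True
        xJ = max(_sclamp(xJ + c.tloop, lo, hi), _sclamp(xE + c.tec, lo, hi))
        xC = max(_sclamp(xC + c.tloop, lo, hi), _sclamp(xE + c.tec, lo, hi))
        xN = _sclamp(xN + c.tloop, lo, hi)
        xB = max(_sclamp(xN + c.tmove, lo, hi), _sclamp(xJ + c.tmove, lo, hi))
    raw = _sclamp(xC + c.tmove, lo, hi)
    bits = NEG_INF if raw == sent else raw / sp.scale
    return _record(seq, "vit", raw, bits, saturated, threshold, lazy_passes=max_lazy)
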