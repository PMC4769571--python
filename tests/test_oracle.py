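"""Oracle-of-the-oracle: exhaustive path enumeration on tiny instances.

The naive DP oracles are themselves verified here against brute-force
enumeration of every legal alignment path through the filter models, in
unbounded integer arithmetic on the same quantized scores.  Instances are tiny
(L ≤ 3, len ≤ 4) so full enumeration is feasible.
"""

import numpy as np
import pytest

from hmmfilt.filters import make_constants
from hmmfilt.model_io import NEG_INF_INT, quantize, quantize_msv_costs
from hmmfilt.oracle import UNBOUNDED_FLOOR, naive_msv, naive_ssv, naive_viterbi
from hmmfilt.pipeline import gen_model, gen_sequences

NO_PATH = UNBOUNDED_FLOOR // 2  # anything below this counts as "no path"


def enumerate_ssv(seq, scores, c):
    """Max over all (start row, start state, length) single segments."""
    n, L = len(seq), scores.L
    best = None
    for r in range(1, n + 1):
        for k0 in range(1, L + 1):
            acc = c.tmove + c.tbm
            m = 0
            while r + m <= n and k0 + m <= L:
                acc += int(scores.values[k0 + m - 1, int(seq.residues[r + m - 1])])
                m += 1
                total = acc + c.tec + c.tloop * (n - (r + m - 1)) + c.tmove
                best = total if best is None else max(best, total)
    return best


def enumerate_msv(seq, scores, c):
    """Max over ordered sets of disjoint ungapped segments with J rejoins."""
    n, L = len(seq), scores.L

    def seg_scores(r):
        """All (end_row, score) for segments starting at row r."""
        for k0 in range(1, L + 1):
            acc = 0
            m = 0
            while r + m <= n and k0 + m <= L:
                acc += int(scores.values[k0 + m - 1, int(seq.residues[r + m - 1])])
                m += 1
                yield r + m - 1, c.tbm + acc + c.tec

    best = None

    def extend(r, acc):
        nonlocal best
        for end, sc in seg_scores(r):
            # finish here: C decays over the remaining rows, then C->T
            total = acc + sc + c.tloop * (n - end) + c.tmove
            best = total if best is None else max(best, total)
            # or rejoin through J and start another segment later
            for r2 in range(end + 1, n + 1):
                extend(r2, acc + sc + c.tloop * (r2 - end - 1) + c.tmove)

    for r in range(1, n + 1):
        extend(r, c.base + c.tmove)
    return best


def enumerate_viterbi(seq, scores, c):
    """DFS over every legal Plan-7 path (E collects from M only)."""
    n, L = len(seq), scores.L
    res = seq.residues
    best = None

    def upd(v):
        nonlocal best
        best = v if best is None or v > best else best

    def tr(key, k):
        v = int(scores.transitions[key][k - 1])
        return None if v == NEG_INF_INT else v

    def em(k, i):  # emission of M_k consuming residue index i (0-based)
        v = int(scores.values[k - 1, int(res[i])])
        return None if v == scores.sentinel else v

    def go_M(k, i, acc):
        go_E(i, acc)  # uniform zero-cost exit
        if i < n:
            t = tr("MM", k)
            e = em(k + 1, i) if k < L else None
            if k < L and t is not None and e is not None:
                go_M(k + 1, i + 1, acc + t + e)
            t = tr("MI", k)
            if t is not None:
                go_I(k, i + 1, acc + t)  # insert emission fixed at 0
        t = tr("MD", k)
        if k < L and t is not None:
            go_D(k + 1, i, acc + t)

    def go_I(k, i, acc):
        if i < n:
            t = tr("IM", k)
            e = em(k + 1, i) if k < L else None
            if k < L and t is not None and e is not None:
                go_M(k + 1, i + 1, acc + t + e)
            t = tr("II", k)
            if t is not None:
                go_I(k, i + 1, acc + t)

    def go_D(k, i, acc):
        if i < n:
            t = tr("DM", k)
            e = em(k + 1, i) if k < L else None
            if k < L and t is not None and e is not None:
                go_M(k + 1, i + 1, acc + t + e)
        t = tr("DD", k)
        if k < L and t is not None:
            go_D(k + 1, i, acc + t)

    def go_E(i, acc):
        go_C(i, acc + c.tec)
        go_J(i, acc + c.tec)

    def go_J(i, acc):
        if i < n:
            go_J(i + 1, acc + c.tloop)
        go_B(i, acc + c.tmove)

    def go_B(i, acc):
        if i < n:
            for k in range(1, L + 1):
                e = em(k, i)
                if e is not None:
                    go_M(k, i + 1, acc + c.tbm + e)

    def go_C(i, acc):
        if i == n:
            upd(acc + c.tmove)
        else:
            go_C(i + 1, acc + c.tloop)

    def go_N(i, acc):
        if i < n:
            go_N(i + 1, acc + c.tloop)
        go_B(i, acc + c.tmove)

    go_N(0, 0)
    return best


def tiny_instances(n_cases=40, seed=2026):
    rng = np.random.default_rng(seed)
    for _ in range(n_cases):
        L = int(rng.integers(1, 4))
        n = int(rng.integers(1, 5))
        model = gen_model(L, seed=int(rng.integers(2**31)),
                          dd_prob=float(rng.uniform(0.02, 0.95)))
        seq = gen_sequences(1, n, n, seed=int(rng.integers(2**31)))[0]
        yield model, seq


def test_ssv_oracle_equals_exhaustive_enumeration():
    for model, seq in tiny_instances():
        scores = quantize(model, "8s")
        c = make_constants(model.L, len(seq))
        got = naive_ssv(seq, scores, c, saturating=False)
        assert got == enumerate_ssv(seq, scores, c)


def test_msv_oracle_equals_exhaustive_enumeration():
    for model, seq in tiny_instances():
        scores = quantize(model, "8s")  # score form; MSV oracle adds base
        c = make_constants(model.L, len(seq))
        got = naive_msv(seq, scores, c, saturating=False)
        assert got == enumerate_msv(seq, scores, c)


def test_viterbi_oracle_equals_exhaustive_enumeration():
    for model, seq in tiny_instances(30):
        scores = quantize(model, "16s")
        c = make_constants(model.L, len(seq))
        got = naive_viterbi(seq, scores, c, saturating=False)
        expected = enumerate_viterbi(seq, scores, c)
        if expected is None:
            assert got < NO_PATH
        else:
            assert got == expected


def test_hand_computed_two_state_two_residue_viterbi():
    """Pencil-and-paper worked example with small integer scores."""
    model = gen_model(2, seed=0)
    # overwrite with simple round numbers (bits); scale=1 keeps integers exact
    model.match_emissions[:] = -1.0
    model.match_emissions[0, 0] = 3.0   # state 1 emits A at +3
    model.match_emissions[1, 2] = 4.0   # state 2 emits D at +4
    for key, v in [("MM", -1.0), ("MI", -3.0), ("MD", -3.0), ("IM", -1.0),
                   ("II", -2.0), ("DM", -1.0), ("DD", -2.0)]:
        model.transitions[key][:] = v
    scores = quantize(model, "16s", scale=1.0)
    seq = gen_sequences(1, 2, 2, seed=0)[0]
    seq.residues[:] = [0, 2]  # "AD"
    c = make_constants(2, 2, scale=1.0)
    # n=2: tloop=log2(2/5)->-1, tmove=log2(3/5)->-1 (rint(-0.737)), tbm=log2(2/6)->-2, tec=-1
    assert (c.tloop, c.tmove, c.tbm, c.tec) == (-1, -1, -2, -1)
    # best path: N ->B(-1) M1(+3-2) ->MM(-1) M2(+4) ->E ->C(-1) ->T(-1) = +1
    assert naive_viterbi(seq, scores, c, saturating=False) == 1
    assert enumerate_viterbi(seq, scores, c) == 1


def test_unsaturated_at_least_saturated_above_floor(rng):
    """Clamping can only lower a score (or pin it at the representation floor)."""
    from tests.conftest import random_pair

    for _ in range(20):
        model, seq = random_pair(rng, L_range=(2, 60), len_range=(1, 80))
        c = make_constants(model.L, len(seq))
        s8 = quantize(model, "8s")
        assert naive_ssv(seq, s8, c, True) <= max(naive_ssv(seq, s8, c, False), -128)
        sm = quantize_msv_costs(model)
        assert naive_msv(seq, sm, c, True) <= max(naive_msv(seq, sm, c, False), 0)
        s16 = quantize(model, "16s")
        assert naive_viterbi(seq, s16, c, True) <= max(
            naive_viterbi(seq, s16, c, False), -32768
        )
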