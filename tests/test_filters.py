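"""Striped filter engines: closed forms, special cases and oracle spot checks.

The full 200-pair bit-exact equivalence sweep lives in the acceptance suite;
here we cover the structural behaviours: closed-form tiny cases, Lazy-F early
exit, saturation promotion, monotonicity and padding invariance.
"""

import numpy as np
import pytest

from hmmfilt.filters import (
    build_filter_profile,
    make_constants,
    msv_score,
    ssv_score,
    viterbi_score,
)
from hmmfilt.model_io import quantize, quantize_msv_costs
from hmmfilt.oracle import naive_msv, naive_ssv, naive_viterbi
from hmmfilt.pipeline import gen_model, gen_sequences, plant_motif
from hmmfilt.striping import LaneGeometry

from tests.conftest import random_geometry, random_pair


def _clamp8s(v):
    return max(-128, min(127, v))


class TestSSV:
    def test_single_cell_closed_form(self):
        model = gen_model(1, seed=0)
        seq = gen_sequences(1, 1, 1, seed=1)[0]
        sp = build_filter_profile(model, "ssv", LaneGeometry(2, 1))
        c = make_constants(1, 1)
        rec = ssv_score(seq, sp, c)
        e = int(quantize(model, "8s").values[0, int(seq.residues[0])])
        entry = _clamp8s(_clamp8s(0 + c.tmove) + c.tbm)
        expected = _clamp8s(_clamp8s(_clamp8s(entry + e) + c.tec) + c.tmove)
        assert rec.raw_score == expected

    def test_empty_sequence_scores_at_floor(self):
        model = gen_model(8, seed=2)
        seq = gen_sequences(1, 0, 0, seed=0)[0]
        for stage, scorer, floor in (
            ("ssv", ssv_score, -128),
            ("msv", msv_score, 0),
            ("vit", viterbi_score, -32768),
        ):
            sp = build_filter_profile(model, stage, LaneGeometry(4, 2))
            rec = scorer(seq, sp)
            assert rec.raw_score == floor
            assert rec.real_score == float("-inf")

    def test_width_checked(self):
        model = gen_model(4, seed=3)
        sp = build_filter_profile(model, "msv")
        with pytest.raises(ValueError, match="8s"):
            ssv_score(gen_sequences(1, 5, 5, seed=0)[0], sp)


class TestMSV:
    def test_j_state_rejoin_beats_single_segment(self, rng):
        """Two planted copies of the motif: MSV strictly exceeds SSV."""
        model = gen_model(10, seed=4, motif_strength=2.0)
        bg = gen_sequences(1, 60, 60, seed=5)[0]
        seq = plant_motif(plant_motif(bg, model, 5), model, 40)
        c = make_constants(model.L, len(seq))
        scores = quantize(model, "8s")
        msv = naive_msv(seq, scores, c, saturating=False)
        ssv = naive_ssv(seq, scores, c, saturating=False)
        assert msv - c.base > ssv
        # engine agrees with its oracle on both stages
        r_m = msv_score(seq, build_filter_profile(model, "msv", LaneGeometry(4, 4)), c)
        r_s = ssv_score(seq, build_filter_profile(model, "ssv", LaneGeometry(4, 4)), c)
        assert r_m.raw_score == naive_msv(seq, quantize_msv_costs(model), c)
        assert r_s.raw_score == naive_ssv(seq, scores, c)
        assert r_m.real_score > r_s.real_score

    def test_all_sentinel_emissions_score_at_floor(self):
        model = gen_model(6, seed=6)
        model.match_emissions[:] = -np.inf
        seq = gen_sequences(1, 20, 20, seed=7)[0]
        sp = build_filter_profile(model, "msv", LaneGeometry(3, 2))
        assert msv_score(seq, sp).raw_score == 0

    def test_saturation_marks_record_and_forces_pass(self):
        model = gen_model(40, seed=8, motif_strength=6.0)
        bg = gen_sequences(1, 80, 80, seed=9)[0]
        seq = plant_motif(bg, model, 10)
        for stage, scorer in (("ssv", ssv_score), ("msv", msv_score)):
            sp = build_filter_profile(model, stage, LaneGeometry(8, 4))
            rec = scorer(seq, sp, threshold=1e9)
            assert rec.saturated
            assert rec.passed  # clipped score is a lower bound


class TestViterbi:
    def test_dd_neg_inf_exits_lazy_f_after_first_check_pass(self):
        model = gen_model(60, seed=10, dd_prob=0.2)
        model.transitions["DD"][:] = -np.inf
        seq = gen_sequences(1, 50, 50, seed=11)[0]
        sp = build_filter_profile(model, "vit", LaneGeometry(4, 2))
        c = make_constants(model.L, len(seq))
        rec = viterbi_score(seq, sp, c)
        assert rec.lazy_passes == 1
        assert rec.raw_score == naive_viterbi(seq, quantize(model, "16s"), c)

    def test_dd_rich_model_needs_extra_passes_and_stays_exact(self):
        model = gen_model(60, seed=12, dd_prob=0.97)
        seq = gen_sequences(1, 50, 50, seed=13)[0]
        sp = build_filter_profile(model, "vit", LaneGeometry(2, 2))
        c = make_constants(model.L, len(seq))
        rec = viterbi_score(seq, sp, c)
        assert rec.lazy_passes > 1
        assert rec.raw_score == naive_viterbi(seq, quantize(model, "16s"), c)

    def test_single_state_model_closed_form(self):
        model = gen_model(1, seed=14)
        seq = gen_sequences(1, 1, 1, seed=15)[0]
        sp = build_filter_profile(model, "vit", LaneGeometry(2, 1))
        c = make_constants(1, 1)
        e = int(quantize(model, "16s").values[0, int(seq.residues[0])])
        # N ->B M1 ->E ->C ->T, one emitted residue
        expected = c.tmove + c.tbm + e + c.tec + c.tmove
        assert viterbi_score(seq, sp, c).raw_score == expected


def test_engines_match_oracles_on_random_spot_checks(rng):
    for _ in range(25):
        model, seq = random_pair(rng, L_range=(3, 80), len_range=(0, 120))
        geo = random_geometry(rng)
        c = make_constants(model.L, len(seq))
        assert ssv_score(seq, build_filter_profile(model, "ssv", geo), c).raw_score \
            == naive_ssv(seq, quantize(model, "8s"), c)
        assert msv_score(seq, build_filter_profile(model, "msv", geo), c).raw_score \
            == naive_msv(seq, quantize_msv_costs(model), c)
        assert viterbi_score(seq, build_filter_profile(model, "vit", geo), c).raw_score \
            == naive_viterbi(seq, quantize(model, "16s"), c)


def test_raising_one_emission_never_lowers_any_score(rng):
    for _ in range(5):
        model, seq = random_pair(rng, L_range=(5, 40), len_range=(20, 60))
        geo = LaneGeometry(4, 2)
        c = make_constants(model.L, len(seq))
        before = [
            ssv_score(seq, build_filter_profile(model, "ssv", geo), c).raw_score,
            msv_score(seq, build_filter_profile(model, "msv", geo), c).raw_score,
            viterbi_score(seq, build_filter_profile(model, "vit", geo), c).raw_score,
        ]
        k = int(rng.integers(model.L))
        a = int(rng.integers(20))
        model.match_emissions[k, a] += 1.0
        after = [
            ssv_score(seq, build_filter_profile(model, "ssv", geo), c).raw_score,
            msv_score(seq, build_filter_profile(model, "msv", geo), c).raw_score,
            viterbi_score(seq, build_filter_profile(model, "vit", geo), c).raw_score,
        ]
        assert all(b >= a for b, a in zip(after, before))


def test_padding_invariance_across_geometries(rng):
    """Wider lanes only add sentinel padding; scores must not move."""
    for _ in range(5):
        model, seq = random_pair(rng, L_range=(3, 50), len_range=(1, 80))
        c = make_constants(model.L, len(seq))
        geometries = [LaneGeometry(2, 1), LaneGeometry(4, 4), LaneGeometry(32, 4)]
        for stage, scorer in (("ssv", ssv_score), ("msv", msv_score),
                              ("vit", viterbi_score)):
            raws = {
                scorer(seq, build_filter_profile(model, stage, g), c).raw_score
                for g in geometries
            }
            assert len(raws) == 1


def test_identical_inputs_give_identical_records():
    model = gen_model(20, seed=16)
    seq = gen_sequences(1, 50, 50, seed=17)[0]
    sp = build_filter_profile(model, "vit", LaneGeometry(4, 2))
    r1 = viterbi_score(seq, sp)
    r2 = viterbi_score(seq, sp)
    assert r1 == r2
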