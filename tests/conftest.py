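"""Shared fixtures: random (model, sequence, geometry) triples and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from hmmfilt.filters import make_constants
from hmmfilt.model_io import quantize, quantize_msv_costs
from hmmfilt.pipeline import gen_model, gen_sequences
from hmmfilt.striping import LaneGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_pair(rng, L_range=(3, 200), len_range=(0, 300), dd_range=(0.02, 0.9),
                motif_strength=2.0):
    """One random (model, sequence) pair under the study conditions."""
    L = int(rng.integers(*L_range, endpoint=True))
    n = int(rng.integers(*len_range, endpoint=True))
    model = gen_model(
        L,
        seed=int(rng.integers(2**31)),
        motif_strength=motif_strength,
        dd_prob=float(rng.uniform(*dd_range)),
    )
    seq = gen_sequences(1, n, n, seed=int(rng.integers(2**31)))[0]
    return model, seq


def random_geometry(rng):
    """A small random lane geometry (tests must pass for any of them)."""
    return LaneGeometry(
        s_warp=int(rng.choice([2, 3, 4, 8, 16])),
        alpha=int(rng.choice([1, 2, 4])),
    )


@pytest.fixture
def small_model():
    return gen_model(12, seed=42)


@pytest.fixture
def small_seqs():
    return gen_sequences(5, 10, 40, seed=43)


__all__ = ["random_pair", "random_geometry"]
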