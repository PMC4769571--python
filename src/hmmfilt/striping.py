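"""Striped multi-lane layout of quantized profile scores.

A warp of ``S_warp`` threads, each operating on ``alpha`` packed sub-words,
exposes ``lanes = S_warp * alpha`` parallel integer lanes.  Profile states are
rearranged across these lanes with stripe interval

    Q = max((L - 1) // (alpha * S_warp) + 1, 2)

so that state k (1-based) lives at lane ``(k-1) // Q``, inner iteration
``(k-1) % Q``.  A DP row is then evaluated in Q lane-wide steps, and the
diagonal dependency of the next row is satisfied by a single one-lane shift
(see :func:`hmmfilt.lane_engine.reorder`).  Grid cells past state L are padded
with the scheme's sentinel (−inf: 0, −128 or −32768) and never influence
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hmmfilt.model_io import NEG_INF_INT, QuantizedScores, TRANSITION_KEYS

__all__ = [
    "LaneGeometry",
    "StripedProfile",
    "compute_q",
    "stripe",
    "stripe_vector",
    "unstripe",
    "unstripe_grid",
    "dump_striped_tsv",
]


@dataclass(frozen=True)
class LaneGeometry:
    """Lane layout of one warp: ``s_warp`` threads × ``alpha`` sub-lanes each.

    Defaults model a 32-thread warp; ``alpha`` is 4 for the 8-bit MSV/SSV
    schemes and 2 for the 16-bit Viterbi scheme.  Any positive values are
    accepted so tests can use tiny geometries.
    """

    s_warp: int = 32
    alpha: int = 4

    def __post_init__(self) -> None:
        if self.s_warp < 1 or self.alpha < 1:
            raise ValueError("s_warp and alpha must be positive")

    @property
    def lanes(self) -> int:
        return self.s_warp * self.alpha


def compute_q(L: int, alpha: int, s_warp: int) -> int:
    """Stripe interval Q for a model of L states on alpha×s_warp lanes.

    Integer (floor) division, with a lower bound of 2 so the one-lane shift
    at the end of each row always has a previous iteration to draw from.
    """
    if L < 1 or alpha < 1 or s_warp < 1:
        raise ValueError("L, alpha and s_warp must all be positive")
    return max((L - 1) // (alpha * s_warp) + 1, 2)


@dataclass
class StripedProfile:
    """Quantized profile scores rearranged into the (q, lane) striped order.

    ``emissions`` has shape ``(21, Q, lanes)``: one Q×lanes grid per residue
    symbol (20 amino acids + the ambiguity column).  For the Viterbi scheme,
    ``transitions`` holds striped Q×lanes grids keyed by transition name;
    ``*_in`` variants are pre-shifted by one state so that the grid cell of
    state k carries the transition *into* k from state k−1.
    """

    name: str
    L: int
    width: str
    scale: float
    bias: int
    sentinel: int
    geometry: LaneGeometry
    Q: int
    emissions: np.ndarray
    transitions: dict[str, np.ndarray] | None = None
    cost_form: bool = False

    def __post_init__(self) -> None:
        if self.Q < 2:
            raise ValueError("Q must be at least 2")
        if self.Q * self.geometry.lanes < self.L:
            raise ValueError("geometry too small: Q*lanes < L")


def stripe_vector(values: np.ndarray, Q: int, geometry: LaneGeometry,
                  sentinel: int) -> np.ndarray:
    """Stripe a per-state vector (length L) into a Q×lanes grid."""
    values = np.asarray(values, dtype=np.int64)
    L = values.shape[0]
    grid = np.full((Q, geometry.lanes), sentinel, dtype=np.int64)
    ks = np.arange(L)
    grid[ks % Q, ks // Q] = values
    return grid


def unstripe_grid(grid: np.ndarray, L: int, Q: int) -> np.ndarray:
    """Inverse of :func:`stripe_vector` on states 1..L."""
    ks = np.arange(L)
    return grid[ks % Q, ks // Q].copy()


def stripe(scores: QuantizedScores, geometry: LaneGeometry | None = None,
           *, name: str = "profile", Q: int | None = None) -> StripedProfile:
    """Rearrange quantized scores into the striped (q, lane) layout.

    ``Q`` defaults to :func:`compute_q` for the given geometry; passing a
    larger value (or a wider geometry) only adds sentinel padding and leaves
    every downstream filter score unchanged.
    """
    if geometry is None:
        geometry = LaneGeometry(alpha=2 if scores.width == "16s" else 4)
    L = scores.L
    if Q is None:
        Q = compute_q(L, geometry.alpha, geometry.s_warp)
    emissions = np.stack(
        [stripe_vector(scores.values[:, a], Q, geometry, scores.sentinel)
         for a in range(scores.values.shape[1])]
    )
    transitions = None
    if scores.transitions is not None:
        # Transition grids are deltas, so their -inf is NEG_INF_INT (far below
        # any representable value): a saturating add with it always floors.
        transitions = {}
        for key in TRANSITION_KEYS:
            src = scores.transitions[key]
            transitions[key] = stripe_vector(src, Q, geometry, NEG_INF_INT)
            # incoming variant: cell of state k holds the k-1 -> k transition
            shifted = np.concatenate(([NEG_INF_INT], src[:-1]))
            transitions[key + "_in"] = stripe_vector(shifted, Q, geometry,
                                                     NEG_INF_INT)
    return StripedProfile(
        name=name, L=L, width=scores.width, scale=scores.scale,
        bias=scores.bias, sentinel=scores.sentinel, geometry=geometry,
        Q=Q, emissions=emissions, transitions=transitions,
        cost_form=scores.cost_form,
    )


def unstripe(sp: StripedProfile) -> QuantizedScores:
    """Recover the per-state quantized scores from a striped profile.

    Exact inverse of :func:`stripe` on states 1..L; padded cells never
    appear in the output.
    """
    n_sym = sp.emissions.shape[0]
    values = np.stack(
        [unstripe_grid(sp.emissions[a], sp.L, sp.Q) for a in range(n_sym)], axis=1
    )
    transitions = None
    if sp.transitions is not None:
        transitions = {
            key: unstripe_grid(sp.transitions[key], sp.L, sp.Q)
            for key in TRANSITION_KEYS
        }
    return QuantizedScores(
        width=sp.width, scale=sp.scale, bias=sp.bias, sentinel=sp.sentinel,
        values=values, transitions=transitions, cost_form=sp.cost_form,
    )


def dump_striped_tsv(path, sp: StripedProfile, symbol: int = 0) -> None:
    """Debug dump of one residue symbol's Q×lanes grid as TSV."""
    with open(path, "w") as fh:
        fh.write("# q\\lane\t" + "\t".join(str(l) for l in range(sp.geometry.lanes)) + "\n")
        for q in range(sp.Q):
            fh.write(str(q) + "\t" + "\t".join(str(int(v)) for v in sp.emissions[symbol, q]) + "\n")
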