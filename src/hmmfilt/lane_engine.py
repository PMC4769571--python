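"""Warp-wide vector primitives over lane rows.

These mirror, at the level of observable values, the per-sub-word SIMD video
operations of a GPU warp (saturating add/subtract, per-lane max), the
closed-cycle shuffle that rotates a row by one lane at the end of each striped
iteration, and the butterfly max-reduction that extracts a row's maximum.

The warp's 32-thread × alpha-sub-word structure is flattened to a single
``lanes``-wide integer vector: the thread boundary has no semantic effect,
only the flat striped lane order matters, which keeps the contracts simple and
the results bit-identical to the packed-register formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hmmfilt.model_io import width_bounds
from hmmfilt.striping import LaneGeometry

__all__ = [
    "LaneRow",
    "GeometryMismatchError",
    "sat_add",
    "sat_sub",
    "vmax",
    "reorder",
    "max_reduce",
    "sat_add_arrays",
    "sat_sub_arrays",
    "reorder_array",
]


class GeometryMismatchError(ValueError):
    """Operands disagree in lane geometry or integer width."""


@dataclass
class LaneRow:
    """One DP row: a flat vector of ``lanes`` integers in striped lane order."""

    geometry: LaneGeometry
    width: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (self.geometry.lanes,):
            raise ValueError(
                f"row has {self.values.shape} values for {self.geometry.lanes} lanes"
            )
        lo, hi, _ = width_bounds(self.width)
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise ValueError(f"values out of range for width {self.width}")

    @classmethod
    def full(cls, geometry: LaneGeometry, width: str, value: int) -> "LaneRow":
        return cls(geometry, width, np.full(geometry.lanes, value, dtype=np.int64))


def _check(a: LaneRow, b: LaneRow) -> None:
    if a.geometry != b.geometry or a.width != b.width:
        raise GeometryMismatchError(
            f"mismatched rows: {a.geometry}/{a.width} vs {b.geometry}/{b.width}"
        )


# Array-level kernels (int64 in, clamped int64 out); the saturating behaviour
# of the fixed-width hardware ops is reproduced by clamping every result.

def sat_add_arrays(a: np.ndarray, b, width: str) -> np.ndarray:
    lo, hi, _ = width_bounds(width)
    return np.clip(a + b, lo, hi)


def sat_sub_arrays(a: np.ndarray, b, width: str) -> np.ndarray:
    lo, hi, _ = width_bounds(width)
    return np.clip(a - b, lo, hi)


def reorder_array(values: np.ndarray, sentinel: int) -> np.ndarray:
    out = np.empty_like(values)
    out[0] = sentinel
    out[1:] = values[:-1]
    return out


def sat_add(a: LaneRow, b: LaneRow) -> LaneRow:
    """Per-sublane saturating addition (vadd with .sat semantics)."""
    _check(a, b)
    return LaneRow(a.geometry, a.width, sat_add_arrays(a.values, b.values, a.width))


def sat_sub(a: LaneRow, b: LaneRow) -> LaneRow:
    """Per-sublane saturating subtraction (vsub with .sat semantics)."""
    _check(a, b)
    return LaneRow(a.geometry, a.width, sat_sub_arrays(a.values, b.values, a.width))


def vmax(a: LaneRow, b: LaneRow) -> LaneRow:
    """Per-sublane maximum (vmax semantics; max never saturates)."""
    _check(a, b)
    return LaneRow(a.geometry, a.width, np.maximum(a.values, b.values))


def reorder(row: LaneRow, sentinel: int) -> LaneRow:
    """Closed-cycle one-lane shift: out[0] = sentinel, out[l] = in[l-1].

    Applied to the row of the last striped iteration (q = Q−1), this places
    the score of state k where the diagonal recurrence of the next DP row's
    q = 0 step expects state k−1.  The value cycled off the last lane is
    discarded and the vacated lane receives the scheme's −inf sentinel
    (0 for MSV, the 0x80 byte pattern i.e. −128 for SSV, −32768 for Viterbi).
    """
    return LaneRow(row.geometry, row.width, reorder_array(row.values, sentinel))


def max_reduce(row: LaneRow) -> int:
    """Maximum over all sublanes (butterfly-reduction result, as a scalar)."""
    return int(row.values.max())
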