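"""Hardware-aware work scheduling and occupancy models.

Three decisions a GPU host program makes before launching the filter kernels
are modelled analytically (no device required):

* **warp work assignment** — warp ``O_warp`` of ``N_warp × N_smx`` resident
  warps processes sequence ``I_next = O_warp + C_warp · N_warp · N_smx`` as
  its ``C_warp``-th item, a static interleave that partitions any database
  with no synchronization;
* **occupancy** — with DP rows held in shared memory, a warp needs
  ``(Q+1)·S_warp·4`` bytes for the 8-bit stages and ``(3Q+1)·S_warp·4`` for
  the Viterbi stage (three state rows); the resident-warp count is the
  largest value satisfying the shared-memory and resident-thread constraints,
  and occupancy is the resulting fraction of maximum resident threads.  The
  local-memory variant keeps the launched warp count (32 by default)
  regardless of model size;
* **variant selection** — shared memory wins only for small models (empirical
  crossovers: L ≤ 300 for MSV/SSV, L ≤ 200 for Viterbi); local memory
  otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from hmmfilt.striping import compute_q

__all__ = [
    "DeviceSpec",
    "OccupancyPlan",
    "OccupancyError",
    "next_sequence_index",
    "warp_partition",
    "occupancy",
    "select_variant",
    "max_model_length_local",
    "STAGE_ALPHA",
    "SHARED_CROSSOVER",
]

#: Sub-lanes per thread for each stage (8-bit quads vs 16-bit pairs).
STAGE_ALPHA = {"ssv": 4, "msv": 4, "vit": 2}

#: Largest model length at which the shared-memory kernel is still preferred.
SHARED_CROSSOVER = {"ssv": 300, "msv": 300, "vit": 200}

#: Bytes per 32-bit register word.
_WORD = 4


class OccupancyError(ValueError):
    """No feasible resident-warp count under the given constraints."""


@dataclass(frozen=True)
class DeviceSpec:
    """Device constants relevant to the occupancy model.

    Defaults model a Kepler-class part: 15 multiprocessors, 2048 resident
    threads and 48 KB of shared memory per multiprocessor, 32-thread warps.
    """

    n_smx: int = 15
    s_thread: int = 2048
    s_shared: int = 49152
    s_warp: int = 32

    def __post_init__(self) -> None:
        if min(self.n_smx, self.s_thread, self.s_shared, self.s_warp) < 1:
            raise ValueError("device constants must be positive")


@dataclass(frozen=True)
class OccupancyPlan:
    """Resource plan for one stage at one model length."""

    L: int
    stage: str
    variant: str
    Q: int
    n_hat_warp: int
    u_bytes: int
    occupancy_pct: float
    launched_warps: int


def next_sequence_index(o_warp: int, c_warp: int, n_warp: int, n_smx: int) -> int:
    """Index of the next database sequence for one warp.

    ``o_warp`` is the warp's ordinal id across all multiprocessors, ``c_warp``
    the number of sequences it has already processed.  The caller stops once
    the returned index reaches the database size.
    """
    if min(o_warp, c_warp) < 0 or n_warp < 1 or n_smx < 1:
        raise ValueError("arguments must be non-negative (counts positive)")
    if o_warp >= n_warp * n_smx:
        raise ValueError(f"o_warp {o_warp} out of range for {n_warp * n_smx} warps")
    return o_warp + c_warp * n_warp * n_smx

def warp_partition(total: int, n_warp: int, n_smx: int) -> list[list[int]]:
    """Per-warp sequence index lists under the static interleave.

    The union over warps is exactly ``{0..total-1}`` with no duplicates.
    """
    stride = n_warp * n_smx
    out = []
    for o_warp in range(stride):
        idxs = []
        c = 0
        while True:
            i = next_sequence_index(o_warp, c, n_warp, n_smx)
            if i >= total:
                break
            idxs.append(i)
            c += 1
        out.append(idxs)
    return out


def _bytes_per_warp(Q: int, s_warp: int, stage: str) -> int:
    rows = 3 * Q + 1 if stage == "vit" else Q + 1
    return rows * s_warp * _WORD


def occupancy(
    L: int,
    stage: str,
    variant: str,
    dev: DeviceSpec | None = None,
    launched_warps: int = 32,
    alpha: int | None = None,
) -> OccupancyPlan:
    """Occupancy plan for one stage/variant at model length L.

    For the shared variant the resident-warp count is maximized subject to
    ``U <= S_shared`` and ``N_warp * S_warp <= S_thread``; the local variant
    simply keeps ``launched_warps`` resident (bounded by the thread limit)
    and uses no shared memory, so its occupancy is constant in L.
    """
    if stage not in STAGE_ALPHA:
        raise ValueError(f"unknown stage {stage!r}")
    if dev is None:
        dev = DeviceSpec()
    if alpha is None:
        alpha = STAGE_ALPHA[stage]
    Q = compute_q(L, alpha, dev.s_warp)
    max_by_threads = dev.s_thread // dev.s_warp
    if variant == "shared":
        per_warp = _bytes_per_warp(Q, dev.s_warp, stage)
        n_hat = min(max_by_threads, dev.s_shared // per_warp)
        if n_hat < 1:
            raise OccupancyError(
                f"no resident warp fits: {per_warp} B/warp > {dev.s_shared} B shared"
            )
        u = per_warp * n_hat
    elif variant == "local":
        n_hat = min(launched_warps, max_by_threads)
        u = 0
    else:
        raise ValueError(f"unknown variant {variant!r}")
    pct = n_hat * dev.s_warp / dev.s_thread * 100.0
    return OccupancyPlan(
        L=L, stage=stage, variant=variant, Q=Q, n_hat_warp=n_hat,
        u_bytes=u, occupancy_pct=pct, launched_warps=launched_warps,
    )


def select_variant(L: int, stage: str,
                   crossovers: dict[str, int] | None = None) -> str:
    """Choose shared vs local DP-row storage by model length."""
    if L < 1:
        raise ValueError("L must be positive")
    cut = (crossovers or SHARED_CROSSOVER)[stage]
    return "shared" if L <= cut else "local"


def max_model_length_local(n_local_bytes: int = 512 * 1024, alpha: int = 2,
                           s_warp: int = 32) -> int:
    """Largest model length storable in per-thread local memory.

    With three 32-bit state rows (M/I/D) per DP cell and ``n_local_bytes`` of
    local memory per thread, at most ``n_local_bytes // (4*3) - 1`` striped
    iterations fit, bounding L at ``(n_local_bytes/(4*3) - 1)·alpha·s_warp +
    1``.  Exposed as the documented formula; the bound is theoretical.
    """
    return (n_local_bytes // (_WORD * 3) - 1) * alpha * s_warp + 1
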