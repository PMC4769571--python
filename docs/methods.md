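# Methods

## Scoring model

All three filters score a digitized protein sequence against a profile HMM of
`L` match states under multihit local alignment semantics with uniform entry
and exit:

* entry `B → M_k` costs `tbm = log2(2 / (L(L+1)))` for every k;
* exit `M_k → E` is free for every k (E collects from match states only —
  delete states never feed E in the filters);
* `E → {J, C}` costs `tec = log2(1/2)`;
* the flanking/joining states N, J and C emit one residue per self-loop at
  `tloop = log2(n/(n+3))` and hand over via `tmove = log2(3/(n+3))`, where
  `n` is the *target sequence length* — these two are therefore recomputed
  per sequence (`make_constants`); a profile's `special_params` or an
  explicit `FilterConstants` can pin them instead.

SSV is this model restricted to a single ungapped segment (no J); MSV keeps
only match states plus the specials; the Viterbi filter adds the full
Match/Insert/Delete core with per-state transition scores.  Insert emissions
are fixed at 0 (configurable in principle via the profile, but the filter
semantics never read them).

## Quantization schemes

Real log-odds scores (bits) are quantized at `scale` integer units per bit
(default `3/ln 2` ≈ 4.33, i.e. third-bits):

| stage | width | representation | −inf / padding |
| --- | --- | --- | --- |
| SSV | 8-bit signed | `rint(scale·s)` | −128 (the 0x80 byte pattern) |
| MSV | 8-bit unsigned | cost bytes `clamp(bias − rint(scale·s), 0, 255)`; DP values sit on a base offset (default 190) | cost 255; row floor 0 |
| Viterbi | 16-bit signed | `rint(scale·s)` | −32768 |

The MSV cost form mirrors the vaddus/vsubus instruction pair of the real
8-bit MSV inner loop: a cell is `(max(diag, xB + tbm) +sat bias) −sat cost`.
It is not a stylistic choice — with score-form bytes there is no padding
value that an unsigned saturating add can make absorbing, whereas the maximal
cost 255 floors a padded lane exactly.  `bias` defaults to the best
emission's scaled score so that the best cost is 0.

Transition scores are *deltas*, not stored lane values, so their −inf is a
separate huge negative integer (`NEG_INF_INT = −2^30`): a saturating add with
it floors the result for every operand, which is what makes an impossible
transition truly absorbing (and makes Lazy-F exit immediately when
`t_DD = −inf`).

Quantization is monotone and clamps into the representable range; the
de-quantization error of any finite unclamped score is at most `0.5/scale`.
Ambiguity codes (B, J, O, U, X, Z → code 20) score each state's worst finite
emission — a conservative choice that can only lower the score of a sequence
carrying them.

## Striping and the lane engine

State `k` (1-based) lives at lane `(k−1) div Q`, inner step `q = (k−1) mod
Q`, with `Q = max((L−1) div (α·S_warp) + 1, 2)`.  Consecutive `q` within a
lane are consecutive states, so the diagonal predecessor of the row's `q = 0`
step is the previous row's `q = Q−1` vector shifted by one lane — the
closed-cycle `reorder`, which discards the last lane's value and injects the
scheme's sentinel into lane 0.  The warp's thread boundary (32 threads × α
sub-words) is flattened to a single `lanes`-wide vector; only the flat
striped order is semantically relevant, and results are bit-identical to the
packed formulation.

Cells past state `L` hold the sentinel.  Padded emission cells can still
produce lane values above the hard floor (e.g. a signed saturating add of a
boundary score with −128 lands above −128), but such leakage is provably
harmless: a leaked value is always at least one full `tloop` below a score
the running row-maximum already absorbed on the previous row, so no special,
flag or final score ever moves.  The padding-invariance tests (same scores
under 8-lane and 128-lane geometries) exercise exactly this.

## Lazy-F

The within-row Delete recursion `D[k] = max(M[k−1]+t_MD, D[k−1]+t_DD)` is
sequential in `k`.  The engine computes it lazily: the main striped pass
carries a per-lane carry `dcv` (each lane's own in-lane chain), the
end-of-row carry is shifted across the lane boundary once and merged into
`q = 0`, and then carry-propagation sweeps (`dcv += t_DD`, merge by max) run
only while a sweep still changes some cell.  Each productive sweep extends
chain influence by at least one lane, so the pass count is capped at
`lanes + 1`; exceeding the cap raises an internal error rather than returning
a wrong score.  Equivalence with the strict sequential recursion is asserted
against the oracle on randomized models including delete-rich ones
(`t_DD` probability up to 0.9–0.97).

## Oracles and arithmetic modes

`naive_ssv/msv/viterbi` are deliberately plain sequential DP loops on the
same quantized integers.  Saturation is not associative, so the per-operation
clipping *order* is part of the engine/oracle contract and is identical on
both sides.  With `saturating=False` the same recurrences run in unbounded
integers with a true −inf floor (`−2^40`; quantized sentinels map back to
−inf), giving the exact path optimum — this mode backs the structural
inequality SSV ≤ MSV (every single-segment path is a feasible multi-segment
path; both models share entry, exit and loop costs, including the C-state
`tloop` decay after the segment ends) and is itself validated on tiny
instances (L ≤ 3, len ≤ 4) against exhaustive enumeration of every legal
alignment path.

Saturation handling: a row whose match maximum reaches the type ceiling
(255 / 127 / 32767) marks the record saturated, and a saturated record always
passes its stage — a clipped score is a lower bound, so overflow means
"certainly above threshold".  In the pipeline a saturated SSV record is
promoted to a regular MSV evaluation.  Empty sequences are legal and score at
the floor (−inf bits).

## Planner

The occupancy model charges a warp `(Q+1)·S_warp·4` bytes of shared memory
for the 8-bit stages (Q striped row vectors plus the carry row) and
`(3Q+1)·S_warp·4` for Viterbi (M/I/D rows); the resident-warp count is the
largest value satisfying the shared-memory and resident-thread constraints,
and occupancy is `N̂_warp·S_warp / S_thread`.  The local-memory variant keeps
the launched warp count (32 by default) at any model length, hence constant
occupancy.  Device defaults model a Kepler-class part (15 SMX, 2048 threads,
48 KB shared, warp 32).  Variant selection uses fixed empirical crossovers
(shared only for L ≤ 300 at 8 bit, L ≤ 200 for Viterbi) rather than
re-deriving them from timing, which is hardware-bound; the thresholds are
configuration knobs, and filter scores are identical under either variant.
The warp scheduler's static interleave `I_next = O_warp + C_warp·N_warp·N_smx`
partitions any database exactly; the pipeline can replay it and must produce
a report identical to sequential processing.

## Synthetic data

`gen_sequences` draws i.i.d. uniform residues (codes 0–19) — a deliberately
neutral background.  `gen_model` plants a consensus residue per state at
`motif_strength` bits (default 2.0, a moderately informative column) against
off-consensus emissions centred at −1 bit, and draws core transitions from
match-dominated Dirichlet columns (mean M→M 0.9; `dd_prob` sets the mean D→D
extension and thus the length of Lazy-F chains).  `plant_motif` overwrites a
window with the consensus.  What this does *not* emulate: real amino-acid
composition, position-specific conservation structure, indel-rich homologs,
or calibrated score statistics — so passing tests demonstrate numerical
correctness of the engines on the shared integer scheme, not retrieval
performance on biological databases.  Likewise the pipeline takes plain
bit-score thresholds; E-value/P-value calibration is out of scope.

## Problem sizes and numerical choices

The randomized equivalence suite uses 200 (model, sequence, geometry)
triples per filter with L ∈ [3, 200], lengths ∈ [0, 300] and lane counts
from 2 to 128 — small enough for the pure-Python oracles to stay pleasant to
run, large enough to hit every stripe/padding/carry configuration many times.
Rounding is IEEE round-half-even (`np.rint`) everywhere.  Ties in `max` are
resolved identically on both sides by construction (plain `max`).  The
8-bit schemes assume the finite special costs stay within the byte range
(true for L up to a few thousand and any target length at the default
scale); beyond that the usual 8-bit filter caveats apply and the 16-bit
stage remains exact.
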