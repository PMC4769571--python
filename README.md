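# hmmfilt

A testable reimplementation of the three heuristic filter stages of
profile-HMM homology search (`hmmsearch`-style), built the way a warp of GPU
threads evaluates them — striped multi-lane layout, saturating sub-word
integer arithmetic, closed-cycle lane reordering, Lazy-F delete-chain
evaluation — and verified **bit-exactly** against naive sequential
dynamic-programming oracles.  A planner module models the accompanying
hardware decisions: static warp work scheduling, shared- vs local-memory
occupancy, and kernel-variant selection by model size.

## Who this is for

People studying or re-engineering the fast filter pipeline of modern
profile-HMM search: the numerics of 8-/16-bit saturating scoring, why the
striped layout turns a diagonal DP dependency into a single end-of-row lane
shift, how the lazy evaluation of the Delete–Delete chain converges, and how
on-chip memory budgets bound occupancy.  Everything runs on a CPU in plain
Python/NumPy; the GPU is *modelled*, never required.

## The filters

A query profile HMM with `L` match states scores each target sequence three
times, cheapest first:

* **SSV** (single ungapped segment): best diagonal run
  `M[i][k] = max(M[i-1][k-1], entry) + e_k(a_i)` on 8-bit signed lanes
  (−128 = −inf, the `0x80` shift-in pattern);
* **MSV** (multiple ungapped segments): SSV plus the J-state rejoin
  `xJ = max(xJ + t_loop, xE + t_EJ)`, `xB = max(base + t_move, xJ + t_move)`
  on 8-bit unsigned lanes over a base offset, emissions applied as the
  saturating `+bias` / `−cost` pair;
* **P7Viterbi**: the full Plan-7 recurrence over Match/Insert/Delete states
  on 16-bit signed lanes, with the sequential in-row D chain resolved by
  Lazy-F carry-propagation passes that stop at a fixpoint.

States are striped across `lanes = α·S_warp` vector lanes (128 for the 8-bit
stages, 64 for Viterbi at a 32-thread warp) with stripe interval

    Q = max((L − 1) div (α·S_warp) + 1, 2),

so each DP row takes Q lane-wide steps plus one closed-cycle shift.  The
`oracle` module computes the same scores by the obvious sequential DP on the
same quantized integers; the test suite demands exact equality.

## Worked example

Generate a random 30-state profile and 60 background sequences, 6 of them
with the consensus motif planted, then run the filter funnel:

```
$ hmmfilt --seed 11 synth --n-seqs 60 --plant 6 --model-length 30 \
          --len-min 80 --len-max 200 --out-seqs demo.fasta --out-profile demo.tsv
wrote 60 sequences to demo.fasta (6 with planted motif) and profile to demo.tsv

$ hmmfilt search --profile demo.tsv --seqs demo.fasta \
          --ssv-t 8 --msv-t 8 --vit-t 12 --out demo_hits.tsv
ssv: evaluated 60, passed 6 (10.0% of database)
msv: evaluated 6, passed 6 (10.0% of database)
vit: evaluated 6, passed 6 (10.0% of database)
wrote 72 records to demo_hits.tsv
```

All 60 sequences get an SSV score; only the 6 planted ones cross the 8-bit
threshold and continue to MSV and then Viterbi — the filter funnel at work.
The per-sequence TSV shows raw quantized scores, de-quantized bit scores, and
the saturation flag (a clipped 8-bit score is a lower bound, so saturation
always promotes a sequence to the next stage):

```
seq_id     stage  raw_score  bits     saturated  passed
seq00000   ssv    98         22.6428  1          1
seq00000   msv    226        8.3178   1          1
seq00000   vit    142        32.8090  0          1
```

The planner prints the resource model for a query length — stripe interval
Q, feasible resident warps, shared-memory bytes and occupancy per variant,
with `*` marking the selected kernel:

```
$ hmmfilt plan --length 600
stage  Q   variant  chosen  N_warp  U_bytes  occupancy
msv    5   shared           64      49152    100.0%
msv    5   local    *       32      0        50.0%
...
```

Library use mirrors the CLI: `gen_model` / `gen_sequences` / `plant_motif`
build fixtures, `build_filter_profile` quantizes and stripes a profile,
`ssv_score` / `msv_score` / `viterbi_score` score one sequence, and
`run_pipeline` chains the stages over a database.

## Layout

| module | contents |
| --- | --- |
| `hmmfilt.model_io` | FASTA + profile I/O (HMMER3/f subset, TSV dialect), digitization, integer quantization |
| `hmmfilt.striping` | stripe interval Q, (q, lane) layout, sentinel padding |
| `hmmfilt.lane_engine` | saturating vector ops, closed-cycle reorder, max-reduction |
| `hmmfilt.filters` | the SSV/MSV/Viterbi striped engines |
| `hmmfilt.oracle` | naive sequential DP baselines (saturating and exact modes) |
| `hmmfilt.planner` | warp scheduling, occupancy, variant selection |
| `hmmfilt.pipeline` | stage chaining, reports, synthetic fixtures |
| `hmmfilt.cli` | `hmmfilt search / plan / synth` |

See `docs/methods.md` for the scoring model, quantization schemes and design
notes.
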