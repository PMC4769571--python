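"""Filter pipeline over a sequence database, plus synthetic fixtures.

The pipeline chains SSV → MSV → Viterbi per sequence: every sequence gets an
SSV score; sequences whose SSV score crosses the stage threshold — or whose
8-bit score saturated, so the true score may be higher — continue to a regular
MSV evaluation, and MSV survivors continue to the Viterbi filter.  Thresholds
are plain bit scores (no E-value calibration); a ``None`` threshold passes
everything at that stage.

The synthetic generators produce the study conditions used throughout the
test-suite: i.i.d. uniform-residue background sequences, random profiles whose
consensus is favoured by a configurable number of bits, and motif planting by
overwriting a window of a background sequence with the profile consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from hmmfilt.filters import (
    FilterRecord,
    build_filter_profile,
    make_constants,
    msv_score,
    ssv_score,
    viterbi_score,
)
from hmmfilt.model_io import DEFAULT_SCALE, DigitizedSequence, ProfileModel
from hmmfilt.planner import warp_partition
from hmmfilt.striping import LaneGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "STAGES",
    "StageStats",
    "PipelineReport",
    "run_pipeline",
    "gen_sequences",
    "gen_model",
    "plant_motif",
]

STAGES = ("ssv", "msv", "vit")


@dataclass
class StageStats:
    evaluated: int = 0
    passed: int = 0

    def pass_fraction(self, total: int) -> float:
        return self.passed / total if total else 0.0


@dataclass
class PipelineReport:
    """Per-stage statistics and per-sequence records of one pipeline run."""

    profile_name: str
    total_sequences: int
    thresholds: dict[str, float | None]
    stages: dict[str, StageStats]
    records: list[FilterRecord]
    metadata: dict = field(default_factory=dict)

    def survivors(self) -> list[str]:
        """Ids of sequences that passed every evaluated stage."""
        last = [s for s in STAGES if s in self.stages]
        if not last:
            return []
        return [r.seq_id for r in self.records if r.stage == last[-1] and r.passed]

    def to_rows(self) -> list[dict]:
        return [
            {
                "seq_id": r.seq_id,
                "stage": r.stage,
                "raw_score": r.raw_score,
                "bits": r.real_score,
                "saturated": r.saturated,
                "passed": r.passed,
            }
            for r in self.records
        ]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seq_id\tstage\traw_score\tbits\tsaturated\tpassed\n")
            for row in self.to_rows():
                fh.write(
                    f"{row['seq_id']}\t{row['stage']}\t{row['raw_score']}\t"
                    f"{row['bits']:.4f}\t{int(row['saturated'])}\t{int(row['passed'])}\n"
                )


def run_pipeline(
    model: ProfileModel,
    seqs: list[DigitizedSequence],
    thresholds: dict[str, float | None] | None = None,
    stages: tuple[str, ...] = STAGES,
    geometry_8bit: LaneGeometry | None = None,
    geometry_16bit: LaneGeometry | None = None,
    scale: float = DEFAULT_SCALE,
    warp_schedule: tuple[int, int] | None = None,
) -> PipelineReport:
    """Score a database through the SSV → MSV → Viterbi filter funnel.

    ``thresholds`` maps stage name to a bit-score cutoff (``None`` = pass
    all).  ``warp_schedule = (n_warp, n_smx)`` processes the database in the
    static per-warp interleave instead of sequential order; because sequences
    are independent, the merged report is identical either way.
    """
    thresholds = {s: (thresholds or {}).get(s) for s in STAGES}
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    profiles = {}
    if "ssv" in stages:
        profiles["ssv"] = build_filter_profile(model, "ssv", geometry_8bit, scale)
    if "msv" in stages:
        profiles["msv"] = build_filter_profile(model, "msv", geometry_8bit, scale)
    if "vit" in stages:
        profiles["vit"] = build_filter_profile(model, "vit", geometry_16bit, scale)

    order = range(len(seqs))
    if warp_schedule is not None:
        n_warp, n_smx = warp_schedule
        order = [i for warp in warp_partition(len(seqs), n_warp, n_smx) for i in warp]

    stats = {s: StageStats() for s in stages}
    by_index: dict[int, list[FilterRecord]] = {}
    scorers = {"ssv": ssv_score, "msv": msv_score, "vit": viterbi_score}
    for i in order:
        seq = seqs[i]
        recs: list[FilterRecord] = []
        alive = True
        for stage in stages:
            if not alive:
                break
            c = make_constants(model.L, len(seq), scale,
                               overrides=model.special_params)
            rec = scorers[stage](seq, profiles[stage], c, thresholds[stage])
            stats[stage].evaluated += 1
            stats[stage].passed += rec.passed
            recs.append(rec)
            alive = rec.passed
        by_index[i] = recs

    records = [r for i in sorted(by_index) for r in by_index[i]]
    report = PipelineReport(
        profile_name=model.name,
        total_sequences=len(seqs),
        thresholds=thresholds,
        stages=stats,
        records=records,
        metadata={
            "scale": scale,
            "stages": list(stages),
            "warp_schedule": warp_schedule,
        },
    )
    for s in stages:
        logger.info(
            "stage %s: evaluated=%d passed=%d (%.1f%% of database)",
            s, stats[s].evaluated, stats[s].passed,
            100.0 * stats[s].pass_fraction(len(seqs)),
        )
    return report


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


def gen_sequences(
    n: int,
    len_min: int = 1,
    len_max: int = 300,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> list[DigitizedSequence]:
    """Random background sequences with i.i.d. uniform residues (codes 0-19)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if len_min < 0 or len_max < len_min:
        raise ValueError("need 0 <= len_min <= len_max")
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(len_min, len_max + 1))
        out.append(
            DigitizedSequence(f"seq{i:05d}", rng.integers(0, 20, size=length))
        )
    return out


def gen_model(
    L: int,
    seed: int | None = 0,
    motif_strength: float = 2.0,
    dd_prob: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ProfileModel:
    """Random profile with a planted consensus.

    Each state draws a consensus residue; its match emission is centred on
    ``motif_strength`` bits while the other 19 residues centre on −1 bit
    (weakly unfavourable, as in a real alignment column).  Core transitions
    are drawn per state around a match-dominated column (mean match→match
    probability 0.9); ``dd_prob`` sets the mean delete→delete extension
    probability, which controls how long the within-row D chains that the
    Lazy-F evaluation must resolve can get.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    consensus = rng.integers(0, 20, size=L)
    em = rng.normal(-1.0, 0.4, size=(L, 20))
    em[np.arange(L), consensus] = rng.normal(motif_strength, 0.25, size=L)

    def dirichlet(means: list[float], conc: float = 50.0) -> np.ndarray:
        return rng.dirichlet(np.asarray(means) * conc)

    trans = {k: np.full(L, -np.inf) for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")}
    for k in range(L):
        m = dirichlet([0.90, 0.05, 0.05])
        i = dirichlet([0.7, 0.3])
        d = dirichlet([1.0 - dd_prob, dd_prob])
        if k < L - 1:
            trans["MM"][k], trans["MI"][k], trans["MD"][k] = np.log2(m)
            trans["IM"][k], trans["II"][k] = np.log2(i)
            trans["DM"][k], trans["DD"][k] = np.log2(d)
        else:
            # last state: only M->I / I->I self transitions remain meaningful
            trans["MI"][k] = np.log2(i[1])
            trans["II"][k] = np.log2(i[1])
    return ProfileModel(
        name=f"synth-L{L}-s{seed if seed is not None else 'rng'}",
        L=L,
        match_emissions=em,
        insert_emissions=np.zeros((L, 20)),
        transitions=trans,
    )


def plant_motif(seq: DigitizedSequence, model: ProfileModel,
                pos: int) -> DigitizedSequence:
    """Overwrite ``seq[pos : pos+L]`` with the model consensus.

    The sequence length is unchanged; the window must fit entirely.
    """
    L = model.L
    if pos < 0 or pos + L > len(seq):
        raise ValueError(
            f"motif of length {L} at position {pos} does not fit in "
            f"sequence of length {len(seq)}"
        )
    residues = seq.residues.copy()
    residues[pos : pos + L] = model.consensus()
    return DigitizedSequence(seq.id, residues)
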