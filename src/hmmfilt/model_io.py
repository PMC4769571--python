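"""Profile and sequence I/O, residue digitization and integer quantization.

Real-valued log-odds scores (in bits) are quantized to one of three fixed-width
integer schemes before any filter runs:

``8u``
    unsigned bytes in [0, 255] with a positive bias; the MSV filter's scheme.
    The sentinel (−inf) is 0, so the bias is normally chosen such that the
    worst finite score still maps at or above 1.
``8s``
    signed bytes in [−128, 127]; the SSV filter's scheme.  The sentinel is
    −128, i.e. the 0x80 byte pattern shifted into vacated lanes.
``16s``
    signed 16-bit words in [−32768, 32767]; the Viterbi filter's scheme, with
    −32768 as sentinel.

All downstream engines and oracles operate on the *same* quantized integers,
so filter correctness is independent of the particular scale/bias chosen here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "AMBIGUOUS_CODE",
    "BACKGROUND_FREQS",
    "DEFAULT_SCALE",
    "NEG_INF",
    "ProfileModel",
    "DigitizedSequence",
    "QuantizedScores",
    "ProfileFormatError",
    "SequenceFormatError",
    "digitize",
    "read_fasta",
    "write_fasta",
    "read_profile",
    "write_profile",
    "write_profile_hmmer3",
    "quantize",
    "quantize_msv_costs",
    "quantize_values",
    "dequantize",
    "NEG_INF_INT",
    "default_bias",
    "width_bounds",
]

#: Canonical 20-letter amino-acid alphabet; residue code = index in this string.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Code assigned to every ambiguity / non-standard symbol (B, J, O, U, X, Z).
AMBIGUOUS_CODE = 20

_AMBIGUOUS_LETTERS = set("BJOUXZ")
_CODE_OF = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: −inf marker for real-valued log-odds scores.
NEG_INF = float("-inf")

#: Integer −inf for quantized *deltas* (transition costs).  Unlike a stored
#: value sentinel it is far below every representable score, so a saturating
#: add truly floors the result regardless of the other operand.
NEG_INF_INT = -(2**30)

#: Default quantization scale: 3/ln 2 integer units per bit (third-nats).
DEFAULT_SCALE = 3.0 / math.log(2.0)

#: Swiss-Prot amino-acid background frequencies, indexed like AMINO_ACIDS.
BACKGROUND_FREQS = np.array(
    [
        0.0787945,  # A
        0.0151600,  # C
        0.0535222,  # D
        0.0668298,  # E
        0.0397062,  # F
        0.0695071,  # G
        0.0229198,  # H
        0.0590092,  # I
        0.0594422,  # K
        0.0963728,  # L
        0.0237718,  # M
        0.0414386,  # N
        0.0482904,  # P
        0.0395639,  # Q
        0.0540978,  # R
        0.0683364,  # S
        0.0540687,  # T
        0.0673417,  # V
        0.0114135,  # W
        0.0304133,  # Y
    ]
)

#: Transition keys, indexed by *source* state k (array position k−1).
TRANSITION_KEYS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")

_WIDTH_BOUNDS = {
    "8u": (0, 255, 0),
    "8s": (-128, 127, -128),
    "16s": (-32768, 32767, -32768),
}


class ProfileFormatError(ValueError):
    """Raised for malformed or unsupported profile files."""


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA input."""


def width_bounds(width: str) -> tuple[int, int, int]:
    """Return ``(lo, hi, sentinel)`` for an integer score width."""
    try:
        return _WIDTH_BOUNDS[width]
    except KeyError:
        raise ValueError(f"unknown score width {width!r}; expected 8u, 8s or 16s")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ProfileModel:
    """A query profile HMM as real-valued log-odds scores (bits).

    Parameters
    ----------
    name:
        Model identifier.
    L:
        Number of consensus (match) states, ≥ 1.
    match_emissions:
        ``(L, 20)`` array of match-state emission log-odds in bits; ``-inf``
        marks an impossible residue.
    insert_emissions:
        Optional ``(L, 20)`` array of insert-state emission log-odds.  The
        Viterbi filter fixes insert emissions to 0, so this is informational.
    transitions:
        Mapping from the seven core transition keys (MM, MI, MD, IM, II, DM,
        DD) to ``(L,)`` arrays of log2 probabilities, indexed by *source*
        state ``k`` at array position ``k-1``.  Transitions that do not exist
        (e.g. MM out of the last state) are ``-inf``.
    special_params:
        Optional fixed overrides (in bits) for the loop/move/begin/exit costs
        of the filter models (keys ``tloop``, ``tmove``, ``tbm``, ``tec``).
        By default these are recomputed per target sequence; see
        :func:`hmmfilt.filters.make_constants`.
    """

    name: str
    L: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray | None = None
    transitions: dict[str, np.ndarray] | None = None
    special_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("profile must have at least one match state")
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        if self.match_emissions.shape != (self.L, 20):
            raise ValueError(
                f"match_emissions shape {self.match_emissions.shape} != ({self.L}, 20)"
            )
        if self.insert_emissions is not None:
            self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
            if self.insert_emissions.shape != (self.L, 20):
                raise ValueError("insert_emissions shape mismatch")
        if self.transitions is not None:
            for key in TRANSITION_KEYS:
                if key not in self.transitions:
                    raise ValueError(f"missing transition array {key!r}")
                arr = np.asarray(self.transitions[key], dtype=float)
                if arr.shape != (self.L,):
                    raise ValueError(f"transition {key!r} must have shape ({self.L},)")
                self.transitions[key] = arr

    def consensus(self) -> np.ndarray:
        """Residue codes of the highest-scoring residue per match state."""
        return np.argmax(self.match_emissions, axis=1)


@dataclass
class DigitizedSequence:
    """A protein sequence as integer residue codes (0..19; ambiguous → 20)."""

    id: str
    residues: np.ndarray

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=np.int64)
        if self.residues.ndim != 1:
            raise ValueError("residues must be a 1-D vector")
        if self.residues.size and (
            self.residues.min() < 0 or self.residues.max() > AMBIGUOUS_CODE
        ):
            raise ValueError("residue codes must lie in 0..20")

    def __len__(self) -> int:
        return int(self.residues.size)

    def text(self) -> str:
        """Letter representation; ambiguous residues render as 'X'."""
        table = AMINO_ACIDS + "X"
        return "".join(table[c] for c in self.residues)


@dataclass
class QuantizedScores:
    """Integer-quantized profile scores.

    ``values`` holds the match-emission matrix with 21 columns: the 20 amino
    acids followed by the ambiguity column (the worst finite score of each
    row, a conservative stand-in).  For the 16-bit scheme the seven core
    transition arrays are quantized alongside, so engine and oracle consume
    identical integers.
    """

    width: str
    scale: float
    bias: int
    sentinel: int
    values: np.ndarray
    transitions: dict[str, np.ndarray] | None = None
    cost_form: bool = False

    @property
    def L(self) -> int:
        return int(self.values.shape[0])


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def digitize(text: str, *, record_id: str = "<anonymous>") -> np.ndarray:
    """Digitize a residue string case-insensitively.

    Ambiguity and non-standard codes (B, J, O, U, X, Z) map to
    :data:`AMBIGUOUS_CODE`; any other non-alphabetic symbol is an error.
    """
    codes = np.empty(len(text), dtype=np.int64)
    for i, ch in enumerate(text.upper()):
        code = _CODE_OF.get(ch)
        if code is None:
            if ch in _AMBIGUOUS_LETTERS:
                code = AMBIGUOUS_CODE
            else:
                raise SequenceFormatError(
                    f"illegal residue {ch!r} at position {i + 1} of record {record_id!r}"
                )
        codes[i] = code
    return codes


def read_fasta(path) -> list[DigitizedSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file and digitize it.

    Raises :class:`SequenceFormatError` naming the offending record for empty
    headers or illegal residue characters.
    """
    out: list[DigitizedSequence] = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise SequenceFormatError(f"record {idx + 1} in {path} has an empty header")
        out.append(DigitizedSequence(rec.id, digitize(str(rec.seq), record_id=rec.id)))
    return out


def write_fasta(path, seqs: list[DigitizedSequence], *, width: int = 60) -> None:
    """Write digitized sequences back to FASTA (ambiguous residues as 'X')."""
    records = [
        SeqRecord(Seq(s.text()), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


def quantize_values(values: np.ndarray, width: str, scale: float, bias: int,
                    neg_inf: int | None = None) -> np.ndarray:
    """Quantize an array of real log-odds scores (bits) to integers.

    Each finite score ``s`` maps to ``clamp(rint(scale*s) + bias, lo, hi)``;
    ``-inf`` maps to the width's sentinel (or to ``neg_inf`` when given, as
    used for transition deltas).  Defined (by clamping) for every input, and
    monotone: ``s1 <= s2`` implies ``q(s1) <= q(s2)``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    lo, hi, sentinel = width_bounds(width)
    if neg_inf is not None:
        sentinel = neg_inf
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    out = np.full(arr.shape, sentinel, dtype=np.int64)
    scaled = np.rint(scale * arr[finite]).astype(np.int64) + int(bias)
    out[finite] = np.clip(scaled, lo, hi)
    return out


def default_bias(model: ProfileModel, width: str, scale: float) -> int:
    """Bias such that the worst finite match emission maps to at least 1 (8u).

    Signed widths need no offset and get bias 0.
    """
    if width != "8u":
        return 0
    finite = model.match_emissions[np.isfinite(model.match_emissions)]
    if finite.size == 0:
        return 1
    worst = int(np.rint(scale * finite.min()))
    return max(1 - worst, 1)


def quantize(
    model: ProfileModel,
    width: str,
    scale: float = DEFAULT_SCALE,
    bias: int | None = None,
) -> QuantizedScores:
    """Quantize a profile's match emissions (and, for 16s, its transitions).

    The returned matrix has 21 columns; column 20 (ambiguous residues) holds
    each state's worst finite score, a conservative choice that can only
    lower the score of sequences carrying ambiguity codes.
    """
    if bias is None:
        bias = default_bias(model, width, scale)
    lo, hi, sentinel = width_bounds(width)
    em = quantize_values(model.match_emissions, width, scale, bias)
    ambig = np.full((model.L, 1), sentinel, dtype=np.int64)
    for i in range(model.L):
        finite = em[i][em[i] != sentinel]
        if finite.size:
            ambig[i, 0] = finite.min()
    values = np.concatenate([em, ambig], axis=1)

    transitions = None
    if width == "16s" and model.transitions is not None:
        transitions = {
            key: quantize_values(model.transitions[key], width, scale, 0,
                                 neg_inf=NEG_INF_INT)
            for key in TRANSITION_KEYS
        }
    return QuantizedScores(
        width=width,
        scale=float(scale),
        bias=int(bias),
        sentinel=sentinel,
        values=values,
        transitions=transitions,
    )


def quantize_msv_costs(model: ProfileModel, scale: float = DEFAULT_SCALE,
                       bias: int | None = None) -> QuantizedScores:
    """Quantize match emissions into the MSV filter's biased-cost bytes.

    Each finite score ``s`` becomes the cost ``clamp(bias - rint(scale*s),
    0, 255)``; the DP inner loop adds ``bias`` saturating at 255 and then
    subtracts the cost saturating at 0, so the net change is ``rint(scale*s)``
    while −inf / padding cells — cost 255, the minimum representable score
    under the cost interpretation — floor the lane exactly.  ``bias``
    defaults to the best emission's scaled score, giving that emission cost 0.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    em = model.match_emissions
    finite = em[np.isfinite(em)]
    if bias is None:
        bias = max(int(np.rint(scale * finite.max())), 1) if finite.size else 1
    scaled = np.rint(scale * np.where(np.isfinite(em), em, 0.0)).astype(np.int64)
    cost = np.clip(bias - scaled, 0, 255)
    cost[~np.isfinite(em)] = 255
    ambig = np.full((model.L, 1), 255, dtype=np.int64)
    for i in range(model.L):
        row = cost[i][cost[i] != 255]
        if row.size:
            ambig[i, 0] = row.max()  # worst finite score = largest cost
    values = np.concatenate([cost, ambig], axis=1)
    return QuantizedScores(
        width="8u", scale=float(scale), bias=int(bias), sentinel=255,
        values=values, cost_form=True,
    )


def dequantize(raw: int, scheme: QuantizedScores | None = None, *,
               scale: float | None = None, bias: int = 0,
               sentinel: int | None = None) -> float:
    """Map a raw integer score back to bits; the sentinel maps to −inf."""
    if scheme is not None:
        scale, bias, sentinel = scheme.scale, scheme.bias, scheme.sentinel
    if scale is None:
        raise ValueError("either a scheme or an explicit scale is required")
    if sentinel is not None and raw == sentinel:
        return NEG_INF
    return (raw - bias) / scale


# ---------------------------------------------------------------------------
# profile files: package TSV dialect
# ---------------------------------------------------------------------------

_TSV_MAGIC = "#hmmfilt-profile\tv1"


def write_profile(path, model: ProfileModel) -> None:
    """Write a profile in the package's TSV score-matrix dialect.

    Layout: a magic first line, ``name``/``L`` key rows, then one block per
    section.  ``match`` and ``insert`` blocks carry L rows of 20 tab-separated
    log-odds (bits, ``*`` = −inf); the ``transitions`` block carries L rows of
    the seven core transitions in :data:`TRANSITION_KEYS` order.
    """

    def fmt(x: float) -> str:
        return "*" if not math.isfinite(x) else f"{x:.6f}"

    with open(path, "w") as fh:
        fh.write(_TSV_MAGIC + "\n")
        fh.write(f"name\t{model.name}\n")
        fh.write(f"L\t{model.L}\n")
        for key, val in sorted(model.special_params.items()):
            fh.write(f"special\t{key}\t{fmt(val)}\n")
        fh.write("match\n")
        for row in model.match_emissions:
            fh.write("\t".join(fmt(x) for x in row) + "\n")
        if model.insert_emissions is not None:
            fh.write("insert\n")
            for row in model.insert_emissions:
                fh.write("\t".join(fmt(x) for x in row) + "\n")
        if model.transitions is not None:
            fh.write("transitions\t" + "\t".join(TRANSITION_KEYS) + "\n")
            for k in range(model.L):
                fh.write(
                    "\t".join(fmt(model.transitions[key][k]) for key in TRANSITION_KEYS)
                    + "\n"
                )


def _parse_score(tok: str, where: str) -> float:
    if tok == "*":
        return NEG_INF
    try:
        return float(tok)
    except ValueError:
        raise ProfileFormatError(f"bad score {tok!r} in {where}")


def _read_profile_tsv(lines: list[str], path) -> ProfileModel:
    name = "unnamed"
    L = None
    specials: dict[str, float] = {}
    match_rows: list[list[float]] = []
    insert_rows: list[list[float]] = []
    trans_rows: list[list[float]] = []
    section = None
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        toks = line.split("\t")
        head = toks[0]
        if head == "name":
            name = toks[1]
        elif head == "L":
            L = int(toks[1])
        elif head == "special":
            specials[toks[1]] = _parse_score(toks[2], f"{path}:{lineno}")
        elif head in ("match", "insert"):
            section = head
        elif head == "transitions":
            section = "transitions"
        elif section is not None:
            row = [_parse_score(t, f"{path}:{lineno}") for t in toks]
            target = {"match": match_rows, "insert": insert_rows,
                      "transitions": trans_rows}[section]
            expected = 7 if section == "transitions" else 20
            if len(row) != expected:
                raise ProfileFormatError(
                    f"{path}:{lineno}: expected {expected} scores, got {len(row)}"
                )
            target.append(row)
        else:
            raise ProfileFormatError(f"{path}:{lineno}: unexpected line {line!r}")
    if L is None:
        raise ProfileFormatError(f"{path}: missing L header")
    if len(match_rows) != L:
        raise ProfileFormatError(
            f"{path}: declared L={L} but found {len(match_rows)} match rows"
        )
    transitions = None
    if trans_rows:
        if len(trans_rows) != L:
            raise ProfileFormatError(f"{path}: transitions block must have L rows")
        arr = np.array(trans_rows, dtype=float)
        transitions = {key: arr[:, j].copy() for j, key in enumerate(TRANSITION_KEYS)}
    return ProfileModel(
        name=name,
        L=L,
        match_emissions=np.array(match_rows, dtype=float),
        insert_emissions=np.array(insert_rows, dtype=float) if insert_rows else None,
        transitions=transitions,
        special_params=specials,
    )


# ---------------------------------------------------------------------------
# profile files: HMMER3/f ASCII subset
# ---------------------------------------------------------------------------


def _neglog_to_prob(tok: str, where: str) -> float:
    """HMMER3 stores scores as −ln p; '*' denotes probability zero."""
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError:
        raise ProfileFormatError(f"bad value {tok!r} in {where}")


def _log2(p: float) -> float:
    return math.log2(p) if p > 0.0 else NEG_INF


def _read_profile_hmmer3(lines: list[str], path) -> ProfileModel:
    header = lines[0].split()
    if not header or not header[0].startswith("HMMER3/f"):
        raise ProfileFormatError(
            f"{path}: unsupported profile version {lines[0].strip()!r}; "
            "only the HMMER3/f dialect is supported"
        )
    name = "unnamed"
    L = None
    alph = None
    i = 1
    while i < len(lines):
        toks = lines[i].split()
        if not toks:
            i += 1
            continue
        key = toks[0]
        if key == "NAME":
            name = toks[1] if len(toks) > 1 else name
        elif key == "LENG":
            L = int(toks[1])
        elif key == "ALPH":
            alph = toks[1].lower()
        elif key == "HMM":
            break
        i += 1
    else:
        raise ProfileFormatError(f"{path}: missing HMM section")
    if L is None:
        raise ProfileFormatError(f"{path}: missing LENG line")
    if alph != "amino":
        raise ProfileFormatError(f"{path}: only amino alphabets are supported")

    symbols = lines[i].split()[1:]
    if [s.upper() for s in symbols] != list(AMINO_ACIDS):
        raise ProfileFormatError(f"{path}: unexpected symbol order in HMM line")
    i += 2  # skip the transition-label line

    # Node 0: optional COMPO line, insert-0 emissions, begin transitions.
    if i < len(lines) and lines[i].split() and lines[i].split()[0] == "COMPO":
        i += 1
    i += 2

    log_bg = np.log2(BACKGROUND_FREQS)
    match = np.zeros((L, 20))
    insert = np.zeros((L, 20))
    trans = {key: np.full(L, NEG_INF) for key in TRANSITION_KEYS}
    for k in range(1, L + 1):
        if i + 2 >= len(lines):
            raise ProfileFormatError(f"{path}: truncated node block at state {k}")
        mtoks = lines[i].split()
        where = f"{path} node {k}"
        if not mtoks or mtoks[0] != str(k):
            raise ProfileFormatError(f"{where}: expected node index {k}, got {mtoks[:1]}")
        if len(mtoks) < 21:
            raise ProfileFormatError(f"{where}: short match emission line")
        for a in range(20):
            p = _neglog_to_prob(mtoks[1 + a], where)
            match[k - 1, a] = _log2(p) - log_bg[a] if p > 0 else NEG_INF
        itoks = lines[i + 1].split()
        if len(itoks) < 20:
            raise ProfileFormatError(f"{where}: short insert emission line")
        for a in range(20):
            p = _neglog_to_prob(itoks[a], where)
            insert[k - 1, a] = _log2(p) - log_bg[a] if p > 0 else NEG_INF
        ttoks = lines[i + 2].split()
        if len(ttoks) < 7:
            raise ProfileFormatError(f"{where}: short transition line")
        for j, key in enumerate(TRANSITION_KEYS):
            trans[key][k - 1] = _log2(_neglog_to_prob(ttoks[j], where))
        i += 3
    if i >= len(lines) or lines[i].strip() != "//":
        raise ProfileFormatError(f"{path}: missing // terminator")
    return ProfileModel(
        name=name, L=L, match_emissions=match, insert_emissions=insert,
        transitions=trans,
    )


def write_profile_hmmer3(path, model: ProfileModel) -> None:
    """Write a profile as a minimal HMMER3/f ASCII file.

    Emission log-odds are converted back to the format's −ln p convention
    against the standard background, so ``read_profile`` round-trips within
    text precision.  Requires the model to carry transitions.
    """
    if model.transitions is None:
        raise ValueError("HMMER3/f output requires transition scores")

    def em_tok(s: float, a: int) -> str:
        if not math.isfinite(s):
            return "*"
        p = BACKGROUND_FREQS[a] * (2.0 ** s)
        return f"{-math.log(p):8.5f}"

    def tr_tok(s: float) -> str:
        if not math.isfinite(s):
            return "*"
        return f"{-s * math.log(2.0):8.5f}"

    with open(path, "w") as fh:
        fh.write("HMMER3/f [hmmfilt | profile subset]\n")
        fh.write(f"NAME  {model.name}\n")
        fh.write(f"LENG  {model.L}\n")
        fh.write("ALPH  amino\n")
        fh.write("HMM          " + "        ".join(AMINO_ACIDS) + "\n")
        fh.write("            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n")
        zeros = " ".join(["  0.00000"] * 20)
        fh.write("  " + zeros + "\n")  # insert-0 emissions
        fh.write("    0.00000        *  0.00000  0.00000  0.00000        *        *\n")
        for k in range(1, model.L + 1):
            em = " ".join(em_tok(model.match_emissions[k - 1, a], a) for a in range(20))
            cons = AMINO_ACIDS[int(np.argmax(model.match_emissions[k - 1]))].lower()
            fh.write(f"{k:7d} {em} {k:7d} {cons} - - -\n")  # MAP CONS RF MM CS
            if model.insert_emissions is not None:
                ins = " ".join(
                    em_tok(model.insert_emissions[k - 1, a], a) for a in range(20)
                )
            else:
                ins = zeros
            fh.write("  " + ins + "\n")
            tr = " ".join(tr_tok(model.transitions[key][k - 1]) for key in TRANSITION_KEYS)
            fh.write("  " + tr + "\n")
        fh.write("//\n")


def read_profile(path) -> ProfileModel:
    """Read a profile from HMMER3/f ASCII or the package TSV dialect.

    The format is sniffed from the first line; anything else is rejected with
    a :class:`ProfileFormatError`.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ProfileFormatError(f"{path}: empty profile file")
    first = lines[0]
    if first.startswith(_TSV_MAGIC):
        return _read_profile_tsv(lines, path)
    if first.startswith("HMMER"):
        return _read_profile_hmmer3(lines, path)
    raise ProfileFormatError(f"{path}: unrecognized profile format")
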