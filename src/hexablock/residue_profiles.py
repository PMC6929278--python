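"""Per-residue encodings: physicochemical properties and evolutionary profiles.

Two residue-level channels feed the local feature extractors:

* a six-property physicochemical vector per amino-acid type (hydrophobicity,
  side-chain volume, polarity, polarizability, solvent-accessible surface
  area, net charge index of side chains), z-scored per property over the 20
  standard types;
* a position specific scoring matrix (PSSM), either parsed from PSI-BLAST
  ASCII output or constructed from a per-position frequency profile projected
  through a Dayhoff-style substitution matrix, then min-max normalised to
  [0, 1] over the whole L x 20 matrix.

All matrices use the fixed alphabet order A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,
V,W,Y; inputs in other orders are remapped on parse.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "ALPHABET",
    "AA_INDEX",
    "PROPERTY_NAMES",
    "PHYSCHEM_RAW",
    "PhyschemTable",
    "NormalizedPhyschemTable",
    "FrequencyProfile",
    "SubstitutionMatrix",
    "PSSM",
    "NormalizedPSSM",
    "ProfileError",
    "dayhoff_matrix",
    "normalize_physchem",
    "encode_physchem",
    "build_pssm",
    "minmax_normalize",
    "parse_psiblast_pssm",
    "write_psiblast_pssm",
]

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

PROPERTY_NAMES = ("H", "VSC", "P1", "P2", "SASA", "NCISC")

# Six physicochemical properties per standard amino acid, raw units:
# hydrophobicity, side-chain volume, polarity, polarizability,
# solvent-accessible surface area, net charge index of side chains.
PHYSCHEM_RAW = np.array([
    #  H      VSC     P1     P2      SASA    NCISC
    [ 0.62,   27.5,   8.1,  0.046,  1.181,  0.007187],  # A
    [ 0.29,   44.6,   5.5,  0.128,  1.461, -0.03661 ],  # C
    [-0.90,   40.0,  13.0,  0.105,  1.587, -0.02382 ],  # D
    [-0.74,   62.0,  12.3,  0.151,  1.862,  0.006802],  # E
    [ 1.19,  115.5,   5.2,  0.290,  2.228,  0.037552],  # F
    [ 0.48,    0.0,   9.0,  0.000,  0.881,  0.179052],  # G
    [-0.40,   79.0,  10.4,  0.230,  2.025, -0.01069 ],  # H
    [ 1.38,   93.5,   5.2,  0.186,  1.810,  0.021631],  # I
    [-1.50,  100.0,  11.3,  0.219,  2.258,  0.017708],  # K
    [ 1.06,   93.5,   4.9,  0.186,  1.931,  0.051672],  # L
    [ 0.64,   94.1,   5.7,  0.221,  2.034,  0.002683],  # M
    [-0.78,   58.7,  11.6,  0.134,  1.655,  0.005392],  # N
    [ 0.12,   41.9,   8.0,  0.131,  1.468,  0.239531],  # P
    [-0.85,   80.7,  10.5,  0.180,  1.932,  0.049211],  # Q
    [-2.53,  105.0,  10.5,  0.291,  2.560,  0.043587],  # R
    [-0.18,   29.3,   9.2,  0.062,  1.298,  0.004627],  # S
    [-0.05,   51.3,   8.6,  0.108,  1.525,  0.003352],  # T
    [ 1.08,   71.5,   5.9,  0.140,  1.645,  0.057004],  # V
    [ 0.81,  145.5,   5.4,  0.409,  2.663,  0.037977],  # W
    [ 0.26,  117.3,   6.2,  0.298,  2.368,  0.023599],  # Y
])

# Non-standard one-letter codes mapped to their nearest standard type.
AMBIGUOUS_MAP = {"B": "N", "Z": "Q", "U": "C", "O": "K", "J": "L"}


class ProfileError(ValueError):
    """Raised on malformed profiles, tables or parse failures."""


@dataclass(frozen=True)
class PhyschemTable:
    """20 x 6 matrix of raw physicochemical property values."""

    values: np.ndarray = None

    def __post_init__(self):
        v = PHYSCHEM_RAW if self.values is None else np.asarray(self.values, float)
        if v.shape != (20, 6) or not np.all(np.isfinite(v)):
            raise ProfileError("physicochemical table must be a finite 20x6 matrix")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class NormalizedPhyschemTable:
    """20 x 6 table with zero-mean, unit-SD columns over the 20 types."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (20, 6):
            raise ProfileError("normalized table must be 20x6")
        if np.max(np.abs(v.mean(axis=0))) > 1e-9:
            raise ProfileError("columns must have zero mean")
        if np.max(np.abs(v.std(axis=0) - 1.0)) > 1e-9:
            raise ProfileError("columns must have unit SD")
        object.__setattr__(self, "values", v)

    def row(self, aa: str) -> np.ndarray:
        return self.values[AA_INDEX[aa]]


@dataclass(frozen=True)
class FrequencyProfile:
    """L x 20 per-position amino-acid frequencies; rows sum to 1."""

    omega: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.omega, float)
        if w.ndim != 2 or w.shape[1] != 20:
            raise ProfileError("frequency profile must be L x 20")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ProfileError("frequencies must lie in [0, 1]")
        if np.max(np.abs(w.sum(axis=1) - 1.0)) > 1e-6:
            raise ProfileError("each profile row must sum to 1")
        object.__setattr__(self, "omega", w)

    @property
    def length(self) -> int:
        return self.omega.shape[0]


@dataclass(frozen=True)
class SubstitutionMatrix:
    """20 x 20 substitution-score matrix in the internal alphabet order."""

    D: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.D, float)
        if d.shape != (20, 20) or not np.all(np.isfinite(d)):
            raise ProfileError("substitution matrix must be a finite 20x20 matrix")
        object.__setattr__(self, "D", d)


@dataclass(frozen=True)
class PSSM:
    """L x 20 position specific scoring matrix."""

    scores: np.ndarray
    source: str = "constructed"

    def __post_init__(self):
        s = np.asarray(self.scores, float)
        if s.ndim != 2 or s.shape[1] != 20 or not np.all(np.isfinite(s)):
            raise ProfileError("PSSM must be a finite L x 20 matrix")
        object.__setattr__(self, "scores", s)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class NormalizedPSSM:
    """PSSM min-max rescaled to [0, 1] over the whole matrix."""

    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, float)
        if s.ndim != 2 or s.shape[1] != 20:
            raise ProfileError("normalized PSSM must be L x 20")
        if abs(s.min()) > 1e-9 or abs(s.max() - 1.0) > 1e-9:
            raise ProfileError("normalized PSSM must span [0, 1] exactly")
        object.__setattr__(self, "scores", s)

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def row(self, i: int) -> np.ndarray:
        """Profile row for 1-based sequence position i."""
        return self.scores[i - 1]


@lru_cache(maxsize=1)
def dayhoff_matrix() -> SubstitutionMatrix:
    """Dayhoff-family substitution scores (PAM250 log-odds dialect),
    remapped to the internal alphabet order."""
    pam = substitution_matrices.load("PAM250")
    D = np.empty((20, 20))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            D[i, j] = pam[a, b]
    return SubstitutionMatrix(D)


def normalize_physchem(table: Optional[PhyschemTable] = None, ddof: int = 0) -> NormalizedPhyschemTable:
    """Z-score each property column over the 20 amino-acid types.

    ``ddof=0`` (population SD over the full set of 20 types) is the default;
    ``ddof=1`` switches to the sample convention.
    """
    table = table or PhyschemTable()
    v = table.values
    sd = v.std(axis=0, ddof=ddof)
    if np.any(sd < 1e-12):
        raise ProfileError("constant property column: zero standard deviation")
    out = (v - v.mean(axis=0)) / sd
    if ddof != 0:
        # the invariant is stated for population SD; re-wrap without the check
        obj = object.__new__(NormalizedPhyschemTable)
        object.__setattr__(obj, "values", out)
        return obj
    return NormalizedPhyschemTable(out)


def encode_physchem(
    sequence: str,
    table: Optional[NormalizedPhyschemTable] = None,
    strict: bool = False,
) -> np.ndarray:
    """Encode a sequence as an L x 6 matrix of normalized property vectors.

    Ambiguity codes (B, Z, U, O, J) map to the nearest standard type and X to
    the column means; in strict mode any non-standard code raises.
    """
    table = table or normalize_physchem()
    rows = []
    for i, aa in enumerate(sequence.upper()):
        if aa in AA_INDEX:
            rows.append(table.values[AA_INDEX[aa]])
        elif strict:
            raise ProfileError(f"non-standard residue {aa!r} at position {i + 1}")
        elif aa in AMBIGUOUS_MAP:
            rows.append(table.values[AA_INDEX[AMBIGUOUS_MAP[aa]]])
        elif aa == "X":
            rows.append(table.values.mean(axis=0))
        else:
            raise ProfileError(f"unknown residue code {aa!r} at position {i + 1}")
    if not rows:
        raise ProfileError("empty sequence")
    return np.array(rows)


def build_pssm(profile: FrequencyProfile, subst: Optional[SubstitutionMatrix] = None) -> PSSM:
    """Project a frequency profile through a substitution matrix:
    ``scores[i, j] = sum_k omega[i, k] * D[k, j]``."""
    subst = subst or dayhoff_matrix()
    return PSSM(profile.omega @ subst.D, source="constructed")


def minmax_normalize(pssm: PSSM) -> NormalizedPSSM:
    """Rescale the whole matrix to [0, 1] by its global min and max."""
    s = pssm.scores
    lo, hi = float(s.min()), float(s.max())
    if hi - lo < 1e-12:
        raise ProfileError("constant PSSM cannot be min-max normalized")
    return NormalizedPSSM((s - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM I/O
# ---------------------------------------------------------------------------

def parse_psiblast_pssm(text: str, use_frequencies: bool = False):
    """Parse a PSI-BLAST ASCII PSSM file.

    Returns ``(PSSM, sequence)`` from the first 20 (log-odds) columns by
    default.  With ``use_frequencies=True`` returns
    ``(FrequencyProfile, sequence)`` built from the percent-frequency block
    (columns 21-40) divided by 100 and renormalised per row.

    Trailing statistics lines (K, lambda) are ignored.  Columns are remapped
    from the file's own amino-acid header order to the internal order.
    """
    lines = text.splitlines()
    header_order = None
    header_idx = None
    for idx, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(t in AA_INDEX for t in tokens[:20]):
            header_order = tokens
            header_idx = idx
            break
    if header_order is None:
        raise ProfileError("no amino-acid header line found in PSSM text")
    # first 20 header letters give the log-odds column order; a 40-letter
    # header repeats the order for the frequency block
    logodds_order = header_order[:20]
    freq_order = header_order[20:40] if len(header_order) >= 40 else logodds_order

    score_rows, freq_rows, seq = [], [], []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            continue
        if not tokens[0].isdigit():
            break  # trailing statistics block
        if len(tokens) < 22:
            raise ProfileError(f"line {lineno}: truncated PSSM row")
        aa = tokens[1]
        try:
            scores = [float(t) for t in tokens[2:22]]
            freqs = [float(t) for t in tokens[22:42]] if len(tokens) >= 42 else None
        except ValueError as exc:
            raise ProfileError(f"line {lineno}: bad numeric field ({exc})")
        seq.append(aa)
        score_rows.append(scores)
        freq_rows.append(freqs)

    if not score_rows:
        raise ProfileError("no PSSM data rows found")
    sequence = "".join(seq)

    if use_frequencies:
        if any(f is None for f in freq_rows):
            raise ProfileError("file has no percent-frequency block")
        w = np.array(freq_rows) / 100.0
        w = _remap_columns(w, freq_order)
        sums = w.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ProfileError("zero-sum frequency row")
        return FrequencyProfile(w / sums), sequence

    scores = _remap_columns(np.array(score_rows), logodds_order)
    return PSSM(scores, source="parsed"), sequence


def _remap_columns(matrix: np.ndarray, order) -> np.ndarray:
    out = np.empty_like(matrix)
    for src_col, aa in enumerate(order):
        out[:, AA_INDEX[aa]] = matrix[:, src_col]
    return out


def write_psiblast_pssm(pssm: PSSM, sequence: str) -> str:
    """Write a PSSM in the PSI-BLAST ASCII layout (log-odds block only,
    internal alphabet order); round-trips through :func:`parse_psiblast_pssm`."""
    if pssm.length != len(sequence):
        raise ProfileError("sequence length must match PSSM length")
    out = ["", "Last position-specific scoring matrix computed",
           "            " + "  ".join(ALPHABET) + "   " + "  ".join(ALPHABET)]
    for i, aa in enumerate(sequence):
        scores = " ".join(f"{v:6.2f}" for v in pssm.scores[i])
        freqs = " ".join("0.00" for _ in range(20))
        out.append(f"{i + 1:5d} {aa} {scores} {freqs}")
    out.append("")
    return "\n".join(out)
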