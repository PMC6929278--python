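"""Local per-residue feature extractors.

Two complementary views of a residue's neighbourhood are summarised by
block-wise means over profile rows:

* **MLAB** (multi-scale local average block) works on the *sequential*
  window: the residue R plus its five predecessors and five successors in
  chain order (11 slots, clipped at termini).
* **Hexagon** features work on the *spatial* window: R plus its six hexagon
  sector neighbours (nearest non-local Calpha per 60-degree wedge around
  the residue-local y-axis).

In both cases the window rows are grouped into six overlapping blocks — a
global zone (A), a bisection (B, C) and a trichotomy (D, E, F) — and each
block contributes the per-column mean of its *present* rows, giving a fixed
6 x ncols feature vector (120 components for a 20-column profile).  Blocks
with no present rows are zero-filled and flagged, keeping dimensionality
constant for the downstream regression stage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import numpy as np

from .residue_profiles import NormalizedPSSM
from .structure_model import (
    FrameError,
    Residue,
    Structure,
    hexagon_neighbors,
)

__all__ = [
    "BlockScheme",
    "SequentialWindow",
    "HexagonWindow",
    "MlabFeatureVector",
    "HexagonFeatureVector",
    "DEFAULT_SEQUENTIAL_SCHEME",
    "DEFAULT_HEXAGON_SCHEME",
    "sequential_window",
    "mlab_features",
    "hexagon_window",
    "hexagon_features",
]

BLOCK_LABELS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class BlockScheme:
    """Assignment of window slots to the six blocks A..F.

    A must cover all slots; B and C together must cover all slots; D, E and
    F together must cover all slots except (optionally) a designated
    ``center`` slot, so a trichotomy of pure neighbour slots around a target
    is admissible.  Blocks may overlap.  The scheme is serialised with any
    trained model via :meth:`fingerprint`.
    """

    blocks: Mapping[str, FrozenSet[int]]
    n_slots: int
    center: Optional[int] = None

    def __post_init__(self):
        blocks = {k: frozenset(v) for k, v in self.blocks.items()}
        if set(blocks) != set(BLOCK_LABELS):
            raise ValueError(f"scheme must define exactly blocks {BLOCK_LABELS}")
        universe = set(range(self.n_slots))
        for label, slots in blocks.items():
            if not slots <= universe:
                raise ValueError(f"block {label} references slots outside the window")
        if blocks["A"] != frozenset(universe):
            raise ValueError("block A must cover every slot")
        if blocks["B"] | blocks["C"] != frozenset(universe):
            raise ValueError("blocks B and C must cover every slot")
        tri_universe = universe - ({self.center} if self.center is not None else set())
        if not blocks["D"] | blocks["E"] | blocks["F"] >= tri_universe:
            raise ValueError("blocks D, E, F must cover every non-center slot")
        object.__setattr__(self, "blocks", blocks)

    def slots(self, label: str) -> FrozenSet[int]:
        return self.blocks[label]

    def fingerprint(self) -> str:
        desc = ";".join(
            f"{label}:{','.join(map(str, sorted(self.blocks[label])))}"
            for label in BLOCK_LABELS
        )
        return hashlib.sha256(
            f"{self.n_slots}|{self.center}|{desc}".encode()
        ).hexdigest()[:16]


# Sequential window slots are 0..10 for R-5 .. R .. R+5 (centre slot 5).
# B runs up to and including R, C from R onward (they overlap at R);
# D/E/F split the window into near-equal disjoint thirds.
DEFAULT_SEQUENTIAL_SCHEME = BlockScheme(
    blocks={
        "A": frozenset(range(11)),
        "B": frozenset(range(0, 6)),
        "C": frozenset(range(5, 11)),
        "D": frozenset(range(0, 4)),
        "E": frozenset(range(4, 8)),
        "F": frozenset(range(8, 11)),
    },
    n_slots=11,
)

# Hexagon window slots: 0 = target residue, 1..6 = sector neighbours.
# B/C are the two half-spaces (each including the target), D/E/F pair up
# adjacent sectors (target exempt from the trichotomy).
DEFAULT_HEXAGON_SCHEME = BlockScheme(
    blocks={
        "A": frozenset(range(7)),
        "B": frozenset({0, 1, 2, 3}),
        "C": frozenset({0, 4, 5, 6}),
        "D": frozenset({1, 2}),
        "E": frozenset({3, 4}),
        "F": frozenset({5, 6}),
    },
    n_slots=7,
    center=0,
)


@dataclass
class SequentialWindow:
    """Profile rows for slots R-5..R+5; absent slots only at chain termini."""

    rows: np.ndarray          # n_slots x ncols, absent rows zeroed
    present: np.ndarray       # n_slots bools
    center: int = 5

    def __post_init__(self):
        if not self.present[self.center]:
            raise ValueError("window centre must be present")


@dataclass
class HexagonWindow:
    """Profile rows for the target (slot 0) and sector neighbours (1..6)."""

    rows: np.ndarray
    present: np.ndarray
    valid: bool = True        # False when the residue frame failed

    def __post_init__(self):
        if self.valid and not self.present[0]:
            raise ValueError("target row must be present in a valid window")


@dataclass
class MlabFeatureVector:
    values: np.ndarray            # 6 * ncols, block-major (A..F)
    block_counts: Dict[str, int]
    empty_blocks: Tuple[str, ...] = ()


@dataclass
class HexagonFeatureVector:
    values: np.ndarray
    block_counts: Dict[str, int]
    empty_blocks: Tuple[str, ...] = ()
    valid: bool = True


def sequential_window(profile: NormalizedPSSM, i: int) -> SequentialWindow:
    """Window of profile rows i-5..i+5 (1-based i), clipped to the chain."""
    L = profile.length
    if not 1 <= i <= L:
        raise IndexError(f"position {i} outside 1..{L}")
    ncols = profile.scores.shape[1]
    rows = np.zeros((11, ncols))
    present = np.zeros(11, dtype=bool)
    for slot, pos in enumerate(range(i - 5, i + 6)):
        if 1 <= pos <= L:
            rows[slot] = profile.scores[pos - 1]
            present[slot] = True
    return SequentialWindow(rows=rows, present=present)


def _block_means(
    rows: np.ndarray, present: np.ndarray, scheme: BlockScheme
) -> Tuple[np.ndarray, Dict[str, int], Tuple[str, ...]]:
    ncols = rows.shape[1]
    out = np.zeros((len(BLOCK_LABELS), ncols))
    counts: Dict[str, int] = {}
    empty: List[str] = []
    for b, label in enumerate(BLOCK_LABELS):
        idx = [s for s in sorted(scheme.slots(label)) if present[s]]
        counts[label] = len(idx)
        if idx:
            out[b] = rows[idx].mean(axis=0)
        else:
            empty.append(label)
    return out.ravel(), counts, tuple(empty)


def mlab_features(
    window: SequentialWindow, scheme: BlockScheme = DEFAULT_SEQUENTIAL_SCHEME
) -> MlabFeatureVector:
    """Block means over the sequential window (mean of present rows per block)."""
    if scheme.n_slots != window.rows.shape[0]:
        raise ValueError("scheme slot count does not match window")
    values, counts, empty = _block_means(window.rows, window.present, scheme)
    return MlabFeatureVector(values=values, block_counts=counts, empty_blocks=empty)


def hexagon_window(
    structure: Structure,
    profiles: Mapping[str, NormalizedPSSM],
    residue: Residue,
    cutoff: float = 10.0,
    min_seq_sep: int = 4,
    cross_chain: bool = True,
) -> HexagonWindow:
    """Spatial window: the target's profile row plus one row per hexagon sector.

    ``profiles`` maps chain id to that chain's normalised profile; each
    neighbour contributes the profile row of its own sequence position.
    If the residue frame cannot be built (missing backbone, collinear
    geometry) an invalid all-absent window is returned rather than raising,
    so chain breaks degrade to flagged zero features.
    """
    profile = profiles[residue.chain_id]
    ncols = profile.scores.shape[1]
    rows = np.zeros((7, ncols))
    present = np.zeros(7, dtype=bool)
    try:
        neighbors = hexagon_neighbors(
            structure, residue, cutoff=cutoff,
            min_seq_sep=min_seq_sep, cross_chain=cross_chain,
        )
    except FrameError:
        return HexagonWindow(rows=rows, present=present, valid=False)
    rows[0] = profile.row(residue.seq_index)
    present[0] = True
    for sector, nb in enumerate(neighbors, start=1):
        if nb is None:
            continue
        nb_profile = profiles.get(nb.chain_id)
        if nb_profile is None:
            continue
        rows[sector] = nb_profile.row(nb.seq_index)
        present[sector] = True
    return HexagonWindow(rows=rows, present=present, valid=True)


def hexagon_features(
    window: HexagonWindow, scheme: BlockScheme = DEFAULT_HEXAGON_SCHEME
) -> HexagonFeatureVector:
    """Block means over the spatial window; an invalid window gives zeros."""
    if scheme.n_slots != window.rows.shape[0]:
        raise ValueError("scheme slot count does not match window")
    if not window.valid:
        ncols = window.rows.shape[1]
        return HexagonFeatureVector(
            values=np.zeros(6 * ncols),
            block_counts={label: 0 for label in BLOCK_LABELS},
            empty_blocks=BLOCK_LABELS,
            valid=False,
        )
    values, counts, empty = _block_means(window.rows, window.present, scheme)
    return HexagonFeatureVector(
        values=values, block_counts=counts, empty_blocks=empty, valid=True
    )
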