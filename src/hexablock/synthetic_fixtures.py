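"""Deterministic, seeded generators for toy complexes, decoy ladders and
synthetic sequence profiles.

Everything the pipeline consumes — structures, docking decoys with known
interface-RMSD labels, and per-chain profiles — can be generated here, so
every stage is testable without external databases.  All generators are
pure functions of their arguments and a single seed; per-generator random
streams are derived by stable hashing of ``(seed, generator name, index)``
so adding a generator never shifts another's draws.

The geometry is idealised: chains are poly-residue helices or strands with
backbone plus Cbeta atoms placed from fixed internal coordinates (helix:
2.3 A radius, 1.5 A rise and 100 degrees twist per residue, giving the
canonical ~3.8 A Calpha-Calpha virtual bond; strand: extended zigzag with
3.3 A rise).  Side chains beyond Cbeta, clash relaxation and sequence
design are deliberately out of scope.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .capri_metrics import CapriScore, score_pose
from .residue_profiles import (
    ALPHABET,
    FrequencyProfile,
    NormalizedPSSM,
    build_pssm,
    minmax_normalize,
)
from .structure_model import (
    Atom,
    Chain,
    Residue,
    RigidTransform,
    Structure,
    apply_transform,
    contact_pairs,
    ONE_TO_THREE,
)

__all__ = [
    "FixtureSpec",
    "HELIX_CA_RISE",
    "derive_seed",
    "make_ideal_chain",
    "make_toy_complex",
    "make_decoy_ladder",
    "make_synthetic_profile",
    "DEFAULT_MAGNITUDES",
]

# Helix parameters: radius (A), twist per residue (deg), rise per residue (A).
_HELIX_RADIUS = 2.3
_HELIX_TWIST = 100.0
_HELIX_RISE = 1.5
# Resulting ideal Calpha-Calpha distance between consecutive residues.
HELIX_CA_RISE = math.sqrt(
    (2 * _HELIX_RADIUS * math.sin(math.radians(_HELIX_TWIST / 2))) ** 2 + _HELIX_RISE**2
)

_STRAND_RISE = 3.3
_STRAND_WOBBLE = 0.9

# Default decoy-ladder perturbation magnitudes (rotation deg, translation A):
# spans near-native through clearly-incorrect CAPRI classes.
DEFAULT_MAGNITUDES: Tuple[Tuple[float, float], ...] = (
    (1.0, 0.5),
    (2.0, 1.0),
    (5.0, 2.0),
    (10.0, 4.0),
    (20.0, 8.0),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic two-chain complex and its decoy set."""

    chain_lengths: Tuple[int, int] = (30, 30)
    contact_distance: float = 4.0
    decoy_count: int = 20
    magnitudes: Tuple[Tuple[float, float], ...] = DEFAULT_MAGNITUDES
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.chain_lengths):
            raise ValueError("chain lengths must be >= 1")
        if self.contact_distance <= 0:
            raise ValueError("contact distance must be positive")
        if any(deg < 0 or trans < 0 for deg, trans in self.magnitudes):
            raise ValueError("perturbation magnitudes must be >= 0")


def derive_seed(seed: int, name: str, index: int = 0) -> int:
    """Stable sub-seed below 2**31 from (seed, generator name, call index)."""
    digest = hashlib.sha256(f"{seed}:{name}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_ideal_chain(n: int, geometry: str = "helix", chain_id: str = "A") -> Chain:
    """Build an n-residue chain with ideal backbone + Cbeta geometry.

    Residue types cycle deterministically through the 20-letter alphabet.
    No randomness is involved: two calls with the same arguments are
    bit-identical.
    """
    if n < 1:
        raise ValueError("chain must have at least one residue")
    if geometry not in ("helix", "strand"):
        raise ValueError(f"unknown geometry {geometry!r}")

    ca_positions = np.empty((n, 3))
    for i in range(n):
        if geometry == "helix":
            theta = math.radians(_HELIX_TWIST * i)
            ca_positions[i] = (
                _HELIX_RADIUS * math.cos(theta),
                _HELIX_RADIUS * math.sin(theta),
                _HELIX_RISE * i,
            )
        else:
            ca_positions[i] = (0.9 * (-1) ** i, _STRAND_WOBBLE * (-1) ** i * 0.3, _STRAND_RISE * i)

    residues: List[Residue] = []
    for i in range(n):
        ca = ca_positions[i]
        # local frame along the chain axis: t = direction to next CA (or from
        # previous at the C-terminus), r = outward radial-ish direction
        if i + 1 < n:
            t = ca_positions[i + 1] - ca
        else:
            t = ca - ca_positions[i - 1] if n > 1 else np.array([0.0, 0.0, 1.0])
        t = t / np.linalg.norm(t)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(t @ ref) > 0.95:
            ref = np.array([0.0, 1.0, 0.0])
        r = ref - (ref @ t) * t
        r = r / np.linalg.norm(r)
        s = np.cross(t, r)
        # fixed internal offsets (A) in the (t, r, s) frame; N/CA/C/CB are
        # mutually non-collinear so residue frames are always constructible
        offsets = {
            "N": -1.20 * t + 0.80 * r,
            "CA": np.zeros(3),
            "C": 1.25 * t + 0.60 * r,
            "O": 1.60 * t + 1.60 * r + 0.40 * s,
            "CB": 0.40 * t - 1.00 * r + 1.10 * s,
        }
        aa = ALPHABET[i % 20]
        atoms = [
            Atom(name, name[0], ca + off) for name, off in offsets.items()
        ]
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_index=i + 1,
                res_type=ONE_TO_THREE[aa],
                atoms=atoms,
                resseq=i + 1,
            )
        )
    return Chain(chain_id, residues)


def _min_inter_distance(a: Chain, b: Chain, offset: np.ndarray) -> float:
    pa = np.concatenate([r.coords() for r in a.residues])
    pb = np.concatenate([r.coords() for r in b.residues]) + offset
    from scipy.spatial.distance import cdist

    return float(cdist(pa, pb).min())


def make_toy_complex(spec: FixtureSpec) -> Structure:
    """Two ideal helices (chains A and B) with the closest inter-unit atom
    distance tuned to ``spec.contact_distance`` within 0.01 A by bisection
    along the x-axis."""
    n1, n2 = spec.chain_lengths
    a = make_ideal_chain(n1, "helix", "A")
    b = make_ideal_chain(n2, "helix", "B")

    lo, hi = 0.0, 200.0
    if _min_inter_distance(a, b, np.array([lo, 0, 0])) > spec.contact_distance:
        raise ValueError("placement infeasible: chains too far apart at zero offset")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        d = _min_inter_distance(a, b, np.array([mid, 0, 0]))
        if d < spec.contact_distance:
            lo = mid
        else:
            hi = mid
    offset = np.array([0.5 * (lo + hi), 0.0, 0.0])
    for res in b.residues:
        res.atoms = [Atom(at.name, at.element, at.coord + offset) for at in res.atoms]
    return Structure([a, b], receptor_ids={"A"}, ligand_ids={"B"})


def _random_pose_transform(
    rng: np.random.Generator, degrees: float, translation: float, center: np.ndarray
) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(math.radians(degrees) * axis).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    # rotate about the ligand centroid, then translate
    t = center - R @ center + translation * direction
    return RigidTransform(R, t)


def make_decoy_ladder(
    native: Structure,
    magnitudes: Sequence[Tuple[float, float]] = DEFAULT_MAGNITUDES,
    n_per_magnitude: int = 20,
    seed: int = 0,
    contact_cutoff: float = 6.0,
) -> List[Tuple[str, Structure, CapriScore]]:
    """Seeded decoys at increasing perturbation magnitude, with true labels.

    Each decoy perturbs the ligand unit by a rotation of exactly the given
    angle about a uniformly random axis through the ligand centroid, plus a
    translation of exactly the given norm in a uniformly random direction.
    Labels are computed against the native complex on the fly.
    """
    if not contact_pairs(native, cutoff=contact_cutoff).pairs:
        raise ValueError("native complex has no interface to perturb")
    lig_coords = np.concatenate(
        [r.coords() for r in native.unit_residues("ligand")]
    )
    center = lig_coords.mean(axis=0)
    decoys: List[Tuple[str, Structure, CapriScore]] = []
    for m_idx, (degrees, translation) in enumerate(magnitudes):
        rng = np.random.default_rng(derive_seed(seed, "decoy_ladder", m_idx))
        for d_idx in range(n_per_magnitude):
            if degrees == 0 and translation == 0:
                t = RigidTransform.identity()
            else:
                t = _random_pose_transform(rng, degrees, translation, center)
            pose = apply_transform(native, t, unit="ligand")
            label = score_pose(pose, native, contact_cutoff=contact_cutoff)
            decoys.append((f"m{m_idx}_d{d_idx}", pose, label))
    return decoys


def make_synthetic_profile(
    L: int, seed: int = 0, sharpness: float = 2.0
) -> Tuple[FrequencyProfile, NormalizedPSSM]:
    """Seeded per-position frequency profile and its derived normalised PSSM.

    Rows are symmetric Dirichlet draws with concentration ``1/sharpness``
    (larger sharpness -> peakier, more conserved-looking positions).  The
    PSSM is the profile projected through the packaged substitution matrix
    and min-max normalised to [0, 1].
    """
    if L < 1:
        raise ValueError("profile length must be >= 1")
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    rng = np.random.default_rng(derive_seed(seed, "synthetic_profile"))
    omega = rng.dirichlet(np.full(20, 1.0 / sharpness), size=L)
    profile = FrequencyProfile(omega)
    pssm = minmax_normalize(build_pssm(profile))
    return profile, pssm
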