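"""Hierarchical 3D model of a two-unit protein complex, PDB I/O and geometry.

The model is deliberately minimal: a :class:`Structure` holds an ordered list
of chains partitioned into a *receptor* unit and a *ligand* unit; residues
carry both their author numbering (``resseq``/``icode``, used for reporting
and for matching a pose against a native complex) and a 1-based sequential
position in the chain (``seq_index``, used for sequence-locality tests and
for indexing profile rows).

Geometry operations provided here:

* residue-residue contact detection under a strict distance cutoff
  (default 6 A, the interface-residue rule),
* a residue-local orthonormal frame (Calpha at the origin, Cbeta on +y,
  N in the x-y half-plane with x > 0),
* hexagon spatial neighbour search (six 60-degree azimuthal sectors about
  the frame's y-axis, nearest non-local Calpha per sector),
* least-squares rigid superposition (Kabsch, proper rotations only),
* rigid-transform application to one unit (realising a docking pose).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "RigidTransform",
    "ContactSet",
    "Frame",
    "ResidueKey",
    "StructureError",
    "FrameError",
    "read_pdb",
    "write_pdb",
    "contact_pairs",
    "interface_residues",
    "residue_frame",
    "hexagon_neighbors",
    "superpose",
    "apply_transform",
    "virtual_cbeta",
]

# 3-letter <-> 1-letter codes for the 20 standard amino acids
THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_NAMES = ("N", "CA", "C", "O")


class StructureError(ValueError):
    """Raised for malformed structures, bad configuration or parse failures."""


class FrameError(StructureError):
    """Raised when a residue-local frame cannot be constructed."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single atom: PDB atom label, element symbol and coordinates in A."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coord, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(f"atom {self.name}: coord must be a finite 3-vector")
        object.__setattr__(self, "coord", c)


# Stable identifier for a residue across structures sharing author numbering.
ResidueKey = Tuple[str, int, str]  # (chain_id, resseq, icode)


@dataclass
class Residue:
    """One amino-acid residue.

    ``seq_index`` is the 1-based position in the chain (sequential numbering
    used for locality and profile lookups); ``resseq``/``icode`` carry the
    author numbering from the PDB file.
    """

    chain_id: str
    seq_index: int
    res_type: str  # 3-letter code, one of the 20 standard types
    atoms: List[Atom] = field(default_factory=list)
    resseq: Optional[int] = None
    icode: str = ""

    def __post_init__(self):
        if self.seq_index < 1:
            raise StructureError("seq_index must be >= 1")
        if self.res_type not in THREE_TO_ONE:
            raise StructureError(f"non-standard residue type {self.res_type!r}")
        if self.resseq is None:
            self.resseq = self.seq_index
        seen: Set[str] = set()
        for a in self.atoms:
            if a.name in BACKBONE_NAMES + ("CB",):
                if a.name in seen:
                    raise StructureError(
                        f"residue {self.chain_id}{self.resseq}: duplicate atom {a.name}"
                    )
                seen.add(a.name)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.res_type]

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.resseq, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Chain:
    id: str
    residues: List[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """A complex partitioned into a receptor unit and a ligand unit."""

    chains: List[Chain]
    receptor_ids: frozenset
    ligand_ids: frozenset

    def __post_init__(self):
        self.receptor_ids = frozenset(self.receptor_ids)
        self.ligand_ids = frozenset(self.ligand_ids)
        ids = {c.id for c in self.chains}
        if self.receptor_ids & self.ligand_ids:
            raise StructureError("receptor and ligand chain ids overlap")
        if not self.receptor_ids or not self.ligand_ids:
            raise StructureError("both units must be non-empty")
        missing = (self.receptor_ids | self.ligand_ids) - ids
        if missing:
            raise StructureError(f"unknown chain id(s): {sorted(missing)}")
        if ids - (self.receptor_ids | self.ligand_ids):
            extra = ids - (self.receptor_ids | self.ligand_ids)
            raise StructureError(f"chain(s) not assigned to a unit: {sorted(extra)}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise StructureError(f"no chain {chain_id!r}")

    def unit_residues(self, unit: str) -> List[Residue]:
        ids = self.receptor_ids if unit == "receptor" else self.ligand_ids
        return [r for c in self.chains if c.id in ids for r in c.residues]

    def all_residues(self) -> List[Residue]:
        return [r for c in self.chains for r in c.residues]

    def residue(self, key: ResidueKey) -> Optional[Residue]:
        for c in self.chains:
            if c.id != key[0]:
                continue
            for r in c.residues:
                if r.resseq == key[1] and r.icode == key[2]:
                    return r
        return None

    def copy(self) -> "Structure":
        chains = [
            Chain(c.id, [replace(r, atoms=list(r.atoms)) for r in c.residues])
            for c in self.chains
        ]
        return Structure(chains, self.receptor_ids, self.ligand_ids)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise StructureError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise StructureError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise StructureError("rotation must be proper (det=+1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


@dataclass
class ContactSet:
    """Inter-unit residue contacts: (receptor key, ligand key) -> min distance."""

    pairs: Dict[Tuple[ResidueKey, ResidueKey], float]
    cutoff: float

    def __post_init__(self):
        for pair, d in self.pairs.items():
            if not d < self.cutoff:
                raise StructureError(f"pair {pair}: distance {d} not below cutoff")

    def residue_pairs(self) -> Set[Tuple[ResidueKey, ResidueKey]]:
        return set(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Frame:
    """Residue-local orthonormal frame; ``axes`` rows are the x, y, z axes."""

    origin: np.ndarray
    axes: np.ndarray

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.origin) @ self.axes.T

    def from_frame(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.axes + self.origin


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(text: str, receptor_ids: Iterable[str], ligand_ids: Iterable[str]) -> Structure:
    """Parse PDB-format text into a two-unit :class:`Structure`.

    Only ATOM records of standard amino acids are kept (HETATM and waters are
    dropped).  Alternate locations are resolved to the highest-occupancy
    conformer, ties broken by altloc label order.  Residues keep file order;
    ``seq_index`` is assigned sequentially per chain.
    """
    receptor_ids = frozenset(receptor_ids)
    ligand_ids = frozenset(ligand_ids)
    parser = PDBParser(QUIET=True)
    model = None
    bio = parser.get_structure("s", io.StringIO(text))
    for model in bio:
        break  # first model only
    if model is None:
        raise StructureError("no ATOM records found")

    chains: List[Chain] = []
    for bio_chain in model:
        residues: List[Residue] = []
        for res in bio_chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():  # HETATM / water
                continue
            if res.get_resname() not in THREE_TO_ONE:
                continue
            atoms: List[Atom] = []
            for at in res:
                if at.is_disordered():
                    alts = sorted(
                        at.disordered_get_list(),
                        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                    )
                    chosen = alts[0]
                else:
                    chosen = at
                atoms.append(
                    Atom(chosen.get_id(), (chosen.element or "").strip() or chosen.get_id()[0],
                         np.array(chosen.get_coord(), dtype=float))
                )
            if atoms:
                residues.append(
                    Residue(
                        chain_id=bio_chain.id,
                        seq_index=len(residues) + 1,
                        res_type=res.get_resname(),
                        atoms=atoms,
                        resseq=resseq,
                        icode=icode.strip(),
                    )
                )
        if residues:
            chains.append(Chain(bio_chain.id, residues))

    if not chains or not any(c.residues for c in chains):
        raise StructureError("no ATOM records found")
    present = {c.id for c in chains}
    missing = (receptor_ids | ligand_ids) - present
    if missing:
        raise StructureError(f"unknown chain id(s): {sorted(missing)}")
    chains = [c for c in chains if c.id in receptor_ids | ligand_ids]
    return Structure(chains, receptor_ids, ligand_ids)


def write_pdb(structure: Structure) -> str:
    """Serialise a Structure back to minimal ATOM/TER records."""
    lines: List[str] = []
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                name = atom.name
                # PDB atom-name column convention: element-aligned for short names
                padded = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:>5d} {padded}{'':1s}{res.res_type:>3s} "
                    f"{chain.id:1s}{res.resseq:>4d}{res.icode or ' ':1s}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}      {chain.residues[-1].res_type:>3s} "
                     f"{chain.id:1s}{chain.residues[-1].resseq:>4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_pairs(structure: Structure, cutoff: float = 6.0) -> ContactSet:
    """All inter-unit residue pairs whose minimum atom-atom distance is < cutoff.

    The inequality is strict: a pair at exactly the cutoff is not a contact.
    """
    rec = structure.unit_residues("receptor")
    lig = structure.unit_residues("ligand")
    if not any(r.atoms for r in rec) or not any(r.atoms for r in lig):
        raise StructureError("both units need at least one residue with atoms")

    rec_coords, rec_owner = _flatten(rec)
    lig_coords, lig_owner = _flatten(lig)
    tree = cKDTree(lig_coords)
    pairs: Dict[Tuple[ResidueKey, ResidueKey], float] = {}
    neighbours = tree.query_ball_point(rec_coords, r=cutoff)
    for i, hits in enumerate(neighbours):
        if not hits:
            continue
        rkey = rec[rec_owner[i]].key
        for j in hits:
            d = float(np.linalg.norm(rec_coords[i] - lig_coords[j]))
            if d >= cutoff:
                continue
            lkey = lig[lig_owner[j]].key
            prev = pairs.get((rkey, lkey))
            if prev is None or d < prev:
                pairs[(rkey, lkey)] = d
    return ContactSet(pairs, cutoff)


def _flatten(residues: Sequence[Residue]) -> Tuple[np.ndarray, np.ndarray]:
    coords = []
    owner = []
    for idx, r in enumerate(residues):
        for a in r.atoms:
            coords.append(a.coord)
            owner.append(idx)
    return np.array(coords), np.array(owner)


def interface_residues(contacts: ContactSet) -> Tuple[Set[ResidueKey], Set[ResidueKey]]:
    """Residues appearing in at least one contact pair, per unit."""
    rec = {p[0] for p in contacts.pairs}
    lig = {p[1] for p in contacts.pairs}
    return rec, lig


# ---------------------------------------------------------------------------
# residue frames and hexagon neighbours
# ---------------------------------------------------------------------------

# Ideal tetrahedral Cbeta: bond length and the N-CA-CB / C-CA-CB angle.
CB_BOND_LENGTH = 1.53
CB_ANGLE_DEG = 110.5


def virtual_cbeta(residue: Residue) -> np.ndarray:
    """Place an ideal Cbeta from N, CA, C (glycine or missing side chain).

    The direction is the combination a*d + b*p of the inverted N/C bisector d
    and the N x C normal p (unit vectors in the CA-centred frame), with a
    fixed by the 110.5-degree bond angle and the sign of b chosen to give
    L-amino-acid chirality.
    """
    n, ca, c = residue.atom("N"), residue.atom("CA"), residue.atom("C")
    if n is None or ca is None or c is None:
        raise FrameError(
            f"residue {residue.chain_id}{residue.resseq}: need N, CA, C for virtual CB"
        )
    u1 = _unit(n.coord - ca.coord, "N-CA")
    u2 = _unit(c.coord - ca.coord, "C-CA")
    bis = u1 + u2
    nb = np.linalg.norm(bis)
    if nb < 1e-6:
        raise FrameError("N, CA, C nearly collinear; cannot place virtual CB")
    d = -bis / nb
    p = np.cross(u2, u1)
    npn = np.linalg.norm(p)
    if npn < 1e-6:
        raise FrameError("N, CA, C nearly collinear; cannot place virtual CB")
    p = p / npn
    a = math.cos(math.radians(CB_ANGLE_DEG)) / float(d @ u1)
    a = min(max(a, -1.0), 1.0)
    b = math.sqrt(max(0.0, 1.0 - a * a))
    direction = a * d + b * p
    return ca.coord + CB_BOND_LENGTH * direction / np.linalg.norm(direction)


def _unit(v: np.ndarray, label: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise FrameError(f"zero-length vector {label}")
    return v / n


def residue_frame(residue: Residue) -> Frame:
    """Local orthonormal frame: CA origin, CB on +y, N in the x-y plane (x>0)."""
    ca = residue.atom("CA")
    n = residue.atom("N")
    if ca is None or n is None:
        raise FrameError(
            f"residue {residue.chain_id}{residue.resseq}: missing CA or N"
        )
    cb_atom = residue.atom("CB")
    cb = cb_atom.coord if cb_atom is not None else virtual_cbeta(residue)

    y = _unit(cb - ca.coord, "CB-CA")
    nv = n.coord - ca.coord
    x = nv - (nv @ y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-6:
        raise FrameError(
            f"residue {residue.chain_id}{residue.resseq}: CA, CB, N are collinear"
        )
    x = x / nx
    z = np.cross(x, y)
    return Frame(origin=ca.coord.copy(), axes=np.array([x, y, z]))


def hexagon_neighbors(
    structure: Structure,
    residue: Residue,
    cutoff: float = 10.0,
    min_seq_sep: int = 4,
    cross_chain: bool = True,
) -> List[Optional[Residue]]:
    """Nearest non-local Calpha per azimuthal sector around ``residue``.

    The frame's x-z plane is divided into six 60-degree wedges; sector s
    (1-based) covers azimuths [60(s-1), 60 s) measured from +x toward +z.
    A candidate is *local* (excluded) when on the same chain with
    ``|delta seq_index| < min_seq_sep``; candidates on another chain are
    always eligible when ``cross_chain`` is true, never otherwise.
    Returns a 6-slot list (sector 1 at index 0), None for empty sectors.
    """
    frame = residue_frame(residue)
    best: List[Optional[Residue]] = [None] * 6
    best_d = [math.inf] * 6
    for other in structure.all_residues():
        if other is residue:
            continue
        if other.chain_id == residue.chain_id:
            if abs(other.seq_index - residue.seq_index) < min_seq_sep:
                continue
        elif not cross_chain:
            continue
        ca = other.atom("CA")
        if ca is None:
            continue
        d = float(np.linalg.norm(ca.coord - frame.origin))
        if not d < cutoff:
            continue
        local = frame.to_frame(ca.coord)
        az = math.degrees(math.atan2(local[2], local[0])) % 360.0
        sector = min(int(az // 60.0), 5)
        if d < best_d[sector]:
            best_d[sector] = d
            best[sector] = other
    return best


# ---------------------------------------------------------------------------
# superposition and transforms
# ---------------------------------------------------------------------------

def superpose(moving: np.ndarray, fixed: np.ndarray) -> Tuple[RigidTransform, float]:
    """Optimal proper-rigid superposition of ``moving`` onto ``fixed`` (Kabsch).

    Returns the transform t with t(moving) ~= fixed and the residual RMSD.
    Requires >= 3 non-collinear points on each side.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise StructureError("point sets must be matching n x 3 arrays")
    n = moving.shape[0]
    if n < 3:
        raise StructureError("need at least 3 points to superpose")
    cm, cf = moving.mean(axis=0), fixed.mean(axis=0)
    mv, fx = moving - cm, fixed - cf
    for pts, name in ((mv, "moving"), (fx, "fixed")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] < 1e-9 * max(1.0, s[0]):
            raise StructureError(f"{name} point cloud is degenerate (collinear)")
    rot, _ = Rotation.align_vectors(fx, mv)
    R = rot.as_matrix()
    transform = RigidTransform(R, cf - R @ cm)
    resid = mv @ R.T - fx
    rmsd = math.sqrt(float(np.mean(np.sum(resid * resid, axis=1))))
    return transform, rmsd


def apply_transform(structure: Structure, t: RigidTransform, unit: str = "ligand") -> Structure:
    """Return a copy with the given unit's coordinates moved by ``t``."""
    if unit not in ("receptor", "ligand"):
        raise StructureError(f"unknown unit {unit!r}")
    ids = structure.receptor_ids if unit == "receptor" else structure.ligand_ids
    new = structure.copy()
    for chain in new.chains:
        if chain.id not in ids:
            continue
        for res in chain.residues:
            res.atoms = [
                Atom(a.name, a.element, t.apply(a.coord)) for a in res.atoms
            ]
    return new
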