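"""CAPRI-style evaluation of a predicted pose against a native complex.

Three measures are computed from residue-residue contacts under a strict
6 A minimum-atom-distance rule:

* ``fnat`` — fraction of the native complex's contacts recovered by the pose,
* ``fnonnat`` — fraction of the pose's contacts that are not native
  (undefined when the pose has no contacts at all),
* ``irmsd`` — RMSD over the backbone atoms (N, CA, C, O) of the *native*
  interface residues after optimal rigid superposition of the two interfaces.

The (fnat, irmsd) pair maps to a quality class.  The printed CAPRI band
definitions are mutually exclusive on both measures and leave gaps; the
default semantics therefore treat the fnat thresholds as lower bounds
(>=10/>=30/>=50 %) and assign the best class whose irmsd band is met, which
makes the classification total and monotone.  ``strict_verbatim=True``
reproduces the printed bands exactly and yields ``UNCLASSIFIED`` for gaps.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structure_model import (
    BACKBONE_NAMES,
    ContactSet,
    Structure,
    StructureError,
    contact_pairs,
    interface_residues,
    superpose,
)

__all__ = ["Quality", "CapriScore", "fnat", "fnonnat", "irmsd", "quality_class", "score_pose"]


class Quality(enum.Enum):
    INCORRECT = "Incorrect"
    ACCEPTABLE = "Acceptable"
    MEDIUM = "Medium"
    HIGH = "High"
    UNCLASSIFIED = "Unclassified"  # strict-verbatim gaps only

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class CapriScore:
    fnat: float
    fnonnat: Optional[float]  # None when the pose has no contacts
    irmsd: float
    quality: Quality

    def __post_init__(self):
        if not 0.0 <= self.fnat <= 1.0:
            raise ValueError("fnat must lie in [0, 1]")
        if self.fnonnat is not None and not 0.0 <= self.fnonnat <= 1.0:
            raise ValueError("fnonnat must lie in [0, 1]")
        if self.irmsd < 0:
            raise ValueError("irmsd must be non-negative")


def fnat(predicted: ContactSet, native: ContactSet) -> float:
    """|predicted ∩ native| / |native|, by residue-pair identity."""
    native_pairs = native.residue_pairs()
    if not native_pairs:
        raise ValueError("native complex has no contacts")
    return len(predicted.residue_pairs() & native_pairs) / len(native_pairs)


def fnonnat(predicted: ContactSet, native: ContactSet) -> Optional[float]:
    """|predicted \\ native| / |predicted|; None when predicted is empty."""
    pred_pairs = predicted.residue_pairs()
    if not pred_pairs:
        return None
    return len(pred_pairs - native.residue_pairs()) / len(pred_pairs)


def irmsd(pose: Structure, native: Structure, contact_cutoff: float = 6.0) -> float:
    """Interface RMSD of ``pose`` against ``native``.

    Interface residues are determined on the native complex at
    ``contact_cutoff``; the backbone atoms (N, CA, C, O) of those residues
    are collected from both structures in identical residue order (atoms
    missing on either side are dropped pairwise), superposed, and the
    residual RMSD returned.
    """
    native_contacts = contact_pairs(native, cutoff=contact_cutoff)
    rec_iface, lig_iface = interface_residues(native_contacts)
    keys = sorted(rec_iface) + sorted(lig_iface)
    if not keys:
        raise ValueError("native complex has an empty interface")

    pose_pts, native_pts = [], []
    for key in keys:
        nres = native.residue(key)
        pres = pose.residue(key)
        if pres is None:
            raise StructureError(
                f"pose is missing native interface residue {key} (numbering mismatch)"
            )
        for name in BACKBONE_NAMES:
            na, pa = nres.atom(name), pres.atom(name)
            if na is None or pa is None:
                continue
            native_pts.append(na.coord)
            pose_pts.append(pa.coord)
    _, rmsd = superpose(np.array(pose_pts), np.array(native_pts))
    return rmsd


# CAPRI bands: fnat lower bound, irmsd band (lo, hi]; irmsd <= hi and > lo.
_BANDS = (
    (Quality.HIGH, 0.50, None, 1.0),
    (Quality.MEDIUM, 0.30, 1.0, 2.0),
    (Quality.ACCEPTABLE, 0.10, 2.0, 4.0),
)


def quality_class(fnat_value: float, irmsd_value: float, strict_verbatim: bool = False) -> Quality:
    """Map (fnat, irmsd) to a CAPRI quality class.

    Default semantics: Incorrect iff fnat < 0.10 or irmsd > 4.0; otherwise
    the best class whose fnat lower bound is met and whose irmsd upper bound
    is met (irmsd <= 1.0 -> High band, <= 2.0 -> Medium band, <= 4.0 ->
    Acceptable band, each claimable by any pose with sufficient fnat).
    """
    if not 0.0 <= fnat_value <= 1.0:
        raise ValueError("fnat must lie in [0, 1]")
    if irmsd_value < 0:
        raise ValueError("irmsd must be non-negative")

    if strict_verbatim:
        if fnat_value < 0.10 or irmsd_value > 4.0:
            return Quality.INCORRECT
        if fnat_value >= 0.50 and irmsd_value <= 1.0:
            return Quality.HIGH
        if 0.30 <= fnat_value < 0.50 and 1.0 < irmsd_value <= 2.0:
            return Quality.MEDIUM
        if 0.10 <= fnat_value < 0.30 and 2.0 < irmsd_value <= 4.0:
            return Quality.ACCEPTABLE
        return Quality.UNCLASSIFIED

    if fnat_value < 0.10 or irmsd_value > 4.0:
        return Quality.INCORRECT
    best = Quality.INCORRECT
    for quality, fnat_lo, _, irmsd_hi in reversed(_BANDS):
        if fnat_value >= fnat_lo and irmsd_value <= irmsd_hi:
            best = quality
    return best if best is not Quality.INCORRECT else Quality.INCORRECT


def score_pose(pose: Structure, native: Structure, contact_cutoff: float = 6.0) -> CapriScore:
    """Compute all CAPRI measures of a pose against the native complex."""
    native_contacts = contact_pairs(native, cutoff=contact_cutoff)
    pose_contacts = contact_pairs(pose, cutoff=contact_cutoff)
    f = fnat(pose_contacts, native_contacts)
    fn = fnonnat(pose_contacts, native_contacts)
    ir = irmsd(pose, native, contact_cutoff=contact_cutoff)
    return CapriScore(fnat=f, fnonnat=fn, irmsd=ir, quality=quality_class(f, ir))
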