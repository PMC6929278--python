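"""Structure model: PDB I/O, contacts, frames, hexagon sectors, superposition."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hexablock.structure_model import (
    Atom,
    Chain,
    Residue,
    RigidTransform,
    Structure,
    StructureError,
    FrameError,
    apply_transform,
    contact_pairs,
    hexagon_neighbors,
    interface_residues,
    read_pdb,
    residue_frame,
    superpose,
    virtual_cbeta,
    write_pdb,
)
from hexablock.synthetic_fixtures import make_ideal_chain, derive_seed

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY B   1       4.000   0.000   3.000  1.00  0.00           N
ATOM      5  CA  GLY B   1       5.458   0.000   3.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.30  0.00           C
ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.70  0.00           C
ATOM      4  N   GLY B   1       4.000   0.000   3.000  1.00  0.00           N
END
"""


def _single_atom_structure(distance):
    """Two one-atom residues, one per unit, at the given separation."""
    r1 = Residue("A", 1, "ALA", [Atom("CA", "C", np.zeros(3))])
    r2 = Residue("B", 1, "GLY", [Atom("CA", "C", np.array([distance, 0.0, 0.0]))])
    return Structure([Chain("A", [r1]), Chain("B", [r2])], {"A"}, {"B"})


def _random_rigid(rng):
    return RigidTransform(
        Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix(),
        rng.normal(scale=10.0, size=3),
    )


class TestReadWritePdb:
    def test_minimal_two_chain_parse(self):
        s = read_pdb(MINIMAL_PDB, {"A"}, {"B"})
        assert len(s.chains) == 2
        assert [len(c) for c in s.chains] == [1, 1]
        assert s.chains[0].residues[0].res_type == "ALA"

    def test_altloc_resolved_to_highest_occupancy(self):
        s = read_pdb(ALTLOC_PDB, {"A"}, {"B"})
        ca = s.chains[0].residues[0].atom("CA")
        assert ca.coord[0] == pytest.approx(2.0)  # occupancy 0.70 conformer

    def test_unknown_chain_id_rejected(self):
        with pytest.raises(StructureError, match="unknown chain"):
            read_pdb(MINIMAL_PDB, {"A"}, {"Z"})

    def test_no_atom_records_rejected(self):
        with pytest.raises(StructureError):
            read_pdb("HEADER  NOTHING\nEND\n", {"A"}, {"B"})

    def test_round_trip_preserves_coordinates(self, toy_complex):
        text = write_pdb(toy_complex)
        again = read_pdb(text, {"A"}, {"B"})
        for r1, r2 in zip(toy_complex.all_residues(), again.all_residues()):
            assert np.max(np.abs(r1.coords() - r2.coords())) < 1e-3


class TestContacts:
    def test_pair_just_inside_cutoff(self):
        assert len(contact_pairs(_single_atom_structure(5.99), 6.0)) == 1

    def test_pair_exactly_at_cutoff_excluded(self):
        # the interface rule is a strict inequality
        assert len(contact_pairs(_single_atom_structure(6.00), 6.0)) == 0

    def test_matches_brute_force_oracle(self, toy_complex):
        cs = contact_pairs(toy_complex, 6.0)
        rec = toy_complex.unit_residues("receptor")
        lig = toy_complex.unit_residues("ligand")
        expected = {}
        for r in rec:
            for l in lig:
                dmin = min(
                    float(np.linalg.norm(a.coord - b.coord))
                    for a in r.atoms
                    for b in l.atoms
                )
                if dmin < 6.0:
                    expected[(r.key, l.key)] = dmin
        assert cs.residue_pairs() == set(expected)
        for pair, d in cs.pairs.items():
            assert d == pytest.approx(expected[pair], abs=1e-9)

    def test_interface_residues_are_union_of_pair_members(self, toy_complex):
        cs = contact_pairs(toy_complex, 6.0)
        rec, lig = interface_residues(cs)
        assert rec == {p[0] for p in cs.pairs}
        assert lig == {p[1] for p in cs.pairs}

    def test_empty_contacts_give_empty_sets(self):
        from hexablock.structure_model import ContactSet

        rec, lig = interface_residues(ContactSet({}, 6.0))
        assert rec == set() and lig == set()


class TestResidueFrame:
    def _canonical_residue(self):
        return Residue(
            "A", 1, "ALA",
            [
                Atom("CA", "C", np.zeros(3)),
                Atom("CB", "C", np.array([0.0, 1.53, 0.0])),
                Atom("N", "N", np.array([1.2, 0.8, 0.0])),
                Atom("C", "C", np.array([-1.0, 0.5, 1.0])),
            ],
        )

    def test_canonical_placement_gives_identity_frame(self):
        f = residue_frame(self._canonical_residue())
        assert np.allclose(f.origin, 0)
        assert np.allclose(f.axes, np.eye(3), atol=1e-12)

    def test_frame_invariants_in_local_coordinates(self, toy_complex):
        for res in toy_complex.all_residues()[:10]:
            f = residue_frame(res)
            cb = f.to_frame(res.atom("CB").coord)
            n = f.to_frame(res.atom("N").coord)
            assert abs(cb[0]) < 1e-6 and abs(cb[2]) < 1e-6 and cb[1] > 0
            assert abs(n[2]) < 1e-6 and n[0] > 0

    def test_equivariance_under_rigid_motion(self, rng):
        res = self._canonical_residue()
        t = _random_rigid(rng)
        moved = Residue(
            "A", 1, "ALA",
            [Atom(a.name, a.element, t.apply(a.coord)) for a in res.atoms],
        )
        f0, f1 = residue_frame(res), residue_frame(moved)
        pts = np.array([a.coord for a in res.atoms])
        assert np.allclose(f0.to_frame(pts), f1.to_frame(t.apply(pts)), atol=1e-9)

    def test_glycine_virtual_cbeta_yields_valid_frame(self):
        gly = Residue(
            "A", 1, "GLY",
            [
                Atom("N", "N", np.array([1.46, 0.0, 0.0])),
                Atom("CA", "C", np.zeros(3)),
                Atom("C", "C", np.array([-0.55, 1.42, 0.0])),
            ],
        )
        cb = virtual_cbeta(gly)
        assert np.linalg.norm(cb) == pytest.approx(1.53, abs=1e-9)
        for other in ("N", "C"):
            v1 = gly.atom(other).coord / np.linalg.norm(gly.atom(other).coord)
            angle = math.degrees(math.acos(np.clip(v1 @ (cb / np.linalg.norm(cb)), -1, 1)))
            assert angle == pytest.approx(110.5, abs=0.5)
        f = residue_frame(gly)
        assert np.allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-9)

    def test_missing_backbone_raises(self):
        res = Residue("A", 1, "ALA", [Atom("CA", "C", np.zeros(3))])
        with pytest.raises(FrameError):
            residue_frame(res)


def _sector_oracle(structure, residue, cutoff, min_seq_sep=4):
    """Brute-force hexagon assignment: enumerate everything, assign, minimise."""
    frame = residue_frame(residue)
    best = [None] * 6
    best_d = [float("inf")] * 6
    for other in structure.all_residues():
        if other is residue:
            continue
        if (
            other.chain_id == residue.chain_id
            and abs(other.seq_index - residue.seq_index) < min_seq_sep
        ):
            continue
        ca = other.atom("CA")
        if ca is None:
            continue
        d = float(np.linalg.norm(ca.coord - frame.origin))
        if d >= cutoff:
            continue
        x, _, z = frame.to_frame(ca.coord)
        az = math.degrees(math.atan2(z, x)) % 360.0
        sector = min(int(az // 60.0), 5)
        if d < best_d[sector]:
            best_d[sector] = d
            best[sector] = other
    return best


class TestHexagonNeighbors:
    def test_matches_brute_force_oracle(self, toy_complex):
        for res in toy_complex.all_residues():
            got = hexagon_neighbors(toy_complex, res, cutoff=10.0)
            want = _sector_oracle(toy_complex, res, cutoff=10.0)
            assert [g.key if g else None for g in got] == [
                w.key if w else None for w in want
            ]

    def test_sequence_local_candidates_excluded(self):
        chain = make_ideal_chain(8, "helix", "A")
        other = make_ideal_chain(1, "helix", "B")
        for r in other.residues:
            r.atoms = [Atom(a.name, a.element, a.coord + np.array([60.0, 0, 0])) for a in r.atoms]
        s = Structure([chain, other], {"A"}, {"B"})
        target = chain.residues[0]  # neighbours at delta 1..7; only delta>=4 eligible
        got = hexagon_neighbors(s, target, cutoff=50.0)
        for nb in got:
            if nb is not None:
                assert abs(nb.seq_index - target.seq_index) >= 4

    def test_nearest_candidate_wins_within_sector(self):
        # two candidates placed in the same azimuthal wedge at 5 and 7 A
        target = Residue(
            "A", 1, "ALA",
            [
                Atom("CA", "C", np.zeros(3)),
                Atom("CB", "C", np.array([0.0, 1.53, 0.0])),
                Atom("N", "N", np.array([1.2, 0.8, 0.0])),
            ],
        )
        near = Residue("B", 1, "GLY", [Atom("CA", "C", np.array([4.9, 0.0, 1.0]))])
        far = Residue("B", 2, "GLY", [Atom("CA", "C", np.array([6.9, 0.0, 1.2]))])
        s = Structure([Chain("A", [target]), Chain("B", [near, far])], {"A"}, {"B"})
        got = hexagon_neighbors(s, target, cutoff=10.0)
        filled = [nb for nb in got if nb is not None]
        assert len(filled) == 1 and filled[0].seq_index == 1

    def test_candidate_beyond_cutoff_leaves_sector_empty(self):
        target = Residue(
            "A", 1, "ALA",
            [
                Atom("CA", "C", np.zeros(3)),
                Atom("CB", "C", np.array([0.0, 1.53, 0.0])),
                Atom("N", "N", np.array([1.2, 0.8, 0.0])),
            ],
        )
        lone = Residue("B", 1, "GLY", [Atom("CA", "C", np.array([12.0, 0.0, 0.0]))])
        s = Structure([Chain("A", [target]), Chain("B", [lone])], {"A"}, {"B"})
        assert hexagon_neighbors(s, target, cutoff=10.0) == [None] * 6

    def test_sector_assignment_is_a_partition(self, toy_complex, rng):
        """Every eligible candidate falls in exactly one half-open wedge."""
        res = toy_complex.chains[0].residues[10]
        frame = residue_frame(res)
        for _ in range(200):
            p = frame.origin + rng.normal(size=3) * 5
            x, _, z = frame.to_frame(p)
            az = math.degrees(math.atan2(z, x)) % 360.0
            sectors = [s for s in range(6) if 60 * s <= az < 60 * (s + 1)]
            assert len(sectors) == 1


def _quaternion_superpose_oracle(moving, fixed):
    """Horn's closed-form quaternion method, independent of the Kabsch/SVD route."""
    mv = moving - moving.mean(axis=0)
    fx = fixed - fixed.mean(axis=0)
    S = mv.T @ fx
    K = np.array(
        [
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(K)
    w, x, y, z = eigvecs[:, -1]
    R = Rotation.from_quat([x, y, z, w]).as_matrix()
    resid = mv @ R.T - fx
    return math.sqrt(float(np.mean(np.sum(resid**2, axis=1))))


class TestSuperpose:
    def test_identical_sets_have_zero_rmsd(self, rng):
        pts = rng.normal(size=(10, 3))
        _, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_recovers_exactly(self, rng):
        pts = rng.normal(size=(10, 3))
        t = _random_rigid(rng)
        transform, rmsd = superpose(t.apply(pts), pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(transform.apply(t.apply(pts)), pts, atol=1e-8)

    def test_matches_quaternion_oracle_with_noise(self, rng):
        fixed = rng.normal(size=(10, 3)) * 5
        t = _random_rigid(rng)
        moving = t.apply(fixed) + rng.normal(scale=0.3, size=(10, 3))
        _, rmsd = superpose(moving, fixed)
        assert rmsd == pytest.approx(_quaternion_superpose_oracle(moving, fixed), abs=1e-9)

    def test_rmsd_invariant_to_rigid_preperturbation(self, rng):
        fixed = rng.normal(size=(12, 3)) * 4
        moving = fixed + rng.normal(scale=0.5, size=(12, 3))
        _, base = superpose(moving, fixed)
        for _ in range(3):
            t = _random_rigid(rng)
            _, r = superpose(t.apply(moving), fixed)
            assert r == pytest.approx(base, abs=1e-9)

    def test_superposed_rmsd_never_exceeds_raw_rmsd(self, rng):
        for _ in range(10):
            fixed = rng.normal(size=(8, 3)) * 3
            moving = fixed + rng.normal(scale=1.0, size=(8, 3))
            raw = math.sqrt(float(np.mean(np.sum((moving - fixed) ** 2, axis=1))))
            _, opt = superpose(moving, fixed)
            assert opt <= raw + 1e-12

    def test_too_few_or_degenerate_points_rejected(self, rng):
        with pytest.raises(StructureError):
            superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(StructureError, match="degenerate"):
            superpose(line, line + 1.0)


class TestApplyTransform:
    def test_identity_leaves_coordinates(self, toy_complex):
        moved = apply_transform(toy_complex, RigidTransform.identity(), "ligand")
        for r1, r2 in zip(toy_complex.all_residues(), moved.all_residues()):
            assert np.array_equal(r1.coords(), r2.coords())

    def test_inverse_restores_original(self, toy_complex, rng):
        t = _random_rigid(rng)
        there = apply_transform(toy_complex, t, "ligand")
        back = apply_transform(there, t.inverse(), "ligand")
        for r1, r2 in zip(toy_complex.all_residues(), back.all_residues()):
            assert np.max(np.abs(r1.coords() - r2.coords())) < 1e-9

    def test_translation_moves_only_the_stated_unit(self, toy_complex):
        t = RigidTransform(np.eye(3), np.array([10.0, 0.0, 0.0]))
        moved = apply_transform(toy_complex, t, "ligand")
        for unit, delta in (("receptor", 0.0), ("ligand", 10.0)):
            for r1, r2 in zip(
                toy_complex.unit_residues(unit), moved.unit_residues(unit)
            ):
                assert np.allclose(r2.coords()[:, 0] - r1.coords()[:, 0], delta)

    def test_rigid_transform_validation(self):
        with pytest.raises(StructureError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection
        with pytest.raises(StructureError):
            RigidTransform(np.eye(3) * 2, np.zeros(3))
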