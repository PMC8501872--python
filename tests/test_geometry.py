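"""Superposition, dRMS, angles, and contact observables."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pathsage.geometry import (
    apply_transform,
    bend_angle,
    contact_frequency,
    drms,
    group_min_distance,
    superpose,
)
from pathsage.structure import SelectionError, Structure, Trajectory
from pathsage.synthetic import PlantedDomainSpec, make_two_domain_pair, make_ca_trace
import biotite.structure as struc


def _structure_from_coords(coords, names=None, resids=None, elements=None):
    n = len(coords)
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(coords, dtype=np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = np.arange(1, n + 1) if resids is None else np.asarray(resids)
    atoms.res_name = np.full(n, "ALA")
    atoms.atom_name = np.full(n, "CA") if names is None else np.asarray(names)
    atoms.element = np.full(n, "C") if elements is None else np.asarray(elements)
    atoms.hetero = np.zeros(n, dtype=bool)
    return Structure(atoms)


class TestSuperpose:
    def test_identical_sets_identity(self):
        pts = make_ca_trace(20, seed=0)
        R, t, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_planted_rotation_recovered_exactly(self):
        pts = make_ca_trace(30, seed=1)
        rot = Rotation.from_rotvec(np.radians(25.0) * np.array([0.3, -0.5, 0.81]) /
                                   np.linalg.norm([0.3, -0.5, 0.81]))
        moved = pts @ rot.as_matrix().T + np.array([1.0, -2.0, 0.5])
        R, t, rmsd = superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        angle = np.degrees(np.linalg.norm(Rotation.from_matrix(R).as_rotvec()))
        assert angle == pytest.approx(25.0, abs=1e-9)

    def test_reflection_never_used(self):
        # chiral 4-point set vs its mirror image: best proper fit has rmsd > 0
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mirror = pts * np.array([1, 1, -1])
        R, t, rmsd = superpose(mirror, pts)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_matches_brute_force_quaternion_grid(self):
        """Optimal RMSD agrees with a dense rotation-space scan."""
        rng = np.random.default_rng(6)
        a = rng.standard_normal((10, 3))
        b = a + 0.3 * rng.standard_normal((10, 3))
        _, _, rmsd = superpose(b, a)

        a0 = a - a.mean(axis=0)
        b0 = b - b.mean(axis=0)
        best = np.inf
        # coarse grid + local refinement around the best cell
        for rv in itertools.product(np.linspace(-np.pi, np.pi, 21), repeat=3):
            R = Rotation.from_rotvec(rv).as_matrix()
            best = min(best, np.sqrt(np.mean(np.sum((b0 @ R.T - a0) ** 2, axis=1))))
        assert rmsd <= best + 1e-9
        from scipy.optimize import minimize

        res = minimize(
            lambda rv: np.sqrt(np.mean(np.sum(
                (b0 @ Rotation.from_rotvec(rv).as_matrix().T - a0) ** 2, axis=1))),
            x0=np.zeros(3), method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-12, maxiter=10000),
        )
        assert rmsd == pytest.approx(res.fun, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError):
            superpose(line, line)
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDrms:
    def test_identical_structures_zero(self):
        a, _, _ = make_two_domain_pair(PlantedDomainSpec(seed=3))
        assert drms(a, a, "name CA") == 0.0

    def test_hand_computed_three_atom_value(self):
        # A: collinear 0,1,2; B: right angle. Only the 1-3 pair changes:
        # |2 - sqrt(2)| over 3 pairs -> sqrt((2-sqrt2)^2/3) = 0.33818...
        a = _structure_from_coords([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        b = _structure_from_coords([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
        expected = np.sqrt((2 - np.sqrt(2)) ** 2 / 3)
        assert drms(a, b, "name CA") == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.3382, abs=1e-4)

    def test_invariant_under_rigid_transform(self):
        # float64 end to end: the operation itself is exactly invariant
        # (structure files/AtomArrays store float32, i.e. ~1e-7)
        from pathsage.geometry import drms_coords

        a, b, _ = make_two_domain_pair(PlantedDomainSpec(angle=40.0, seed=5))
        ca = np.asarray(a.coords, dtype=float)
        cb = np.asarray(b.coords, dtype=float)
        ref = drms_coords(ca, cb)
        R = Rotation.from_rotvec([0.4, 1.0, -0.2]).as_matrix()
        moved = apply_transform(cb, R, np.array([10.0, -3.0, 7.0]))
        assert abs(drms_coords(ca, moved) - ref) < 1e-10
        # through float32-backed structures the error stays at storage precision
        s_moved = Structure(b.atoms.copy())
        s_moved.coords = moved
        assert abs(drms(a, s_moved, "name CA") - ref) < 1e-5

    def test_selection_mismatch_is_error(self):
        a, b, _ = make_two_domain_pair(PlantedDomainSpec(seed=5))
        trimmed = Structure(b.atoms[:-2])
        with pytest.raises(SelectionError):
            drms(a, trimmed, "name CA")


class TestBendAngle:
    def test_collinear_gives_180(self):
        s = _structure_from_coords([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert bend_angle(s, "resid 1", "resid 2", "resid 3") == pytest.approx(180.0)

    def test_right_angle_and_45_degrees(self):
        s = _structure_from_coords([[1, 0, 0], [0, 0, 0], [0, 1, 0], [1, 1, 0]])
        assert bend_angle(s, "resid 1", "resid 2", "resid 3") == pytest.approx(90.0)
        assert bend_angle(s, "resid 1", "resid 2", "resid 4") == pytest.approx(45.0)

    def test_ambiguous_spec_rejected(self):
        s = _structure_from_coords([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(SelectionError):
            bend_angle(s, "name CA", "resid 2", "resid 3")

    def test_coincident_points_rejected(self):
        s = _structure_from_coords([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            bend_angle(s, "resid 1", "resid 2", "resid 3")


class TestContacts:
    def test_two_atoms_three_angstrom(self):
        s = _structure_from_coords([[0, 0, 0], [3, 0, 0]])
        assert group_min_distance(s, "resid 1", "resid 2") == pytest.approx(3.0)

    def test_overlapping_selections_exclude_self_pairs(self):
        s = _structure_from_coords([[0, 0, 0], [1.5, 0, 0], [5, 0, 0]])
        assert group_min_distance(s, "all", "all") == pytest.approx(1.5)

    def test_empty_selection_named_in_error(self):
        s = _structure_from_coords([[0, 0, 0]])
        with pytest.raises(SelectionError, match="resid 99"):
            group_min_distance(s, "resid 1", "resid 99")

    def test_planted_contact_frequency(self):
        frames = []
        for f in range(10):
            d = 3.0 if f < 7 else 8.0  # contact in 7 of 10 frames at 4 A cutoff
            frames.append(_structure_from_coords([[0, 0, 0], [d, 0, 0]]))
        traj = Trajectory.from_structures(frames)
        assert contact_frequency(traj, "resid 1", "resid 2", cutoff=4.0) == 0.7
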