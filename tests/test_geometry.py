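"""SASA/BSA, hinge rotation, tether reach, and the selection language."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dlptether.geometry import (
    DEFAULT_PROBE_RADIUS, VDW_RADII, buried_surface_area, hinge_angle,
    max_reach, parse_selection, path_reach, rigid_span, rmsd_after_superposition,
    sasa,
)
from dlptether.structure import AtomicStructure, StructureError


def atoms(coords, elements=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    elements = elements or ["C"] * n
    return AtomicStructure(
        chain_id=np.array(["A"] * n),
        res_id=np.arange(1, n + 1),
        res_name=np.array(["GLY"] * n),
        atom_name=np.array([f"C{i}" if i else "CA" for i in range(n)]),
        element=np.array(elements),
        coord=coords,
    )


def dense_reference_sasa(coords, radii, probe, n_points=10_000):
    """Independent dense-sampling accessibility oracle (golden-spiral
    points, exclusion by any other expanded sphere)."""
    k = np.arange(n_points)
    phi = np.pi * (3 - np.sqrt(5)) * k
    z = 1 - 2 * (k + 0.5) / n_points
    rho = np.sqrt(1 - z * z)
    sphere = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    total = 0.0
    per_atom = []
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + (r + probe) * sphere
        free = np.ones(n_points, bool)
        for j, (c2, r2) in enumerate(zip(coords, radii)):
            if j == i:
                continue
            free &= np.linalg.norm(pts - c2, axis=1) >= (r2 + probe)
        area = 4 * np.pi * (r + probe) ** 2 * free.mean()
        per_atom.append(area)
        total += area
    return np.array(per_atom), total


class TestSasa:
    def test_isolated_atom_closed_form(self):
        s = atoms([[0.0, 0, 0]])
        _, total = sasa(s, probe_radius=1.4)
        expected = 4 * np.pi * (VDW_RADII["C"] + 1.4) ** 2
        assert total == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_additive(self):
        s = atoms([[0.0, 0, 0], [100.0, 0, 0]])
        _, total = sasa(s)
        single = 4 * np.pi * (VDW_RADII["C"] + DEFAULT_PROBE_RADIUS) ** 2
        assert total == pytest.approx(2 * single, rel=0.01)

    def test_matches_dense_sampling_oracle(self, rng):
        coords = rng.uniform(0, 6, (10, 3))
        elements = list(rng.choice(["C", "N", "O", "S"], 10))
        s = atoms(coords, elements)
        _, total = sasa(s)
        radii = np.array([VDW_RADII[e] for e in elements])
        _, ref = dense_reference_sasa(coords, radii, DEFAULT_PROBE_RADIUS)
        assert total == pytest.approx(ref, rel=0.02)

    def test_unknown_element_errors(self):
        s = atoms([[0.0, 0, 0]], ["ZZ"])
        with pytest.raises(StructureError, match="radius"):
            sasa(s)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(0, 8, (8, 3))
        s1 = atoms(coords)
        rot = Rotation.from_rotvec([0.5, 1.0, -0.3]).as_matrix()
        s2 = atoms(coords @ rot.T + np.array([10.0, 5.0, -2.0]))
        # the deterministic sphere lattice is orientation-fixed, so point
        # sampling limits agreement to ~the lattice resolution
        assert sasa(s1)[1] == pytest.approx(sasa(s2)[1], rel=0.01)


class TestBsa:
    def _complex(self, separation):
        half = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 1.8, 0]])
        coords = np.vstack([half, half + [separation, 0.0, 0.0]])
        return atoms(coords)

    def test_separated_parts_zero(self):
        s = self._complex(100.0)
        mask_a = np.arange(6) < 3
        rep = buried_surface_area(s, mask_a, ~mask_a)
        assert rep.bsa_two_sided == pytest.approx(0.0, abs=1e-6)

    def test_contact_buries_area_and_symmetry(self):
        s = self._complex(4.0)
        mask_a = np.arange(6) < 3
        rep = buried_surface_area(s, mask_a, ~mask_a)
        assert rep.bsa_two_sided > 10
        assert rep.bsa_one_sided == pytest.approx(rep.bsa_two_sided / 2)
        swapped = buried_surface_area(s, ~mask_a, mask_a)
        assert swapped.bsa_two_sided == pytest.approx(rep.bsa_two_sided,
                                                      rel=1e-9)

    def test_overlapping_selection_rejected(self):
        s = self._complex(4.0)
        mask = np.ones(6, bool)
        with pytest.raises(ValueError, match="overlap"):
            buried_surface_area(s, mask, mask)

    def test_rigid_motion_invariance(self):
        s1 = self._complex(4.0)
        rot = Rotation.from_euler("xyz", [30, 60, -10], degrees=True).as_matrix()
        s2 = atoms(s1.coord @ rot.T + np.array([3.0, -9.0, 1.0]))
        mask_a = np.arange(6) < 3
        r1 = buried_surface_area(s1, mask_a, ~mask_a)
        r2 = buried_surface_area(s2, mask_a, ~mask_a)
        assert r1.bsa_two_sided == pytest.approx(r2.bsa_two_sided, rel=0.02,
                                                 abs=0.5)


class TestHinge:
    def test_identical_states_zero(self, rng):
        ref = rng.normal(0, 5, (10, 3))
        mov = rng.normal(20, 5, (10, 3))
        angle, _, _ = hinge_angle(ref, ref, mov, mov)
        # arccos is ill-conditioned at 0°: 1e-8 matrix noise → ~1e-4 rad
        assert angle == pytest.approx(0.0, abs=1e-2)

    def test_constructed_rotation_recovered(self, rng):
        ref = rng.normal(0, 5, (10, 3))
        mov1 = rng.normal(20, 5, (10, 3))
        axis = np.array([0.0, 0.0, 1.0])
        rot = Rotation.from_rotvec(np.pi / 2 * axis).as_matrix()
        mov2 = mov1 @ rot.T
        angle, got_axis, _ = hinge_angle(ref, ref, mov1, mov2)
        assert angle == pytest.approx(90.0, abs=1e-6)
        assert abs(np.dot(got_axis, axis)) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_between_states(self, rng):
        ref1 = rng.normal(0, 5, (12, 3))
        rot_r = Rotation.from_euler("x", 15, degrees=True).as_matrix()
        ref2 = ref1 @ rot_r.T + [1.0, 0, 0]
        mov1 = rng.normal(25, 5, (12, 3))
        rot_m = Rotation.from_euler("y", 55, degrees=True).as_matrix()
        mov2 = (mov1 @ rot_m.T) @ rot_r.T + [1.0, 0, 0]
        a12, _, _ = hinge_angle(ref1, ref2, mov1, mov2)
        a21, _, _ = hinge_angle(ref2, ref1, mov2, mov1)
        assert a12 == pytest.approx(a21, abs=1e-6)
        assert a12 == pytest.approx(55.0, abs=1e-6)


class TestRmsd:
    def test_zero_for_rigidly_moved_copy(self, rng):
        pts = rng.normal(0, 5, (20, 3))
        rot = Rotation.from_euler("z", 70, degrees=True).as_matrix()
        assert rmsd_after_superposition(pts, pts @ rot.T + 5) == pytest.approx(
            0.0, abs=1e-8)

    def test_positive_for_distorted_copy(self, rng):
        pts = rng.normal(0, 5, (20, 3))
        assert rmsd_after_superposition(pts, pts + rng.normal(0, 1, pts.shape)) > 0.3


class TestReach:
    def test_single_rod(self):
        assert max_reach([("rigid", 50.0)])["reach_A"] == 50.0

    def test_rods_plus_linker_arithmetic(self):
        out = max_reach([("rigid", 50.0), ("linker", 9), ("rigid", 50.0)])
        assert out["reach_A"] == pytest.approx(134.2)
        assert out["reach_nm"] == pytest.approx(13.42)

    def test_toy_path_matches_conformation_search(self, toy_pair, rng):
        """The reach bound agrees with numerical maximisation of the
        anchor–distal distance over linker conformations (freely jointed
        3.8 Å bonds, random search plus the extended configuration)."""
        m = toy_pair.docked
        sA, sC, _ = toy_pair.domain_slices
        anchor = sA.stop - 1      # domain A bead at the first tether
        distal = sC.start         # central entry bead
        bound = path_reach(m, anchor, distal)["reach_A"]
        n_bonds = (sC.start - sA.stop) + 1
        best = 0.0
        for _ in range(500):
            steps = rng.normal(size=(n_bonds, 3))
            steps = 3.8 * steps / np.linalg.norm(steps, axis=1)[:, None]
            best = max(best, float(np.linalg.norm(steps.sum(axis=0))))
        best = max(best, n_bonds * 3.8)  # fully extended member of the search
        assert bound == pytest.approx(best, rel=0.05)
        assert bound >= best * (1 - 1e-9)

    def test_disconnected_path_errors(self):
        with pytest.raises(ValueError):
            max_reach([])


class TestSelectionLanguage:
    def test_chain_and_ranges(self, toy_pair):
        from dlptether.structure import load_structure, write_bead_pdb
        s = load_structure(write_bead_pdb(toy_pair.docked))
        mask = parse_selection(s, "T:1-10+15-16")
        assert mask.sum() == 12
        assert parse_selection(s, "T").sum() == len(s)

    def test_no_match_errors(self, toy_pair):
        from dlptether.structure import load_structure, write_bead_pdb
        s = load_structure(write_bead_pdb(toy_pair.docked))
        with pytest.raises(ValueError):
            parse_selection(s, "Z:1-5")
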