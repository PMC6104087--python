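"""Potential assembly, energies, analytic forces, and minimisation."""

import numpy as np
import pytest

from dlptether import forcefield as ffm
from dlptether.contacts import Contact, ContactMap, cutoff_contacts
from dlptether.forcefield import (
    ForceFieldError, build_forcefield, energy, forces, minimize,
    read_topology, write_topology,
)
from dlptether.structure import BeadModel
from dlptether.synthetic import bundle_bead_model


def straight_chain(n, spacing=3.8):
    coords = np.column_stack([np.arange(n) * spacing,
                              0.05 * np.arange(n) ** 2,  # avoid collinearity
                              np.zeros(n)])
    bonded = np.ones(n, bool)
    bonded[0] = False
    return BeadModel(np.array(["A"] * n), np.arange(1, n + 1), coords, bonded)


def fd_error(ff, coords, beads, h=1e-5):
    f = forces(ff, coords)
    worst = 0.0
    for bead in beads:
        for c in range(3):
            xp, xm = coords.copy(), coords.copy()
            xp[bead, c] += h
            xm[bead, c] -= h
            fd = -(energy(ff, xp)["total"] - energy(ff, xm)["total"]) / (2 * h)
            worst = max(worst, abs(fd - f[bead, c]) / max(1.0, abs(f[bead, c])))
    return worst


empty_map = ContactMap([], "cutoff")


class TestBuild:
    def test_term_counts_straight_chain(self):
        ff = build_forcefield(straight_chain(5), empty_map)
        assert len(ff.bond_idx) == 4
        assert len(ff.angle_idx) == 3
        assert len(ff.dihedral_idx) == 2
        assert len(ff.contact_idx) == 0

    def test_single_contact_term(self):
        m = straight_chain(6)
        cm = ContactMap([Contact(("A", 1), ("A", 6), 19.0)], "cutoff")
        ff = build_forcefield(m, cm)
        assert len(ff.contact_idx) == 1
        assert ff.contact_eps[0] == pytest.approx(1.0)

    def test_interface_half_strength(self, toy_pair):
        ff = build_forcefield(toy_pair.docked, toy_pair.intra_map,
                              toy_pair.interface_map.scaled(0.5, "interface"))
        n_intra = len(toy_pair.intra_map)
        assert np.allclose(ff.contact_eps[:n_intra], 1.0)
        assert np.allclose(ff.contact_eps[n_intra:], 0.5)

    def test_contact_on_missing_residue_errors(self):
        m = straight_chain(5)
        cm = ContactMap([Contact(("A", 1), ("A", 99), 5.0)], "cutoff")
        with pytest.raises(ForceFieldError, match="absent"):
            build_forcefield(m, cm)

    def test_no_terms_across_breaks(self):
        m = straight_chain(6)
        m.bonded_to_prev[3] = False
        ff = build_forcefield(m, empty_map)
        assert len(ff.bond_idx) == 4
        assert len(ff.angle_idx) == 2
        assert len(ff.dihedral_idx) == 0

    def test_linker_beads_no_dihedrals_ideal_bonds(self, toy_pair):
        ff = build_forcefield(toy_pair.docked, toy_pair.intra_map)
        linker = np.flatnonzero(toy_pair.docked.is_linker)
        for quad in ff.dihedral_idx:
            assert not set(quad) & set(linker)
        linker_bonds = [n for n, (i, j) in enumerate(ff.bond_idx)
                        if i in linker or j in linker]
        assert linker_bonds
        assert np.allclose(ff.bond_r0[linker_bonds], 3.8)


class TestEnergy:
    def test_contact_minimum_is_minus_epsilon(self):
        m = straight_chain(6)
        r0 = float(np.linalg.norm(m.coord[5] - m.coord[0]))
        cm = ContactMap([Contact(("A", 1), ("A", 6), r0)], "cutoff")
        ff = build_forcefield(m, cm)
        e = energy(ff, m.coord)
        assert e["contact"] == pytest.approx(-1.0, abs=1e-12)

    def test_contact_vanishes_at_infinity(self):
        m = straight_chain(2)
        cm = ContactMap([Contact(("A", 1), ("A", 2), 3.8)], "cutoff")
        ff = build_forcefield(m, cm)
        far = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        e = energy(ff, far)
        assert e["contact"] == pytest.approx(0.0, abs=1e-10)

    def test_native_bonded_energy_zero(self):
        m = bundle_bead_model(3, 10)
        cm = cutoff_contacts(m, 8.0)
        ff = build_forcefield(m, cm)
        e = energy(ff, m.coord)
        assert e["bond"] == pytest.approx(0, abs=1e-18)
        assert e["angle"] == pytest.approx(0, abs=1e-14)
        assert e["dihedral"] == pytest.approx(0, abs=1e-14)
        # total = contact minima up to the small repulsive correction
        assert e["total"] == pytest.approx(-ff.contact_energy_minimum,
                                           rel=0.01)

    def test_coincident_beads_error(self):
        m = straight_chain(3)
        bad = m.coord.copy()
        bad[1] = bad[0]
        ff = build_forcefield(m, empty_map)
        with pytest.raises(ForceFieldError, match="coincident"):
            energy(ff, bad)

    def test_rigid_motion_invariance(self, toy_pair, rng):
        from scipy.spatial.transform import Rotation
        ff = build_forcefield(toy_pair.docked, toy_pair.intra_map,
                              toy_pair.interface_map.scaled(0.5, "interface"))
        x = toy_pair.docked.coord + rng.normal(0, 0.2, toy_pair.docked.coord.shape)
        e1 = energy(ff, x)["total"]
        rot = Rotation.from_rotvec([1.0, -0.4, 0.2]).as_matrix()
        e2 = energy(ff, x @ rot.T + np.array([17.0, -4.0, 2.0]))["total"]
        assert e2 == pytest.approx(e1, rel=1e-9, abs=1e-6)


class TestForces:
    def test_finite_difference_full_system(self, toy_pair, rng):
        ff = build_forcefield(toy_pair.docked, toy_pair.intra_map,
                              toy_pair.interface_map.scaled(0.5, "interface"))
        x = toy_pair.docked.coord + rng.normal(0, 0.15,
                                               toy_pair.docked.coord.shape)
        beads = rng.integers(0, len(x), 8)
        assert fd_error(ff, x, beads) < 1e-5

    def test_near_native_forces_small(self):
        m = bundle_bead_model(2, 10)
        ff = build_forcefield(m, cutoff_contacts(m, 8.0))
        f = forces(ff, m.coord)
        # bonded terms vanish at native; the contact repulsive factor and
        # excluded volume leave only a small residual
        assert np.abs(f).max() < 1.0

    def test_newtons_third_law_isolated_pair(self):
        m = straight_chain(2)
        cm = ContactMap([Contact(("A", 1), ("A", 2), 5.0)], "cutoff")
        ff = build_forcefield(m, cm)
        x = np.array([[0.0, 0, 0], [4.1, 0.7, -0.3]])
        f = forces(ff, x)
        assert np.allclose(f[0], -f[1], atol=1e-14)


class TestMinimize:
    def test_stretched_bond_relaxes(self):
        m = straight_chain(2)
        ff = build_forcefield(m, empty_map)
        r0 = float(np.linalg.norm(m.coord[1] - m.coord[0]))
        x = m.coord.copy()
        x[1, 0] += 1.0
        out = minimize(ff, x, force_tol=1e-6)
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(r0, abs=1e-4)

    def test_clash_removed(self):
        m = straight_chain(8)
        ff = build_forcefield(m, empty_map)
        x = m.coord.copy()
        x[6] = x[1] + np.array([0.5, 2.0, 0.0])  # non-bonded clash < r_ex
        out = minimize(ff, x, force_tol=1e-3)
        assert np.linalg.norm(out[6] - out[1]) > 3.5

    def test_idempotent(self, toy_pair):
        ff = build_forcefield(toy_pair.docked, toy_pair.intra_map)
        x1 = minimize(ff, toy_pair.docked.coord, force_tol=1e-3)
        x2 = minimize(ff, x1, force_tol=1e-3)
        assert np.allclose(x1, x2, atol=1e-3)

    def test_energy_non_increasing(self, toy_pair):
        ff = build_forcefield(toy_pair.docked, toy_pair.intra_map)
        x0 = toy_pair.start.coord
        out = minimize(ff, x0, force_tol=1e-3)
        assert energy(ff, out)["total"] <= energy(ff, x0)["total"]


class TestTopologyIO:
    def test_round_trip(self, toy_pair):
        ff = build_forcefield(toy_pair.docked, toy_pair.intra_map,
                              toy_pair.interface_map.scaled(0.5, "interface"))
        back = read_topology(write_topology(ff))
        x = toy_pair.docked.coord
        assert energy(back, x)["total"] == pytest.approx(
            energy(ff, x)["total"], rel=1e-9)
        assert np.array_equal(back.ev_pairs, ff.ev_pairs)
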