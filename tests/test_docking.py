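"""Rigid superposition and template-based dimer construction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dlptether.contacts import cutoff_contacts
from dlptether.docking import (
    ResidueCorrespondence, build_heterodimer, interface_contacts,
    rotation_angle, superpose,
)
from dlptether.structure import AtomicStructure, bead_model_to_structure
from dlptether.synthetic import bundle_bead_model


@pytest.fixture()
def points():
    return np.random.default_rng(12345).normal(0, 5, (12, 3))


class TestSuperpose:
    def test_identity(self, points):
        rot, trans, rmsd = superpose(points, points)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0, atol=1e-10)
        assert rmsd == pytest.approx(0, abs=1e-10)

    def test_recovers_constructed_transform(self, points):
        true_rot = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        moved = points @ true_rot.T + np.array([1.0, 2.0, 3.0])
        rot, trans, rmsd = superpose(points, moved)
        assert rotation_angle(rot) == pytest.approx(37.0, abs=1e-6)
        assert rmsd == pytest.approx(0, abs=1e-8)

    def test_mirror_gives_proper_rotation(self, points):
        mirrored = points * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = superpose(points, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_collinear_degenerate(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            superpose(line, line)

    def test_matches_scipy_align_vectors(self, points, rng):
        """Independent cross-check against scipy's Kabsch implementation."""
        target = rng.normal(0, 5, points.shape)
        rot, trans, rmsd = superpose(points, target)
        sp_rot, _ = Rotation.align_vectors(
            target - target.mean(0), points - points.mean(0))
        assert np.allclose(rot, sp_rot.as_matrix(), atol=1e-8)


def _as_template(m, chain):
    s = bead_model_to_structure(m)
    s.chain_id = np.array([chain] * len(s))
    return s


class TestBuildHeterodimer:
    @pytest.fixture()
    def bundle(self):
        return bundle_bead_model(2, 9, chain="P")

    def test_recovers_template_transform(self, bundle):
        rot = Rotation.from_euler("xyz", [10, 40, -25], degrees=True).as_matrix()
        partner = bundle
        t1 = _as_template(bundle, "X")
        t2 = _as_template(bundle.with_coords(
            bundle.coord @ rot.T + np.array([30.0, 0, 0])), "Y")
        from dlptether.docking import _merge
        template = _merge(t1, t2)
        keys = [("P", int(r)) for r in bundle.res_id]
        corr1 = ResidueCorrespondence([(k, ("X", k[1])) for k in keys])
        partner2 = bundle.with_coords(bundle.coord.copy())
        partner2 = type(bundle)(np.array(["Q"] * len(bundle)), bundle.res_id,
                                bundle.coord, bundle.bonded_to_prev)
        corr2 = ResidueCorrespondence([(("Q", k[1]), ("Y", k[1])) for k in keys])
        d = build_heterodimer(partner, corr1, partner2, corr2, template)
        got_rot, got_trans = d.transforms[1]
        assert np.allclose(got_rot, rot, atol=1e-6)
        assert np.allclose(got_trans, [30, 0, 0], atol=1e-6)
        assert d.clash_count == 0

    def test_native_dimer_as_own_template(self, toy_pair):
        """Docking the toy domains onto their own docked pose reproduces it."""
        m = toy_pair.docked
        sA, _, sB = toy_pair.domain_slices
        from dlptether.structure import BeadModel
        a = BeadModel(np.array(["A"] * (sA.stop - sA.start)),
                      m.res_id[sA], m.coord[sA],
                      np.r_[False, [True] * (sA.stop - sA.start - 1)])
        b = BeadModel(np.array(["B"] * (sB.stop - sB.start)),
                      m.res_id[sB], m.coord[sB],
                      np.r_[False, [True] * (sB.stop - sB.start - 1)])
        template = AtomicStructure(
            np.array(["A"] * len(a) + ["B"] * len(b)),
            np.concatenate([a.res_id, b.res_id]),
            np.array(["GLY"] * (len(a) + len(b))),
            np.array(["CA"] * (len(a) + len(b))),
            np.array(["C"] * (len(a) + len(b))),
            np.concatenate([a.coord, b.coord]),
        )
        corr_a = ResidueCorrespondence(
            [(("A", int(r)), ("A", int(r))) for r in a.res_id])
        corr_b = ResidueCorrespondence(
            [(("B", int(r)), ("B", int(r))) for r in b.res_id])
        d = build_heterodimer(a, corr_a, b, corr_b, template)
        assert d.clash_count == 0
        assert np.allclose(d.structure.coord,
                           np.concatenate([a.coord, b.coord]), atol=1e-8)

    def test_overlapping_partners_report_clashes(self, bundle):
        t1 = _as_template(bundle, "X")
        t2 = _as_template(bundle, "Y")  # same place: full overlap
        from dlptether.docking import _merge
        template = _merge(t1, t2)
        keys = [("P", int(r)) for r in bundle.res_id]
        other = type(bundle)(np.array(["Q"] * len(bundle)), bundle.res_id,
                             bundle.coord, bundle.bonded_to_prev)
        d = build_heterodimer(
            bundle, ResidueCorrespondence([(k, ("X", k[1])) for k in keys]),
            other, ResidueCorrespondence([(("Q", k[1]), ("Y", k[1])) for k in keys]),
            template)
        assert d.clash_count > 0

    def test_equivariance_under_template_motion(self, bundle):
        rot = Rotation.from_euler("y", 70, degrees=True).as_matrix()
        shift = np.array([5.0, -2.0, 8.0])
        t1 = _as_template(bundle, "X")
        t2 = _as_template(bundle.with_coords(bundle.coord + [25.0, 0, 0]), "Y")
        from dlptether.docking import _merge
        template = _merge(t1, t2)
        moved_template = template.transformed(rot, shift)
        keys = [("P", int(r)) for r in bundle.res_id]
        other = type(bundle)(np.array(["Q"] * len(bundle)), bundle.res_id,
                             bundle.coord, bundle.bonded_to_prev)
        corr1 = ResidueCorrespondence([(k, ("X", k[1])) for k in keys])
        corr2 = ResidueCorrespondence([(("Q", k[1]), ("Y", k[1])) for k in keys])
        d1 = build_heterodimer(bundle, corr1, other, corr2, template)
        d2 = build_heterodimer(bundle, corr1, other, corr2, moved_template)
        assert np.allclose(d2.structure.coord,
                           d1.structure.coord @ rot.T + shift, atol=1e-8)
        cm1 = interface_contacts(d1, 1.0, cutoff=8.0)
        cm2 = interface_contacts(d2, 1.0, cutoff=8.0)
        assert [c.r0 for c in cm1] == pytest.approx([c.r0 for c in cm2])


class TestInterfaceContacts:
    def _docked(self, bundle_sep):
        bundle = bundle_bead_model(2, 9, chain="P")
        other = type(bundle)(np.array(["Q"] * len(bundle)), bundle.res_id,
                             bundle.coord + np.array([bundle_sep, 0, 0]),
                             bundle.bonded_to_prev)
        t1 = _as_template(bundle, "X")
        t2 = _as_template(other, "Y")
        from dlptether.docking import _merge
        template = _merge(t1, t2)
        keys = [("P", int(r)) for r in bundle.res_id]
        return build_heterodimer(
            bundle, ResidueCorrespondence([(k, ("X", k[1])) for k in keys]),
            other, ResidueCorrespondence([(("Q", k[1]), ("Y", k[1])) for k in keys]),
            template)

    def test_strength_factor_applied(self):
        cm = interface_contacts(self._docked(12.0), 0.5, cutoff=8.0)
        assert len(cm) > 0
        assert all(c.strength == 0.5 and c.kind == "interface" for c in cm)

    def test_separated_partners_empty_map(self):
        cm = interface_contacts(self._docked(50.0), 0.5, cutoff=8.0)
        assert len(cm) == 0

    def test_no_intra_partner_pairs_and_oracle(self):
        d = self._docked(12.0)
        cm = interface_contacts(d, 1.0, cutoff=8.0)
        coords = d.structure.coord
        chains = d.structure.chain_id
        expected = set()
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if chains[i] == chains[j]:
                    continue
                if np.linalg.norm(coords[i] - coords[j]) <= 8.0:
                    expected.add(frozenset({
                        (str(chains[i]), int(d.structure.res_id[i])),
                        (str(chains[j]), int(d.structure.res_id[j]))}))
        assert cm.pair_set() == expected
        for c in cm:
            assert c.a[0] != c.b[0]


class TestSuperposeProperties:
    """Property: RMSD after superposition is invariant under any rigid
    motion applied to either point set."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(angle=st.floats(-3.1, 3.1), axis_seed=st.integers(0, 10),
           tx=st.floats(-50, 50))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_rmsd_rigid_motion_invariant(angle, axis_seed, tx):
        rng = np.random.default_rng(99)
        a = rng.normal(0, 5, (10, 3))
        b = a + rng.normal(0, 0.8, (10, 3))
        _, _, base = superpose(a, b)
        axis = np.random.default_rng(axis_seed).normal(size=3)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
        _, _, moved = superpose(a @ rot.T + np.array([tx, 1.0, -2.0]), b)
        assert moved == pytest.approx(base, abs=1e-8)


def test_hetero_markers_default_to_nucleotide_records(three_residue_pdb):
    """A docked complex whose partners carry HETATM nucleotide records
    gets marker groups for the reaction coordinate automatically."""
    from dlptether.structure import load_structure
    het_line = ("HETATM   10  PB  GDP A   9      10.000  10.000  10.000"
                "  1.00  0.00           P\n")
    text = three_residue_pdb.replace("TER\n", het_line + "TER\n")
    p1 = load_structure(text)
    assert p1.hetero.sum() == 1
    p2 = load_structure(text.replace(" A ", " B "))
    from dlptether.docking import _merge
    template = _merge(p1, p2.transformed(np.eye(3), np.array([30.0, 0, 0])))
    corr1 = ResidueCorrespondence([(("A", i), ("A", i)) for i in (1, 2, 3)])
    corr2 = ResidueCorrespondence([(("B", i), ("B", i)) for i in (1, 2, 3)])
    d = build_heterodimer(p1, corr1, p2, corr2, template)
    assert set(d.marker_groups) == {"A", "B"}
    assert len(d.marker_groups["A"]) == 1
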