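"""Template-based construction of the candidate G-domain heterodimer.

Two partner structures are rigidly superposed onto the two chains of a
template homodimer through explicit residue correspondences (Cα-based
least-squares fits), merged into a docked complex, and the inter-partner
contacts of the docked pose are extracted at a tunable strength fraction
of the native contact strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import contacts as cmod
from .structure import AtomicStructure, BeadModel, StructureError, bead_model_to_structure

DEFAULT_CLASH_DISTANCE_ATOMIC = 2.5
DEFAULT_CLASH_DISTANCE_BEAD = 3.5


@dataclass
class ResidueCorrespondence:
    """One-to-one pairing of residues (mobile → template chain)."""

    pairs: list[tuple[tuple[str, int], tuple[str, int]]]

    def __post_init__(self):
        if len(self.pairs) < 3:
            raise ValueError("superposition needs at least 3 residue pairs")
        mob = [p[0] for p in self.pairs]
        tem = [p[1] for p in self.pairs]
        if len(set(mob)) != len(mob) or len(set(tem)) != len(tem):
            raise ValueError("correspondence must be one-to-one")

    @property
    def coverage(self) -> int:
        return len(self.pairs)


@dataclass
class DockedComplex:
    structure: AtomicStructure | BeadModel
    transforms: list[tuple[np.ndarray, np.ndarray]]  # (R, t) per partner
    clash_count: int
    partner_chains: tuple[frozenset, frozenset]
    marker_groups: dict = field(default_factory=dict)  # name -> atom index array

    def partner_masks(self):
        ch = np.asarray(self.structure.chain_id)
        a = np.isin(ch, list(self.partner_chains[0]))
        b = np.isin(ch, list(self.partner_chains[1]))
        return a, b


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition (Kabsch, reflection-corrected).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    Collinear (rank-deficient) point sets raise: the rotation about the
    degenerate axis would be arbitrary.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate sets required")
    if len(mobile) < 3:
        raise ValueError("need at least 3 points")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, sing, vt = np.linalg.svd(h)
    scale = max(np.abs(sing[0]), 1e-12)
    if sing[1] / scale < 1e-8:
        raise ValueError("degenerate (collinear) point sets")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def rotation_angle(rot: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, degrees."""
    c = (np.trace(rot) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _ca_coords(s, keys):
    """Cα coordinates (or bead coordinates) for ordered residue keys."""
    if isinstance(s, BeadModel):
        return np.array([s.coord[s.index_of(*k)] for k in keys])
    out = []
    for ch, ri in keys:
        mask = (s.chain_id == ch) & (s.res_id == ri) & (s.atom_name == "CA")
        hits = np.flatnonzero(mask)
        if len(hits) != 1:
            raise StructureError(f"correspondence residue ({ch}, {ri}) has no unique Cα")
        out.append(s.coord[hits[0]])
    return np.array(out)


def _merge(a: AtomicStructure, b: AtomicStructure) -> AtomicStructure:
    return AtomicStructure(
        np.concatenate([a.chain_id, b.chain_id]),
        np.concatenate([a.res_id, b.res_id]),
        np.concatenate([a.res_name, b.res_name]),
        np.concatenate([a.atom_name, b.atom_name]),
        np.concatenate([a.element, b.element]),
        np.concatenate([a.coord, b.coord]),
        np.concatenate([a.occupancy, b.occupancy]),
        np.concatenate([a.hetero, b.hetero]),
    )


def build_heterodimer(
    partner1,
    corr1: ResidueCorrespondence,
    partner2,
    corr2: ResidueCorrespondence,
    template: AtomicStructure,
    clash_distance: float | None = None,
) -> DockedComplex:
    """Dock two partners onto the two chains of a template dimer.

    Each partner is rigidly transformed so its correspondence residues fit
    the paired template residues; the merged pose is returned regardless of
    clashes, with the inter-partner clash count reported.  Partners may be
    atomic structures or bead models (both converted to Cα fits).
    """
    parts, transforms = [], []
    for partner, corr in ((partner1, corr1), (partner2, corr2)):
        mob = _ca_coords(partner, [p[0] for p in corr.pairs])
        ref = _ca_coords(template, [p[1] for p in corr.pairs])
        rot, trans, _ = superpose(mob, ref)
        if isinstance(partner, BeadModel):
            moved = partner.with_coords(partner.coord @ rot.T + trans)
            moved = bead_model_to_structure(moved)
        else:
            moved = partner.transformed(rot, trans)
        parts.append(moved)
        transforms.append((rot, trans))

    ch1 = frozenset(str(c) for c in parts[0].chain_id)
    ch2 = frozenset(str(c) for c in parts[1].chain_id)
    if ch1 & ch2:
        raise StructureError(f"partner chain ids overlap: {sorted(ch1 & ch2)}")

    if clash_distance is None:
        atomic = not (isinstance(partner1, BeadModel) or isinstance(partner2, BeadModel))
        clash_distance = (DEFAULT_CLASH_DISTANCE_ATOMIC if atomic
                          else DEFAULT_CLASH_DISTANCE_BEAD)
    t1, t2 = cKDTree(parts[0].coord), cKDTree(parts[1].coord)
    clash = int(t1.count_neighbors(t2, clash_distance))

    merged = _merge(parts[0], parts[1])
    # marker groups default to the bound-nucleotide HETATM records of each
    # partner when present; otherwise configuration supplies pocket residues
    markers = {}
    n0 = len(parts[0])
    het_a = np.flatnonzero(merged.hetero[:n0])
    het_b = n0 + np.flatnonzero(merged.hetero[n0:])
    if len(het_a) and len(het_b):
        markers = {"A": het_a, "B": het_b}
    return DockedComplex(merged, transforms, clash, (ch1, ch2), markers)


def interface_contacts(
    d: DockedComplex,
    strength: float,
    cutoff: float | None = None,
    shadow_radius: float = cmod.DEFAULT_SHADOW_RADIUS,
    method: str = "auto",
) -> cmod.ContactMap:
    """Inter-partner contacts of the docked pose at the given strength.

    ``method`` is ``"shadow"`` (atomic occlusion screening), ``"cutoff"``
    (Cα distance), or ``"auto"``: shadow when the pose has side-chain
    atoms, cutoff for Cα-only poses.  r0 values come from the docked pose.
    Returns an empty map with a warning if the partners share no contacts.
    """
    import logging

    s = d.structure
    has_sidechains = bool(np.any(np.asarray(s.atom_name) != "CA"))
    if method == "auto":
        method = "shadow" if has_sidechains else "cutoff"
    if method == "shadow":
        full = cmod.shadow_contacts(
            s, cutoff or cmod.DEFAULT_ATOMIC_CUTOFF, shadow_radius)
    else:
        from .structure import coarse_grain
        full = cmod.cutoff_contacts(coarse_grain(s),
                                    cutoff or cmod.DEFAULT_BEAD_CUTOFF)
    ch_a, ch_b = d.partner_chains
    inter = [
        cmod.Contact(c.a, c.b, c.r0, "interface", strength)
        for c in full
        if (c.a[0] in ch_a) != (c.b[0] in ch_a)
    ]
    if not inter:
        logging.getLogger(__name__).warning(
            "no inter-partner contacts in docked pose; returning empty map")
    return cmod.ContactMap(inter, "docked-interface",
                           {"strength": strength, "method": method})
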