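"""Synthetic toy systems with the statistical structure the pipeline assumes.

The real system is a heterotetramer in which two GTPase domains, each held
to a rigid central dimer by a short flexible linker, may dimerise across a
designated interface.  The toy analogue keeps exactly that statistical
topology at a size where the full pipeline runs in minutes: two compact
helix-bundle "domains" (native contact networks stabilising each), a
central helix-bundle "body", flexible contact-free linkers joining the
domains to the body, and a designated inter-domain interface contact set
whose strength is a tunable fraction of the native contact strength.

All generators are deterministic for a given seed; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import contacts as cmod
from .analysis import CoordinateSeries
from .contacts import Contact, ContactMap, cutoff_contacts
from .structure import BeadModel, StructureError, arc_points

HELIX_RISE = 1.5          # Å per residue
HELIX_TWIST = np.deg2rad(100.0)
HELIX_RADIUS = 2.3        # Å
AXIS_SPACING = 10.0       # Å between packed helix axes
TURN_RESIDUES = 3
LINKER_SPAN_PER_BOND = 3.8


@dataclass
class ToySpec:
    """Geometry of the toy tethered-dimer system.

    Defaults give 21-bead two-helix domains, a 19-bead central body and
    9-residue linkers (the linker length of the tetramer's flexible
    tether), ~80 beads total.  The scale is set by desk-scale kinetics:
    at the reference integration regime a bead-mass-1 domain diffuses
    with D = T*/(γ N), and domains of this size undergo many reversible
    encounter/release events within a few thousand reduced time units.
    """

    domain_helices: int = 2
    domain_helix_residues: int = 9
    central_helices: int = 2
    central_helix_residues: int = 8
    linker_lengths: tuple = (9, 9)
    target_interface_contacts: int = 15
    #: Cα contact cutoff for the toy maps; 10 Å gives the small two-helix
    #: domains a contact network dense enough to stay folded at T* = 0.92
    contact_cutoff: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.domain_helices < 2 or self.domain_helix_residues < 8:
            raise ValueError("domains need >= 2 helices of >= 8 residues")
        if min(self.central_helices, self.central_helix_residues) < 1:
            raise ValueError("all counts must be >= 1")
        if self.target_interface_contacts < 1:
            raise ValueError("need a positive interface contact target")


@dataclass
class TetheredPair:
    """Everything the pipeline needs about the generated system."""

    start: BeadModel            # monomeric (separated) configuration
    docked: BeadModel           # docked reference (native for the ff)
    intra_map: ContactMap
    interface_map: ContactMap   # strength 1.0; scale before use
    domain_slices: tuple        # (slice A, slice central, slice B)
    marker_groups: dict         # "A"/"B" -> bead index arrays (patch centres)
    patches: tuple              # interface bead indices on A and B
    linker_mask: np.ndarray
    reach: dict                 # max-reach report of the tether path
    spec: ToySpec = None


# ---------------------------------------------------------------------------
# helix bundles


def _grid_position(k: int) -> tuple[float, float]:
    """Serpentine 2-column packing: consecutive helices are 10 Å apart."""
    row, col = divmod(k, 2)
    if row % 2 == 1:
        col = 1 - col
    return col * AXIS_SPACING, row * AXIS_SPACING


def _helix(n: int, cx: float, cy: float, z0: float, up: bool,
           phase: float = 0.0) -> np.ndarray:
    t = np.arange(n)
    ang = phase + HELIX_TWIST * t
    z = z0 + HELIX_RISE * (t if up else (n - 1 - t))
    return np.column_stack([cx + HELIX_RADIUS * np.cos(ang),
                            cy + HELIX_RADIUS * np.sin(ang), z])


#: chord between consecutive helix connection points aimed for when
#: choosing helix phases: 3 turn residues give 4 bonds (15.2 Å of chain),
#: so a ~11.4 Å chord leaves a gentle outward arc
_TURN_TARGET_CHORD = 11.4


def make_helix_bundle(n_helices: int, residues_per_helix: int,
                      seed: int = 0, jitter: float = 0.0):
    """Ideal antiparallel Cα helix bundle.

    Helices (1.5 Å rise, 100° twist, 2.3 Å radius) are packed at 10 Å
    axis spacing in a serpentine grid and joined by 3-residue turns built
    on circular arcs bowing away from the bundle, so every consecutive Cα
    spacing is 3.8 ± 0.1 Å.  Each helix's phase is chosen
    deterministically so the turn chords stay near the relaxed length.
    Returns ``(coords, helix_slices)``.
    """
    centroid = np.array([*np.mean([_grid_position(k) for k in range(n_helices)],
                                  axis=0), HELIX_RISE * residues_per_helix / 2])
    coords_parts = []
    helix_slices = []
    pos = 0
    prev_end = None
    for k in range(n_helices):
        cx, cy = _grid_position(k)
        up = k % 2 == 0
        if prev_end is None:
            hel = _helix(residues_per_helix, cx, cy, 0.0, up)
        else:
            # pick the phase whose start bead gives the target turn chord
            best, hel = None, None
            for phase in np.arange(0, 2 * np.pi, np.pi / 18):
                trial = _helix(residues_per_helix, cx, cy, 0.0, up, phase)
                chord = np.linalg.norm(trial[0] - prev_end)
                score = abs(chord - _TURN_TARGET_CHORD)
                if best is None or score < best:
                    best, hel = score, trial
            mid = (prev_end + hel[0]) / 2
            turn = arc_points(prev_end, hel[0], TURN_RESIDUES,
                              LINKER_SPAN_PER_BOND,
                              bulge_toward=mid - centroid)
            coords_parts.append(turn)
            pos += TURN_RESIDUES
        coords_parts.append(hel)
        helix_slices.append(slice(pos, pos + residues_per_helix))
        pos += residues_per_helix
        prev_end = hel[-1]
    coords = np.concatenate(coords_parts)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter, coords.shape)
    return coords, helix_slices


def bundle_bead_model(n_helices: int, residues_per_helix: int,
                      chain: str = "A", seed: int = 0) -> BeadModel:
    coords, _ = make_helix_bundle(n_helices, residues_per_helix, seed)
    n = len(coords)
    bonded = np.ones(n, dtype=bool)
    bonded[0] = False
    return BeadModel(np.array([chain] * n), np.arange(1, n + 1), coords, bonded)


# ---------------------------------------------------------------------------
# the tethered pair


def _facing_helices(helix_slices, side: str):
    """Indices of the two helices on the ± x face of a 2-column bundle."""
    want_col = 1 if side == "+x" else 0
    out = []
    for k, sl in enumerate(helix_slices):
        col = _grid_position(k)[0] / AXIS_SPACING
        if int(col) == want_col:
            out.append(sl)
    return out


def make_tethered_pair(spec: ToySpec | None = None) -> TetheredPair:
    """Build the toy system: two domains tethered to a central body.

    The docked reference places the designated interface patches of the
    two domains in contact; the native contact maps are extracted from it.
    The monomeric start separates the domains to at least twice the docked
    marker distance.  Raises if the linkers cannot geometrically span the
    required anchor gaps.
    """
    spec = spec or ToySpec()
    dom_coords, dom_slices = make_helix_bundle(
        spec.domain_helices, spec.domain_helix_residues, spec.seed)
    cen_coords, _ = make_helix_bundle(
        spec.central_helices, spec.central_helix_residues, spec.seed)
    n_dom, n_cen = len(dom_coords), len(cen_coords)

    # docked placement: domains face each other across the x = 0 plane
    # (facing helix axes 9 Å apart — dimer-interface packing slightly
    # tighter than the bundle interior), offset sideways from the central
    # body so the docked pose leaves both tethers relaxed (~half extension)
    half_face = 4.5
    a_dock = dom_coords + np.array([-(AXIS_SPACING + half_face), 14.0, 10.0])
    b_dock = a_dock.copy()
    b_dock[:, 0] = -b_dock[:, 0]  # mirror image through x = 0

    chain = "T"
    nA, nB = spec.linker_lengths
    slc_a = slice(0, n_dom)
    slc_la = slice(n_dom, n_dom + nA)
    slc_c = slice(n_dom + nA, n_dom + nA + n_cen)
    slc_lb = slice(n_dom + nA + n_cen, n_dom + nA + n_cen + nB)
    slc_b = slice(n_dom + nA + n_cen + nB, 2 * n_dom + nA + n_cen + nB)
    total = 2 * n_dom + nA + nB + n_cen

    def assemble(a_pos, b_pos):
        parts = [a_pos]
        body_centroid = np.concatenate([a_pos, cen_coords, b_pos]).mean(axis=0)
        anchors = [(a_pos[-1], cen_coords[0], nA),
                   (cen_coords[-1], b_pos[0], nB)]
        for p, q, nl in anchors:
            d = np.linalg.norm(q - p)
            if d > LINKER_SPAN_PER_BOND * (nl + 1):
                raise StructureError(
                    "interface patches geometrically unreachable: linker of "
                    f"{nl} residues cannot span {d:.1f} Å")
            bulge = (p + q) / 2 - body_centroid  # arc bows away from bodies
            parts.append(arc_points(p, q, nl, bulge_toward=bulge)
                         if nl > 0 else np.zeros((0, 3)))
        coords = np.concatenate([parts[0], parts[1], cen_coords,
                                 parts[2], b_pos])
        bonded = np.ones(total, dtype=bool)
        bonded[0] = False
        linker = np.zeros(total, dtype=bool)
        linker[slc_la] = True
        linker[slc_lb] = True
        return BeadModel(np.array([chain] * total),
                         np.arange(1, total + 1), coords, bonded, linker)

    docked = assemble(a_dock, b_dock)

    # interface patches: beads of the facing helices of each domain
    a_face = _facing_helices(dom_slices, "+x")
    b_face = _facing_helices(dom_slices, "+x")  # mirrored → same local slices
    patch_a = np.concatenate([np.arange(sl.start, sl.stop) for sl in a_face])
    patch_b = np.concatenate([np.arange(sl.start, sl.stop) + slc_b.start
                              for sl in b_face])

    # intra-domain native contacts from the docked (native) pose
    body_masks = []
    for sl in (slc_a, slc_c, slc_b):
        mask = np.zeros(total, dtype=bool)
        mask[sl] = True
        body_masks.append(mask)
    intra = cutoff_contacts(docked, spec.contact_cutoff, include=body_masks[0])
    for mask in body_masks[1:]:
        intra = intra.merged(cutoff_contacts(docked, spec.contact_cutoff,
                                             include=mask))
    intra = ContactMap(list(intra), "cutoff",
                       {"cutoff": spec.contact_cutoff})

    # interface contacts: closest inter-patch pairs in the docked pose
    cand = []
    for i in patch_a:
        for j in patch_b:
            r = float(np.linalg.norm(docked.coord[i] - docked.coord[j]))
            if r <= spec.contact_cutoff:
                cand.append((r, int(i), int(j)))
    cand.sort()
    if len(cand) < spec.target_interface_contacts:
        raise StructureError(
            f"docked pose yields only {len(cand)} interface contacts "
            f"(target {spec.target_interface_contacts})")
    chosen = cand[: spec.target_interface_contacts]
    iface = ContactMap(
        sorted(
            (Contact((chain, int(docked.res_id[i])), (chain, int(docked.res_id[j])),
                     r, "interface", 1.0) for r, i, j in chosen),
            key=lambda c: (c.a, c.b),
        ),
        "docked-interface", {"cutoff": spec.contact_cutoff},
    )

    # marker groups: the middle bead of each facing helix
    # (nucleotide-pocket proxy)
    mid = spec.domain_helix_residues // 2
    marker_a = np.array([sl.start + mid for sl in a_face])
    marker_b = np.array([sl.start + mid + slc_b.start for sl in b_face])
    d_dock = float(np.linalg.norm(docked.coord[marker_a].mean(0)
                                  - docked.coord[marker_b].mean(0)))

    # monomeric start: swing the domains outward so the marker separation
    # is at least twice the docked distance
    a_start = a_dock + np.array([-12.0, -4.0, -4.0])
    b_start = b_dock + np.array([+12.0, -4.0, -4.0])
    start = assemble(a_start, b_start)
    d_start = float(np.linalg.norm(start.coord[marker_a].mean(0)
                                   - start.coord[marker_b].mean(0)))
    if d_start < 2 * d_dock:
        raise StructureError("monomeric start not separated enough")

    from .geometry import path_reach
    reach = path_reach(docked, int(marker_a[len(marker_a) // 2]),
                       int(marker_b[len(marker_b) // 2]))

    return TetheredPair(
        start=start, docked=docked, intra_map=intra, interface_map=iface,
        domain_slices=(slc_a, slc_c, slc_b),
        marker_groups={"A": marker_a, "B": marker_b},
        patches=(patch_a, patch_b),
        linker_mask=docked.is_linker.copy(),
        reach=reach,
        spec=spec,
    )


def domain_maps(pair: TetheredPair) -> dict:
    """Per-domain intra contact maps (for Q_intra folding checks)."""
    cutoff = pair.spec.contact_cutoff if pair.spec else 10.0
    out = {}
    for name, sl in zip(("A", "central", "B"),
                        pair.domain_slices):
        mask = np.zeros(len(pair.docked), dtype=bool)
        mask[sl] = True
        out[name] = cutoff_contacts(pair.docked, cutoff, include=mask)
    return out


def bead_index(m: BeadModel) -> dict:
    """(chain, residue) → bead index lookup for analysis routines."""
    return {(str(m.chain_id[i]), int(m.res_id[i])): i for i in range(len(m))}


# ---------------------------------------------------------------------------
# two-state fixture series


def make_two_state_series(stationary_occupancy: float, switch_rate: float,
                          length: int, seed: int = 0) -> CoordinateSeries:
    """Markov-chain Q_int series for occupancy/CI tests.

    A two-state chain with the given stationary dimerised fraction and
    overall switching scale emits Q values from two narrow bands
    (dimerised ~0.85, undimerised ~0.08).
    """
    p = stationary_occupancy
    if not 0 < p <= 1:
        raise ValueError("stationary occupancy must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p01 = min(switch_rate * p, 1.0)          # undimerised -> dimerised
    p10 = min(switch_rate * (1.0 - p), 1.0)  # dimerised -> undimerised
    state = rng.random() < p
    vals = np.empty(length)
    for k in range(length):
        if state:
            vals[k] = 0.80 + 0.10 * rng.random()
            if rng.random() < p10:
                state = False
        else:
            vals[k] = 0.03 + 0.10 * rng.random()
            if rng.random() < p01:
                state = True
    return CoordinateSeries(vals, "q_interface")
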