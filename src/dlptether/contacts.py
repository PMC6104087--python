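"""Native contact maps: shadow-screened atomic contacts and Cα cutoff maps.

The shadow map follows the occlusion idea used for structure-based models:
an atom pair within the cutoff is a native contact only if no third atom
"shadows" the line of sight between the two — i.e. no sphere of the shadow
radius centred on another atom intersects the open segment joining their
centres.  Surviving atomic contacts are aggregated to residue pairs with
the reference distance taken between Cα atoms.

For Cα-only models (synthetic fixtures, bead-level interfaces) a plain
distance-cutoff map is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomicStructure, BeadModel, StructureError

#: published shadow-map convention: atomic cutoff and screening radius
DEFAULT_ATOMIC_CUTOFF = 6.0
DEFAULT_SHADOW_RADIUS = 1.0
#: |i - j| >= 4 for intra-chain pairs; closer pairs are governed by the
#: bonded terms of a Cα model
DEFAULT_MIN_SEQ_SEP = 4
#: Cα-level cutoff for bead-model maps
DEFAULT_BEAD_CUTOFF = 8.0

ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class Contact:
    a: ResidueKey
    b: ResidueKey
    r0: float                  # Cα–Cα reference distance, Å
    kind: str = "intra"        # "intra" | "interface"
    strength: float = 1.0      # dimensionless multiplier on the contact ε

    def unordered(self) -> frozenset:
        return frozenset((self.a, self.b))


@dataclass
class ContactMap:
    contacts: list[Contact]
    provenance: str = "cutoff"   # shadow | cutoff | docked-interface
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for c in self.contacts:
            key = c.unordered()
            if key in seen:
                raise ValueError(f"duplicate contact {c.a}–{c.b}")
            seen.add(key)
            if c.r0 <= 0:
                raise ValueError(f"non-positive reference distance for {c.a}–{c.b}")
            if c.strength < 0:
                raise ValueError("negative contact strength")

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def pair_set(self) -> set:
        return {c.unordered() for c in self.contacts}

    def scaled(self, strength: float, kind: str | None = None) -> "ContactMap":
        return ContactMap(
            [Contact(c.a, c.b, c.r0, kind or c.kind, strength) for c in self.contacts],
            self.provenance, dict(self.parameters),
        )

    def merged(self, other: "ContactMap") -> "ContactMap":
        return ContactMap(self.contacts + other.contacts,
                          f"{self.provenance}+{other.provenance}")


def _sequence_ok(chain_a, res_a, chain_b, res_b, min_sep):
    if chain_a != chain_b:
        return True
    return abs(res_a - res_b) >= min_sep


def _segment_occluded(a, b, points, radius):
    """True if any sphere (centre in `points`, given radius) cuts segment a–b.

    Closed-segment minimum distance is used; for continuous geometry this is
    equivalent to intersection with the open segment, and the endpoints'
    own atoms are excluded by the caller, so an atom never occludes itself.
    """
    if len(points) == 0:
        return False
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return False
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a + t[:, None] * ab
    d2 = np.einsum("ij,ij->i", points - closest, points - closest)
    return bool(np.any(d2 < radius * radius))


def _ca_lookup(s: AtomicStructure) -> dict:
    out = {}
    for i in np.flatnonzero(s.atom_name == "CA"):
        out[(str(s.chain_id[i]), int(s.res_id[i]))] = s.coord[i]
    return out


def shadow_contacts(
    s: AtomicStructure,
    cutoff: float = DEFAULT_ATOMIC_CUTOFF,
    shadow_radius: float = DEFAULT_SHADOW_RADIUS,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
) -> ContactMap:
    """Shadow-screened native contact map at residue resolution.

    Hydrogens are ignored.  A residue pair is a contact if at least one of
    its atom pairs is within ``cutoff`` and survives occlusion screening
    against every other atom.  The reference distance r0 is the Cα–Cα
    distance; residue pairs where either residue lacks a Cα are dropped.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if shadow_radius < 0:
        raise ValueError("shadow radius must be non-negative")
    heavy = s.subset(s.element != "H")
    if heavy.n_residues < 2:
        raise StructureError("need at least 2 residues")

    coords = heavy.coord
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    ca = _ca_lookup(heavy)

    residue_pairs: dict[frozenset, bool] = {}
    for i, j in pairs:
        ra = (str(heavy.chain_id[i]), int(heavy.res_id[i]))
        rb = (str(heavy.chain_id[j]), int(heavy.res_id[j]))
        if ra == rb:
            continue
        if not _sequence_ok(ra[0], ra[1], rb[0], rb[1], min_seq_sep):
            continue
        key = frozenset((ra, rb))
        if residue_pairs.get(key, False):
            continue  # already has a surviving atomic contact
        a, b = coords[i], coords[j]
        # occluders must lie near the segment: search a ball about the
        # midpoint covering it plus the shadow radius
        mid = (a + b) / 2
        reach = np.linalg.norm(b - a) / 2 + shadow_radius + 1e-9
        cand = tree.query_ball_point(mid, reach)
        cand = [k for k in cand if k != i and k != j]
        occluded = _segment_occluded(a, b, coords[cand], shadow_radius)
        residue_pairs[key] = residue_pairs.get(key, False) or not occluded

    contacts = []
    for key, alive in sorted(residue_pairs.items(),
                             key=lambda kv: tuple(sorted(kv[0]))):
        if not alive:
            continue
        ra, rb = sorted(key)
        if ra not in ca or rb not in ca:
            continue
        r0 = float(np.linalg.norm(ca[ra] - ca[rb]))
        contacts.append(Contact(ra, rb, r0, "intra", 1.0))
    return ContactMap(contacts, "shadow", {
        "cutoff": cutoff, "shadow_radius": shadow_radius,
        "min_seq_sep": min_seq_sep,
    })


def cutoff_contacts(
    m: BeadModel,
    cutoff: float = DEFAULT_BEAD_CUTOFF,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
    include: np.ndarray | None = None,
) -> ContactMap:
    """Cα distance-cutoff contact map for bead models.

    ``include`` optionally restricts the map to beads where the mask is
    True (e.g. one folded domain).  Linker beads never carry contacts.
    The sequence-separation rule uses bead indices along the chain, which
    for bead models equals the residue separation.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    mask = np.ones(len(m), dtype=bool) if include is None else np.asarray(include, bool)
    mask = mask & ~m.is_linker
    idx = np.flatnonzero(mask)
    tree = cKDTree(m.coord[idx])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contacts = []
    for ii, jj in sorted(map(tuple, pairs)):
        i, j = int(idx[ii]), int(idx[jj])
        same_chain = m.chain_id[i] == m.chain_id[j]
        if same_chain and abs(i - j) < min_seq_sep:
            continue
        ra = (str(m.chain_id[i]), int(m.res_id[i]))
        rb = (str(m.chain_id[j]), int(m.res_id[j]))
        r0 = float(np.linalg.norm(m.coord[i] - m.coord[j]))
        contacts.append(Contact(*sorted((ra, rb)), r0, "intra", 1.0))
    contacts.sort(key=lambda c: (c.a, c.b))
    return ContactMap(contacts, "cutoff",
                      {"cutoff": cutoff, "min_seq_sep": min_seq_sep})


# ---------------------------------------------------------------------------
# text interchange


def write_contacts(cm: ContactMap) -> str:
    """One line per contact: chainA resA chainB resB r0_Å class strength."""
    params = " ".join(f"{k}={v}" for k, v in sorted(cm.parameters.items()))
    lines = [f"# provenance={cm.provenance} {params}".rstrip() + "\n"]
    for c in cm.contacts:
        lines.append(
            f"{c.a[0]} {c.a[1]} {c.b[0]} {c.b[1]} {c.r0:.6f} {c.kind} {c.strength:g}\n"
        )
    return "".join(lines)


def read_contacts(text: str) -> ContactMap:
    provenance, params = "unknown", {}
    contacts = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k == "provenance":
                        provenance = v
                    else:
                        try:
                            params[k] = float(v)
                        except ValueError:
                            params[k] = v
            continue
        ca, ra, cb, rb, r0, kind, strength = line.split()
        contacts.append(Contact((ca, int(ra)), (cb, int(rb)),
                                float(r0), kind, float(strength)))
    return ContactMap(contacts, provenance, params)
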