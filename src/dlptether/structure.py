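"""Atomic structures, Cα bead models, and their file formats.

Structures are read from PDB or mmCIF text via biotite and held in a thin
array-backed container (:class:`AtomicStructure`).  Coarse-graining places
one bead per residue at the Cα position (:class:`BeadModel`), the
representation used by the forcefield and dynamics modules.  Chain breaks
(excised segments, inter-chain junctions) are flagged explicitly and can be
re-joined with a geometric loop builder (:func:`bridge_gap`) that inserts
flexible, contact-free linker beads on a circular arc.

All coordinates are in Å.  Reduced simulation units are owned by
:mod:`dlptether.dynamics`.
"""

from __future__ import annotations

import io
import logging
import struct
from dataclasses import dataclass, field, replace

import numpy as np

import biotite.structure as bst
import biotite.structure.io.pdb as bpdb
import biotite.structure.io.pdbx as bpdbx

logger = logging.getLogger(__name__)

#: Cα–Cα distance above which consecutive residues are treated as a chain
#: break (trans-peptide Cα–Cα is ~3.8 Å; 4.5 Å allows strained geometry).
CHAIN_BREAK_DISTANCE = 4.5

#: Virtual bond length used for inserted linker beads.
LINKER_BOND_LENGTH = 3.8


class StructureError(ValueError):
    """Malformed or unusable structural input."""


@dataclass
class AtomicStructure:
    """All-atom coordinates with chain/residue/atom labels.

    One entry per atom after alternate-location resolution.  Residue indices
    strictly increase within a chain; positions are finite.
    """

    chain_id: np.ndarray   # (n,) str
    res_id: np.ndarray     # (n,) int
    res_name: np.ndarray   # (n,) str, 3-letter code
    atom_name: np.ndarray  # (n,) str
    element: np.ndarray    # (n,) str
    coord: np.ndarray      # (n, 3) float, Å
    occupancy: np.ndarray = None  # (n,) float
    hetero: np.ndarray = None     # (n,) bool, True for HETATM records

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.occupancy is None:
            self.occupancy = np.ones(len(self.coord))
        if self.hetero is None:
            self.hetero = np.zeros(len(self.coord), dtype=bool)
        self.hetero = np.asarray(self.hetero, dtype=bool)
        for name in ("chain_id", "res_id", "res_name", "atom_name", "element"):
            setattr(self, name, np.asarray(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        if self.coord.ndim != 2 or self.coord.shape[1] != 3:
            raise StructureError("coordinates must be (n, 3)")
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")
        n = len(self.coord)
        for name in ("chain_id", "res_id", "res_name", "atom_name", "element"):
            if len(getattr(self, name)) != n:
                raise StructureError(f"length mismatch in field {name}")
        seen = set()
        for key in zip(self.chain_id, self.res_id, self.atom_name):
            if key in seen:
                raise StructureError(f"duplicate atom after alt-loc resolution: {key}")
            seen.add(key)
        # residue order strictly increases within each chain
        for ch in np.unique(self.chain_id):
            rid = self.res_id[self.chain_id == ch]
            order = rid[np.diff(np.concatenate([[rid[0] - 1], rid])) != 0]
            if np.any(np.diff(np.unique(rid)) <= 0) or np.any(np.diff(order) < 0):
                raise StructureError(f"residue indices not increasing in chain {ch}")

    def __len__(self) -> int:
        return len(self.coord)

    @property
    def n_residues(self) -> int:
        return len(set(zip(self.chain_id, self.res_id)))

    def subset(self, mask: np.ndarray) -> "AtomicStructure":
        return AtomicStructure(
            self.chain_id[mask], self.res_id[mask], self.res_name[mask],
            self.atom_name[mask], self.element[mask], self.coord[mask],
            self.occupancy[mask], self.hetero[mask],
        )

    def select_residues(self, chain: str, residues) -> np.ndarray:
        """Boolean mask of atoms in ``chain`` whose residue id is in ``residues``."""
        residues = set(int(r) for r in residues)
        return (self.chain_id == chain) & np.array(
            [int(r) in residues for r in self.res_id]
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicStructure":
        out = replace(self)
        out.coord = self.coord @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def residue_keys(self):
        """Ordered unique (chain, res_id) pairs."""
        keys, seen = [], set()
        for ch, ri in zip(self.chain_id, self.res_id):
            k = (str(ch), int(ri))
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys


@dataclass
class BeadModel:
    """One bead per residue at the Cα position; mass 1 in reduced units.

    ``bonded_to_prev[i]`` is False at chain starts and flagged breaks:
    bead ``i`` then has no bonded connection to bead ``i-1``.  ``is_linker``
    marks beads inserted by :func:`bridge_gap`, which carry no native
    contacts and no dihedral bias in the forcefield.
    """

    chain_id: np.ndarray       # (n,) str
    res_id: np.ndarray         # (n,) int
    coord: np.ndarray          # (n, 3) float, Å
    bonded_to_prev: np.ndarray  # (n,) bool
    is_linker: np.ndarray = None  # (n,) bool

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        self.chain_id = np.asarray(self.chain_id)
        self.res_id = np.asarray(self.res_id, dtype=int)
        self.bonded_to_prev = np.asarray(self.bonded_to_prev, dtype=bool)
        if self.is_linker is None:
            self.is_linker = np.zeros(len(self.coord), dtype=bool)
        self.is_linker = np.asarray(self.is_linker, dtype=bool)
        if len(self.coord) and self.bonded_to_prev[0]:
            raise StructureError("first bead cannot bond to a predecessor")

    def __len__(self) -> int:
        return len(self.coord)

    @property
    def n_bonds(self) -> int:
        return int(self.bonded_to_prev.sum())

    def index_of(self, chain: str, res: int) -> int:
        hits = np.flatnonzero((self.chain_id == chain) & (self.res_id == int(res)))
        if len(hits) != 1:
            raise KeyError(f"bead ({chain}, {res}) not found uniquely")
        return int(hits[0])

    def with_coords(self, coord: np.ndarray) -> "BeadModel":
        out = replace(self)
        out.coord = np.asarray(coord, dtype=float)
        return out


# ---------------------------------------------------------------------------
# loading


def _resolve_altlocs(arr, altloc_ids, occupancy):
    """Keep the highest-occupancy alt-loc per (chain, res, atom); ties → first."""
    n = arr.array_length()
    keep = np.ones(n, dtype=bool)
    best: dict = {}
    for i in range(n):
        key = (arr.chain_id[i], int(arr.res_id[i]), arr.atom_name[i])
        if altloc_ids is not None and altloc_ids[i] not in (".", "", " ", "\x00"):
            if key in best:
                j = best[key]
                if occupancy[i] > occupancy[j]:
                    keep[j] = False
                    best[key] = i
                else:
                    keep[i] = False
            else:
                best[key] = i
        else:
            if key in best:
                keep[i] = False  # duplicate full-occupancy record; keep first
            best.setdefault(key, i)
    return keep


def load_structure(text: str, model: int = 1, fmt: str | None = None) -> AtomicStructure:
    """Parse PDB or mmCIF text into an :class:`AtomicStructure`.

    Parameters
    ----------
    text:
        File content.  The format is auto-detected (mmCIF starts with
        ``data_`` or contains a ``_atom_site`` loop) unless ``fmt`` is
        given as ``"pdb"`` or ``"cif"``.
    model:
        1-based model number to extract.

    Alternate locations are resolved to the highest occupancy (ties: first
    record in the file).  Insertion codes are rejected: silently renumbering
    them would corrupt residue-keyed contact maps.
    """
    if fmt is None:
        head = text.lstrip()[:500]
        fmt = "cif" if (head.startswith("data_") or "_atom_site." in text) else "pdb"
    try:
        if fmt == "cif":
            f = bpdbx.CIFFile.read(io.StringIO(text))
            arr = bpdbx.get_structure(
                f, model=model, altloc="all",
                extra_fields=["occupancy"],
            )
        else:
            f = bpdb.PDBFile.read(io.StringIO(text))
            arr = bpdb.get_structure(
                f, model=model, altloc="all",
                extra_fields=["occupancy"],
            )
    except Exception as exc:  # biotite raises various subclasses
        raise StructureError(f"cannot parse {fmt} input: {exc}") from exc
    if arr.array_length() == 0:
        raise StructureError(f"model {model} is empty")
    if hasattr(arr, "ins_code") and np.any(arr.ins_code != ""):
        bad = np.flatnonzero(arr.ins_code != "")[0]
        raise StructureError(
            "insertion codes are not supported "
            f"(first at chain {arr.chain_id[bad]} residue {arr.res_id[bad]})"
        )
    occ = (arr.occupancy if "occupancy" in arr.get_annotation_categories()
           else np.ones(arr.array_length()))
    altloc_ids = getattr(arr, "altloc_id", None)
    keep = _resolve_altlocs(arr, altloc_ids, occ)
    arr = arr[keep]
    occ = occ[keep]
    return AtomicStructure(
        chain_id=arr.chain_id.astype(str),
        res_id=arr.res_id.astype(int),
        res_name=arr.res_name.astype(str),
        atom_name=arr.atom_name.astype(str),
        element=arr.element.astype(str),
        coord=np.asarray(arr.coord, dtype=float),
        occupancy=occ.astype(float),
        hetero=(np.asarray(arr.hetero, dtype=bool)
                if "hetero" in arr.get_annotation_categories()
                else None),
    )


def to_biotite(s: AtomicStructure):
    """Convert to a biotite AtomArray (used by the SASA backend)."""
    arr = bst.AtomArray(len(s))
    arr.chain_id = s.chain_id.astype("U4")
    arr.res_id = s.res_id
    arr.res_name = s.res_name.astype("U5")
    arr.atom_name = s.atom_name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.coord = np.asarray(s.coord, dtype=np.float32)
    return arr


# ---------------------------------------------------------------------------
# writing (documented PDB subset: ATOM records, single/multi model)


def _pdb_atom_line(serial, name, res_name, chain, res_id, xyz, occ, element,
                   hetero=False):
    name_f = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    record = "HETATM" if hetero else "ATOM  "
    return (
        f"{record}{serial:5d} {name_f} {res_name:>3s} {chain[:1]:1s}{res_id:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


def write_pdb(s: AtomicStructure) -> str:
    """Serialise to the documented single-model PDB subset (ATOM + TER + END)."""
    lines, serial = [], 1
    prev_chain = None
    for i in range(len(s)):
        if prev_chain is not None and s.chain_id[i] != prev_chain:
            lines.append("TER\n")
        lines.append(_pdb_atom_line(
            serial, str(s.atom_name[i]), str(s.res_name[i]), str(s.chain_id[i]),
            int(s.res_id[i]), s.coord[i], float(s.occupancy[i]), str(s.element[i]),
            bool(s.hetero[i]),
        ))
        serial += 1
        prev_chain = s.chain_id[i]
    lines.append("TER\nEND\n")
    return "".join(lines)


def bead_model_to_structure(m: BeadModel) -> AtomicStructure:
    """Represent a bead model as a Cα-only structure (atom name ``CA``)."""
    n = len(m)
    return AtomicStructure(
        chain_id=m.chain_id,
        res_id=m.res_id,
        res_name=np.array(["GLY"] * n),
        atom_name=np.array(["CA"] * n),
        element=np.array(["C"] * n),
        coord=m.coord,
    )


def write_bead_pdb(m: BeadModel) -> str:
    return write_pdb(bead_model_to_structure(m))


def write_trajectory_pdb(m: BeadModel, frames: np.ndarray) -> str:
    """Multi-model PDB for interchange (one MODEL per frame)."""
    out = []
    for k, frame in enumerate(frames, start=1):
        out.append(f"MODEL     {k:4d}\n")
        body = write_pdb(bead_model_to_structure(m.with_coords(frame)))
        out.append(body.replace("END\n", "ENDMDL\n"))
    out.append("END\n")
    return "".join(out)


_TRAJ_MAGIC = b"DLPT"


def save_trajectory(path, frames: np.ndarray, stride: int, seed: int) -> None:
    """Binary trajectory container.

    Layout: magic ``DLPT``, uint32 version, uint64 frame count, uint64 bead
    count, uint64 stride, int64 seed, then float32 xyz frames in C order.
    """
    frames = np.asarray(frames, dtype=np.float32)
    with open(path, "wb") as fh:
        fh.write(_TRAJ_MAGIC)
        fh.write(struct.pack("<IQQQq", 1, frames.shape[0], frames.shape[1],
                             int(stride), int(seed)))
        fh.write(frames.tobytes())


def load_trajectory(path):
    """Read the binary container; returns (frames, stride, seed)."""
    with open(path, "rb") as fh:
        if fh.read(4) != _TRAJ_MAGIC:
            raise StructureError(f"{path}: not a trajectory container")
        _ver, nframe, nbead, stride, seed = struct.unpack("<IQQQq", fh.read(36))
        data = np.frombuffer(fh.read(), dtype=np.float32)
    frames = data.reshape(nframe, nbead, 3).astype(float)
    return frames, int(stride), int(seed)


def fetch_structure(accession: str, fmt: str = "cif",
                    timeout: float = 30.0) -> str:
    """Download a deposited structure's text from the RCSB archive.

    Purely optional online convenience (``fmt`` is ``"cif"`` or
    ``"pdb"``); everything else in the package works offline.  Returns
    the file content for :func:`load_structure`.
    """
    from urllib.request import urlopen

    ext = "cif" if fmt == "cif" else "pdb"
    url = f"https://files.rcsb.org/download/{accession.upper()}.{ext}"
    with urlopen(url, timeout=timeout) as fh:
        return fh.read().decode()


# ---------------------------------------------------------------------------
# coarse-graining


def coarse_grain(s: AtomicStructure, keep=None) -> BeadModel:
    """Reduce to one bead per residue at the Cα position.

    Parameters
    ----------
    keep:
        Optional residue selection: ``{chain: iterable of residue ids}``.
        ``None`` keeps everything.  Residues lacking a Cα atom are skipped
        with a warning.  Chain breaks are flagged where consecutive selected
        residues are non-adjacent in sequence or their Cα atoms are more
        than 4.5 Å apart.
    """
    is_ca = s.atom_name == "CA"
    if keep is not None:
        sel = np.zeros(len(s), dtype=bool)
        for ch, residues in keep.items():
            sel |= s.select_residues(ch, residues)
        is_ca = is_ca & sel
        n_sel_res = len({k for k in zip(s.chain_id[sel], s.res_id[sel])})
    else:
        n_sel_res = s.n_residues
    if not np.any(is_ca):
        raise StructureError("no Cα atoms in selection")

    chains, res_ids, coords = [], [], []
    for i in np.flatnonzero(is_ca):
        chains.append(str(s.chain_id[i]))
        res_ids.append(int(s.res_id[i]))
        coords.append(s.coord[i])
    n_skipped = n_sel_res - len(coords)
    if n_skipped:
        logger.warning("coarse_grain: %d selected residue(s) lack a Cα atom "
                       "and were skipped", n_skipped)
    if len(coords) < 2:
        raise StructureError("selection resolves to fewer than 2 Cα residues")

    coords = np.asarray(coords)
    bonded = np.zeros(len(coords), dtype=bool)
    for i in range(1, len(coords)):
        same_chain = chains[i] == chains[i - 1]
        adjacent = res_ids[i] == res_ids[i - 1] + 1
        close = np.linalg.norm(coords[i] - coords[i - 1]) <= CHAIN_BREAK_DISTANCE
        bonded[i] = same_chain and adjacent and close
    return BeadModel(np.array(chains), np.array(res_ids), coords, bonded)


# ---------------------------------------------------------------------------
# gap bridging


def arc_points(p: np.ndarray, q: np.ndarray, n: int,
               segment_length: float = LINKER_BOND_LENGTH,
               bulge_toward: np.ndarray | None = None) -> np.ndarray:
    """``n`` points on a circular arc from ``p`` to ``q``.

    The arc is chosen so all ``n + 1`` chord segments have equal length
    ``<= segment_length`` (exactly ``segment_length`` whenever the gap is
    shorter than the fully extended chain; a straight line at the limit).
    The arc plane is picked deterministically from the gap direction
    unless ``bulge_toward`` hints where the arc should bow out.
    """
    from scipy.optimize import brentq

    p, q = np.asarray(p, float), np.asarray(q, float)
    d = float(np.linalg.norm(q - p))
    max_span = segment_length * (n + 1)
    if d > max_span * (1 + 1e-9):
        raise StructureError(
            f"gap unbridgeable at given n: distance {d:.2f} Å > "
            f"{segment_length} Å × {n + 1}"
        )
    if d >= max_span * (1 - 1e-9):  # straight, fully extended
        ts = np.arange(1, n + 1) / (n + 1)
        return p + np.outer(ts, q - p)

    # equal chords of length `segment_length` on a circular arc:
    # solve sin((n+1) b / 2) / sin(b / 2) = d / segment_length for the
    # per-segment subtended angle b
    ratio = d / segment_length

    def h(b):
        return np.sin((n + 1) * b / 2) / np.sin(b / 2) - ratio

    b_hi = 2 * np.pi / (n + 1)
    beta = brentq(h, 1e-12, b_hi * (1 - 1e-12))
    radius = segment_length / (2 * np.sin(beta / 2))

    u = (q - p) / d if d > 1e-12 else np.array([1.0, 0.0, 0.0])
    # off-axis direction: requested bulge (orthogonalised), else the axis
    # least aligned with u
    trial = None
    if bulge_toward is not None:
        cand = np.asarray(bulge_toward, float)
        cand = cand - np.dot(cand, u) * u
        if np.linalg.norm(cand) > 1e-6:
            trial = cand
    if trial is None:
        trial = np.eye(3)[np.argmin(np.abs(u))]
    v = trial - np.dot(trial, u) * u
    v /= np.linalg.norm(v)
    # circle centre sits off the chord midpoint along -v
    total = (n + 1) * beta
    h_mid = radius * np.cos(total / 2)
    centre = (p + q) / 2 - v * h_mid
    # start angle: p relative to centre in the (v, u) plane
    rel = p - centre
    ang0 = np.arctan2(np.dot(rel, u), np.dot(rel, v))
    angs = ang0 + np.arange(1, n + 1) * beta
    return centre + radius * (np.outer(np.cos(angs), v) + np.outer(np.sin(angs), u))


def bridge_gap(m: BeadModel, gap: tuple[int, int], n_residues: int) -> BeadModel:
    """Insert ``n_residues`` flexible linker beads across a flagged break.

    ``gap`` is ``(i, j)`` with ``j == i + 1`` and ``bonded_to_prev[j]``
    False.  The inserted beads lie on a smooth arc with consecutive spacing
    ≤ 3.8 Å, the break flag is cleared, and the new beads are marked as
    linker (no native contacts, no dihedral bias downstream).
    """
    i, j = gap
    if j != i + 1:
        raise StructureError("gap must be between consecutive beads (i, i+1)")
    if m.bonded_to_prev[j]:
        raise StructureError(f"beads {i}-{j} are not a chain break")
    if n_residues < 1:
        raise StructureError("need at least one inserted residue")
    new = arc_points(m.coord[i], m.coord[j], n_residues)

    # synthetic residue ids continue from bead i; must not collide with j
    rid0 = int(m.res_id[i])
    new_ids = rid0 + 1 + np.arange(n_residues)
    if m.chain_id[i] == m.chain_id[j] and new_ids[-1] >= m.res_id[j]:
        raise StructureError(
            "no residue-number room to insert linker "
            f"({n_residues} beads between residues {rid0} and {int(m.res_id[j])})"
        )

    chain = np.concatenate([m.chain_id[:j], [m.chain_id[i]] * n_residues, m.chain_id[j:]])
    rid = np.concatenate([m.res_id[:j], new_ids, m.res_id[j:]])
    coord = np.concatenate([m.coord[:j], new, m.coord[j:]])
    bonded = np.concatenate([m.bonded_to_prev[:j], [True] * n_residues, m.bonded_to_prev[j:]])
    bonded[j + n_residues] = True  # clear the break: j now bonds to last insert
    linker = np.concatenate([m.is_linker[:j], [True] * n_residues, m.is_linker[j:]])
    return BeadModel(chain, rid, coord, bonded, linker)
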