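"""Cα structure-based potential with Gaussian native contacts.

The potential is the standard Cα Gō-type form whose global minimum is the
native structure: stiff harmonic bonds and angles at their native values,
a cosine dihedral bias, one Gaussian attractive well per native contact
centred at the native pair distance (combined with a short-range r^-12
core so the well depth at r0 is exactly −ε), and a purely repulsive
excluded volume between all remaining non-local pairs:

    V_bond     = k_b (r − r0)²
    V_angle    = k_a (θ − θ0)²
    V_dihedral = k_d [(1 − cos Δφ) + ½ (1 − cos 3Δφ)]
    V_contact  = ε [(1 + (r_ex/r)¹²)(1 − exp(−(r − r0)²/2σ²)) − 1]
    V_excl     = (r_ex/r)¹²      (truncated at 12 Å)

Energies are in reduced units of the native contact strength ε = 1.
Interface contacts carry a tunable strength factor multiplying ε — the
mechanism probed by the tethered-dimerisation pipeline, where an interface
half as strong as the native contacts is the reference condition.

Linker beads inserted by :func:`dlptether.structure.bridge_gap` are an
entropic tether: they receive bonds (r0 = 3.8 Å) and angles (θ0 = 2.0 rad)
at standard stiffness but no dihedral bias and no contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .contacts import ContactMap
from .structure import BeadModel

# published Cα+Gaussian convention defaults (reduced units, Å)
DEFAULT_PARAMS = dict(
    k_bond=200.0,      # ε/Å²
    k_angle=40.0,      # ε/rad²
    k_dihedral=1.0,    # ε
    epsilon=1.0,       # contact depth, the energy unit
    sigma=0.5,         # Gaussian well width, Å
    r_excluded=4.0,    # excluded-volume radius, Å
    ev_min_seq_sep=4,
    linker_bond_r0=3.8,
    linker_angle_th0=2.0,
)


class ForceFieldError(ValueError):
    pass


def _angle(a, b, c):
    u, v = a - b, c - b
    cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cos, -1, 1)))


def _dihedral(a, b, c, d):
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    return float(np.arctan2(y, x))


@dataclass
class ForceField:
    """Assembled term arrays ready for the evaluation kernels."""

    n_beads: int
    bond_idx: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angle_idx: np.ndarray
    angle_th0: np.ndarray
    angle_k: np.ndarray
    dihedral_idx: np.ndarray
    dihedral_phi0: np.ndarray
    dihedral_k: np.ndarray
    contact_idx: np.ndarray
    contact_r0: np.ndarray
    contact_eps: np.ndarray   # ε × strength factor per contact
    sigma: float
    r_excluded: float
    ev_pairs: np.ndarray      # candidate excluded-volume pairs
    params: dict = field(default_factory=dict)

    @property
    def contact_energy_minimum(self) -> float:
        """Σ ε over contacts: depth of the fully native contact energy."""
        return float(self.contact_eps.sum())


def build_forcefield(
    m: BeadModel,
    intra_map: ContactMap,
    interface_map: ContactMap | None = None,
    params: dict | None = None,
) -> ForceField:
    """Assemble the potential for a bead model and its contact maps.

    Bonds/angles/dihedrals follow chain connectivity only (no terms across
    unbridged breaks).  Each contact-map entry becomes one Gaussian well
    with ε scaled by its strength factor.  Every remaining pair with
    sequence separation ≥ 4 (or inter-chain) gets excluded volume.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    n = len(m)
    coords = m.coord
    bonded = m.bonded_to_prev
    linker = m.is_linker

    bonds, b_r0 = [], []
    for i in range(1, n):
        if bonded[i]:
            bonds.append((i - 1, i))
            if linker[i] or linker[i - 1]:
                b_r0.append(p["linker_bond_r0"])
            else:
                b_r0.append(float(np.linalg.norm(coords[i] - coords[i - 1])))

    angles, a_th0 = [], []
    for i in range(2, n):
        if bonded[i] and bonded[i - 1]:
            angles.append((i - 2, i - 1, i))
            if linker[i - 2:i + 1].any():
                a_th0.append(p["linker_angle_th0"])
            else:
                a_th0.append(_angle(coords[i - 2], coords[i - 1], coords[i]))

    dihedrals, d_phi0 = [], []
    for i in range(3, n):
        if bonded[i] and bonded[i - 1] and bonded[i - 2]:
            if linker[i - 3:i + 1].any():
                continue  # tether beads carry no dihedral bias
            dihedrals.append((i - 3, i - 2, i - 1, i))
            d_phi0.append(_dihedral(coords[i - 3], coords[i - 2],
                                    coords[i - 1], coords[i]))

    index = {(str(m.chain_id[i]), int(m.res_id[i])): i for i in range(n)}
    con_idx, con_r0, con_eps = [], [], []
    seen_pairs = set()
    missing = []
    maps = [intra_map] + ([interface_map] if interface_map is not None else [])
    for cmap in maps:
        for c in cmap:
            if c.a not in index or c.b not in index:
                missing.append((c.a, c.b))
                continue
            i, j = index[c.a], index[c.b]
            if linker[i] or linker[j]:
                raise ForceFieldError(
                    f"contact {c.a}–{c.b} touches an inserted linker bead")
            key = frozenset((i, j))
            if key in seen_pairs:
                raise ForceFieldError(f"contact {c.a}–{c.b} defined twice")
            seen_pairs.add(key)
            con_idx.append((i, j))
            con_r0.append(c.r0)
            con_eps.append(p["epsilon"] * c.strength)
    if missing:
        raise ForceFieldError(
            f"contacts reference residues absent from the model: {missing}")

    # excluded volume: all pairs with |i-j| >= ev_min_seq_sep or inter-chain,
    # excluding contact pairs
    sep = int(p["ev_min_seq_sep"])
    chain = m.chain_id
    ev = []
    for i in range(n):
        for j in range(i + 1, n):
            if chain[i] == chain[j] and j - i < sep:
                continue
            if frozenset((i, j)) in seen_pairs:
                continue
            ev.append((i, j))

    def arr2(x, w):
        return (np.array(x, dtype=np.int64).reshape(-1, w) if x
                else np.zeros((0, w), dtype=np.int64))

    return ForceField(
        n_beads=n,
        bond_idx=arr2(bonds, 2), bond_r0=np.array(b_r0, float),
        bond_k=np.full(len(bonds), p["k_bond"]),
        angle_idx=arr2(angles, 3), angle_th0=np.array(a_th0, float),
        angle_k=np.full(len(angles), p["k_angle"]),
        dihedral_idx=arr2(dihedrals, 4), dihedral_phi0=np.array(d_phi0, float),
        dihedral_k=np.full(len(dihedrals), p["k_dihedral"]),
        contact_idx=arr2(con_idx, 2), contact_r0=np.array(con_r0, float),
        contact_eps=np.array(con_eps, float),
        sigma=float(p["sigma"]), r_excluded=float(p["r_excluded"]),
        ev_pairs=arr2(ev, 2),
        params=p,
    )


_TERM_NAMES = ("bond", "angle", "dihedral", "contact", "excluded")


def energy(ff: ForceField, coords: np.ndarray) -> dict:
    """Per-term-class energies and total, in reduced units."""
    e, _ = _evaluate(ff, coords)
    out = {name: float(e[i]) for i, name in enumerate(_TERM_NAMES)}
    out["total"] = float(e.sum())
    return out


def forces(ff: ForceField, coords: np.ndarray) -> np.ndarray:
    """Analytic −∂V/∂x, (n, 3) in reduced units/Å."""
    _, f = _evaluate(ff, coords)
    return f


def _evaluate(ff: ForceField, coords: np.ndarray):
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.shape != (ff.n_beads, 3):
        raise ForceFieldError(
            f"coordinate shape {coords.shape} != ({ff.n_beads}, 3)")
    if not np.all(np.isfinite(coords)):
        raise ForceFieldError("non-finite coordinates")
    try:
        e, f = _kernels.compute_energy_forces(
            coords,
            ff.bond_idx, ff.bond_r0, ff.bond_k,
            ff.angle_idx, ff.angle_th0, ff.angle_k,
            ff.dihedral_idx, ff.dihedral_phi0, ff.dihedral_k,
            ff.contact_idx, ff.contact_r0, ff.contact_eps, ff.sigma,
            ff.r_excluded, ff.ev_pairs, ff.ev_pairs.shape[0],
        )
    except ZeroDivisionError as exc:
        raise ForceFieldError("coincident beads: r = 0 in a pair term") from exc
    if np.any(np.isnan(e)):
        raise ForceFieldError("coincident beads: r = 0 in a pair term")
    return e, f


def minimize(ff: ForceField, coords: np.ndarray,
             force_tol: float = 1e-3, max_iter: int = 20000,
             step0: float = 1e-3) -> np.ndarray:
    """Steepest descent with backtracking until max |force| < force_tol.

    Energy is non-increasing across accepted steps.  Raises on NaN energy
    (divergence).  Returns new coordinates; the input is not modified.
    """
    x = np.array(coords, dtype=float)
    e, f = _evaluate(ff, x)
    v = e.sum()
    step = step0
    for _ in range(max_iter):
        fmax = np.abs(f).max() if len(f) else 0.0
        if fmax < force_tol:
            break
        trial = x + step * f
        try:
            e_t, f_t = _evaluate(ff, trial)
        except ForceFieldError:
            step *= 0.5
            continue
        v_t = e_t.sum()
        if not np.isfinite(v_t):
            raise ForceFieldError("minimisation diverged (NaN energy)")
        if v_t <= v:
            x, v, f = trial, v_t, f_t
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return x


# ---------------------------------------------------------------------------
# text topology interchange


def write_topology(ff: ForceField) -> str:
    out = [f"[header] n_beads {ff.n_beads} sigma {ff.sigma:g} "
           f"r_excluded {ff.r_excluded:g}\n"]
    out.append("[bonds]\n")
    for (i, j), r0, k in zip(ff.bond_idx, ff.bond_r0, ff.bond_k):
        out.append(f"{i} {j} {r0:.6f} {k:g}\n")
    out.append("[angles]\n")
    for (i, j, l), t0, k in zip(ff.angle_idx, ff.angle_th0, ff.angle_k):
        out.append(f"{i} {j} {l} {t0:.8f} {k:g}\n")
    out.append("[dihedrals]\n")
    for (i, j, l, mm), p0, k in zip(ff.dihedral_idx, ff.dihedral_phi0, ff.dihedral_k):
        out.append(f"{i} {j} {l} {mm} {p0:.8f} {k:g}\n")
    out.append("[contacts]\n")
    for (i, j), r0, ep in zip(ff.contact_idx, ff.contact_r0, ff.contact_eps):
        out.append(f"{i} {j} {r0:.6f} {ep:.8g}\n")
    out.append("[exclusions]\n")
    for i, j in ff.ev_pairs:
        out.append(f"{i} {j}\n")
    return "".join(out)


def read_topology(text: str) -> ForceField:
    section = None
    head = {}
    data = {k: [] for k in ("bonds", "angles", "dihedrals", "contacts", "exclusions")}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("[header]"):
            toks = line.split()[1:]
            head = {toks[i]: toks[i + 1] for i in range(0, len(toks), 2)}
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        data[section].append(line.split())

    def cols(rows, nidx):
        if not rows:
            return (np.zeros((0, nidx), np.int64),
                    *([np.zeros(0)] * (len(rows[0]) - nidx if rows else 0)))
        arr = np.array(rows, dtype=float)
        return (arr[:, :nidx].astype(np.int64),
                *[arr[:, k] for k in range(nidx, arr.shape[1])])

    b = cols(data["bonds"], 2) if data["bonds"] else (np.zeros((0, 2), np.int64), np.zeros(0), np.zeros(0))
    a = cols(data["angles"], 3) if data["angles"] else (np.zeros((0, 3), np.int64), np.zeros(0), np.zeros(0))
    d = cols(data["dihedrals"], 4) if data["dihedrals"] else (np.zeros((0, 4), np.int64), np.zeros(0), np.zeros(0))
    c = cols(data["contacts"], 2) if data["contacts"] else (np.zeros((0, 2), np.int64), np.zeros(0), np.zeros(0))
    ev = (np.array(data["exclusions"], dtype=np.int64)
          if data["exclusions"] else np.zeros((0, 2), np.int64))
    return ForceField(
        n_beads=int(head["n_beads"]),
        bond_idx=b[0], bond_r0=b[1], bond_k=b[2],
        angle_idx=a[0], angle_th0=a[1], angle_k=a[2],
        dihedral_idx=d[0], dihedral_phi0=d[1], dihedral_k=d[2],
        contact_idx=c[0], contact_r0=c[1], contact_eps=c[2],
        sigma=float(head["sigma"]), r_excluded=float(head["r_excluded"]),
        ev_pairs=ev,
    )
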