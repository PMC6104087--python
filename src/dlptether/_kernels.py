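"""Numba kernels: potential-energy terms, forces, and the Langevin loop.

All arrays are float64/int64 and pre-assembled by the forcefield module.
The excluded-volume potential is truncated at EV_CUTOFF exactly, which
makes the Verlet-list path bit-identical to a brute-force evaluation over
all candidate pairs.
"""

import numpy as np
from numba import njit

EV_CUTOFF = 8.0   # Å; (r_ex/r)^12 ≈ 2.4e-4 ε here for r_ex = 4 Å
EV_SKIN = 2.0     # Verlet-list skin beyond the cutoff


@njit(cache=True, fastmath=True)
def _bond_ef(coords, idx, r0, k, forces):
    e = 0.0
    for n in range(idx.shape[0]):
        i, j = idx[n, 0], idx[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            return np.nan
        dr = r - r0[n]
        e += k[n] * dr * dr
        g = 2.0 * k[n] * dr / r
        forces[i, 0] -= g * dx
        forces[i, 1] -= g * dy
        forces[i, 2] -= g * dz
        forces[j, 0] += g * dx
        forces[j, 1] += g * dy
        forces[j, 2] += g * dz
    return e


@njit(cache=True, fastmath=True)
def _angle_ef(coords, idx, th0, k, forces):
    e = 0.0
    for n in range(idx.shape[0]):
        i, j, l = idx[n, 0], idx[n, 1], idx[n, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[l, 0] - coords[j, 0]
        vy = coords[l, 1] - coords[j, 1]
        vz = coords[l, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        th = np.arccos(c)
        dth = th - th0[n]
        e += k[n] * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        pref = 2.0 * k[n] * dth / s  # dV/dθ · (−1/sinθ) sign folded below
        # dθ/du = −(1/sinθ) dcosθ/du ;  dcosθ/du = v/(|u||v|) − cosθ u/|u|²
        gux = pref * (vx / (nu * nv) - c * ux / (nu * nu))
        guy = pref * (vy / (nu * nv) - c * uy / (nu * nu))
        guz = pref * (vz / (nu * nv) - c * uz / (nu * nu))
        gvx = pref * (ux / (nu * nv) - c * vx / (nv * nv))
        gvy = pref * (uy / (nu * nv) - c * vy / (nv * nv))
        gvz = pref * (uz / (nu * nv) - c * vz / (nv * nv))
        # force = −dV/dr; dV/du = −pref·(...) so force on i is −dV/du = −gu·(−1)
        forces[i, 0] += gux
        forces[i, 1] += guy
        forces[i, 2] += guz
        forces[l, 0] += gvx
        forces[l, 1] += gvy
        forces[l, 2] += gvz
        forces[j, 0] -= gux + gvx
        forces[j, 1] -= guy + gvy
        forces[j, 2] -= guz + gvz
    return e


@njit(cache=True, fastmath=True)
def _dihedral_ef(coords, idx, phi0, k, forces):
    e = 0.0
    for n in range(idx.shape[0]):
        i, j, l, m = idx[n, 0], idx[n, 1], idx[n, 2], idx[n, 3]
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[l, 0] - coords[j, 0]
        b2y = coords[l, 1] - coords[j, 1]
        b2z = coords[l, 2] - coords[j, 2]
        b3x = coords[m, 0] - coords[l, 0]
        b3y = coords[m, 1] - coords[l, 1]
        b3z = coords[m, 2] - coords[l, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        x = n1x * n2x + n1y * n2y + n1z * n2z
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        y = (cx * b2x + cy * b2y + cz * b2z) / nb2
        phi = np.arctan2(y, x)
        d = phi - phi0[n]
        e += k[n] * ((1.0 - np.cos(d)) + 0.5 * (1.0 - np.cos(3.0 * d)))
        dv = k[n] * (np.sin(d) + 1.5 * np.sin(3.0 * d))
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue  # collinear: torque undefined, potential flat
        a1 = -nb2 / n1sq   # dφ/dr_i = a1 · n1
        a4 = nb2 / n2sq    # dφ/dr_m = a4 · n2
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        dix = a1 * n1x
        diy = a1 * n1y
        diz = a1 * n1z
        dmx = a4 * n2x
        dmy = a4 * n2y
        dmz = a4 * n2z
        djx = -(1.0 + s12) * dix + s32 * dmx
        djy = -(1.0 + s12) * diy + s32 * dmy
        djz = -(1.0 + s12) * diz + s32 * dmz
        dlx = s12 * dix - (1.0 + s32) * dmx
        dly = s12 * diy - (1.0 + s32) * dmy
        dlz = s12 * diz - (1.0 + s32) * dmz
        forces[i, 0] -= dv * dix
        forces[i, 1] -= dv * diy
        forces[i, 2] -= dv * diz
        forces[j, 0] -= dv * djx
        forces[j, 1] -= dv * djy
        forces[j, 2] -= dv * djz
        forces[l, 0] -= dv * dlx
        forces[l, 1] -= dv * dly
        forces[l, 2] -= dv * dlz
        forces[m, 0] -= dv * dmx
        forces[m, 1] -= dv * dmy
        forces[m, 2] -= dv * dmz
    return e


@njit(cache=True, fastmath=True)
def _contact_ef(coords, idx, r0, eps, sigma, rex, forces):
    e = 0.0
    for n in range(idx.shape[0]):
        i, j = idx[n, 0], idx[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            return np.nan
        u = rex * rex / (r * r)
        rep = u * u * u
        rep = rep * rep
        dr = r - r0[n]
        gauss = np.exp(-dr * dr / (2.0 * sigma * sigma))
        e += eps[n] * ((1.0 + rep) * (1.0 - gauss) - 1.0)
        # dV/dr = ε[ −12 rep/r (1−G) + (1+rep) G (r−r0)/σ² ]
        dvdr = eps[n] * (-12.0 * rep / r * (1.0 - gauss)
                         + (1.0 + rep) * gauss * dr / (sigma * sigma))
        g = dvdr / r
        forces[i, 0] -= g * dx
        forces[i, 1] -= g * dy
        forces[i, 2] -= g * dz
        forces[j, 0] += g * dx
        forces[j, 1] += g * dy
        forces[j, 2] += g * dz
    return e


@njit(cache=True, fastmath=True)
def _ev_ef(coords, pairs, npairs, rex, forces):
    e = 0.0
    cut2 = EV_CUTOFF * EV_CUTOFF
    for n in range(npairs):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2 or r2 < 1e-24:
            continue
        inv = rex * rex / r2
        rep = inv * inv * inv
        rep = rep * rep
        e += rep
        g = -12.0 * rep / r2
        forces[i, 0] -= g * dx
        forces[i, 1] -= g * dy
        forces[i, 2] -= g * dz
        forces[j, 0] += g * dx
        forces[j, 1] += g * dy
        forces[j, 2] += g * dz
    return e


@njit(cache=True, fastmath=True)
def _ef_into(coords,
             bond_idx, bond_r0, bond_k,
             ang_idx, ang_th0, ang_k,
             dih_idx, dih_phi0, dih_k,
             con_idx, con_r0, con_eps, sigma, rex,
             ev_pairs, n_ev, forces, energies):
    forces[:] = 0.0
    energies[0] = _bond_ef(coords, bond_idx, bond_r0, bond_k, forces)
    energies[1] = _angle_ef(coords, ang_idx, ang_th0, ang_k, forces)
    energies[2] = _dihedral_ef(coords, dih_idx, dih_phi0, dih_k, forces)
    energies[3] = _contact_ef(coords, con_idx, con_r0, con_eps, sigma, rex, forces)
    energies[4] = _ev_ef(coords, ev_pairs, n_ev, rex, forces)


@njit(cache=True, fastmath=True)
def compute_energy_forces(coords,
                          bond_idx, bond_r0, bond_k,
                          ang_idx, ang_th0, ang_k,
                          dih_idx, dih_phi0, dih_k,
                          con_idx, con_r0, con_eps, sigma, rex,
                          ev_pairs, n_ev):
    """Full potential. Returns (energies[5], forces); energies are
    [bond, angle, dihedral, contact, excluded-volume]."""
    forces = np.zeros_like(coords)
    energies = np.zeros(5)
    _ef_into(coords, bond_idx, bond_r0, bond_k, ang_idx, ang_th0, ang_k,
             dih_idx, dih_phi0, dih_k, con_idx, con_r0, con_eps, sigma, rex,
             ev_pairs, n_ev, forces, energies)
    return energies, forces


@njit(cache=True, fastmath=True)
def _build_verlet(coords, cand_pairs, out_pairs):
    """Fill out_pairs with candidate pairs within EV_CUTOFF + EV_SKIN."""
    lim2 = (EV_CUTOFF + EV_SKIN) ** 2
    n = 0
    for m in range(cand_pairs.shape[0]):
        i, j = cand_pairs[m, 0], cand_pairs[m, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        if dx * dx + dy * dy + dz * dz < lim2:
            out_pairs[n, 0] = i
            out_pairs[n, 1] = j
            n += 1
    return n


@njit(cache=True, fastmath=True)
def langevin_run_kernel(coords0, vel0,
                        bond_idx, bond_r0, bond_k,
                        ang_idx, ang_th0, ang_k,
                        dih_idx, dih_phi0, dih_k,
                        con_idx, con_r0, con_eps, sigma, rex,
                        cand_pairs,
                        mobile,
                        n_steps, dt, gamma, temperature, stride, seed,
                        frames, energies, kinetic):
    """BAOAB Langevin leapfrog in reduced units (mass 1, k_B = 1).

    Frames and per-frame potential energies are written into the
    pre-allocated output arrays (frame 0 is the start).  Returns
    (status, step): status 0 on success, 1 on energy divergence.
    """
    np.random.seed(seed)
    coords = coords0.copy()
    vel = vel0.copy()
    nb = coords.shape[0]

    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(temperature * (1.0 - c1 * c1))

    verlet = np.empty_like(cand_pairs)
    n_verlet = _build_verlet(coords, cand_pairs, verlet)
    ref_coords = coords.copy()
    half_skin = EV_SKIN / 2.0

    forces = np.zeros_like(coords)
    e = np.zeros(5)
    _ef_into(coords, bond_idx, bond_r0, bond_k, ang_idx, ang_th0, ang_k,
             dih_idx, dih_phi0, dih_k, con_idx, con_r0, con_eps, sigma, rex,
             verlet, n_verlet, forces, e)
    frames[0] = coords
    energies[0] = e.sum()
    ke = 0.0
    for i in range(nb):
        ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
    kinetic[0] = 0.5 * ke

    frame = 1
    for step in range(1, n_steps + 1):
        for i in range(nb):
            if mobile[i]:
                for c in range(3):
                    vel[i, c] += 0.5 * dt * forces[i, c]
                    coords[i, c] += 0.5 * dt * vel[i, c]
        if c2 > 0.0:
            noise = np.random.standard_normal(nb * 3)
            for i in range(nb):
                if mobile[i]:
                    for c in range(3):
                        vel[i, c] = c1 * vel[i, c] + c2 * noise[3 * i + c]
        elif c1 < 1.0:
            for i in range(nb):
                if mobile[i]:
                    for c in range(3):
                        vel[i, c] = c1 * vel[i, c]
        for i in range(nb):
            if mobile[i]:
                for c in range(3):
                    coords[i, c] += 0.5 * dt * vel[i, c]

        # refresh Verlet list when any bead moved more than half the skin
        max_d2 = 0.0
        for i in range(nb):
            dx = coords[i, 0] - ref_coords[i, 0]
            dy = coords[i, 1] - ref_coords[i, 1]
            dz = coords[i, 2] - ref_coords[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_d2:
                max_d2 = d2
        if max_d2 > half_skin * half_skin:
            n_verlet = _build_verlet(coords, cand_pairs, verlet)
            for i in range(nb):
                ref_coords[i, 0] = coords[i, 0]
                ref_coords[i, 1] = coords[i, 1]
                ref_coords[i, 2] = coords[i, 2]

        _ef_into(coords, bond_idx, bond_r0, bond_k, ang_idx, ang_th0, ang_k,
                 dih_idx, dih_phi0, dih_k, con_idx, con_r0, con_eps, sigma, rex,
                 verlet, n_verlet, forces, e)
        for i in range(nb):
            if mobile[i]:
                for c in range(3):
                    vel[i, c] += 0.5 * dt * forces[i, c]

        if step % stride == 0:
            total = e.sum()
            if not np.isfinite(total) or np.abs(total) > 1e9:
                return 1, step
            frames[frame] = coords
            energies[frame] = total
            ke = 0.0
            for i in range(nb):
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            kinetic[frame] = 0.5 * ke
            frame += 1
    return 0, n_steps
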