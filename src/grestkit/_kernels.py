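"""Numba-compiled inner loops for ToySystem evaluation.

The pure-numpy routines in :mod:`grestkit.model` stay the reference
implementation (and serve the finite-difference and decomposition
tests); these kernels reproduce them exactly — same functional forms,
same IUPAC dihedral convention — with explicit loops so that replica
propagation runs at compiled speed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["forces_into", "energy_components", "baoab_block", "scaled_energies"]


@njit(cache=False)
def _accumulate_forces(x, lam, F,
                       bonds, bond_k, bond_r0, bond_e,
                       angles, angle_k, angle_t0, angle_e,
                       dihedrals, dih_K, dih_n, dih_d, dih_e,
                       pairs, pair_eps, pair_sig, pair_qq, vdw_e, elec_e,
                       r_atoms, r_k, r_x0,
                       c_atoms, c_k, c_rad, c_x0):
    """Add scaled forces for one replica; returns the scaled energy."""
    energy = 0.0
    for t in range(bonds.shape[0]):
        i, j = bonds[t, 0], bonds[t, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        w = lam ** bond_e[t] if bond_e[t] != 0.0 else 1.0
        energy += w * 0.5 * bond_k[t] * (r - bond_r0[t]) ** 2
        c = -w * bond_k[t] * (r - bond_r0[t]) / r
        F[i, 0] += c * dx
        F[i, 1] += c * dy
        F[i, 2] += c * dz
        F[j, 0] -= c * dx
        F[j, 1] -= c * dy
        F[j, 2] -= c * dz
    for t in range(angles.shape[0]):
        ia, ib, ic = angles[t, 0], angles[t, 1], angles[t, 2]
        ux = x[ia, 0] - x[ib, 0]
        uy = x[ia, 1] - x[ib, 1]
        uz = x[ia, 2] - x[ib, 2]
        vx = x[ic, 0] - x[ib, 0]
        vy = x[ic, 1] - x[ib, 1]
        vz = x[ic, 2] - x[ib, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ux /= nu
        uy /= nu
        uz /= nu
        vx /= nv
        vy /= nv
        vz /= nv
        ct = ux * vx + uy * vy + uz * vz
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        st = np.sqrt(max(1.0 - ct * ct, 1e-12))
        theta = np.arccos(ct)
        w = lam ** angle_e[t] if angle_e[t] != 0.0 else 1.0
        energy += w * 0.5 * angle_k[t] * (theta - angle_t0[t]) ** 2
        dU = w * angle_k[t] * (theta - angle_t0[t])
        # grad theta wrt outer atoms
        gAx = -(vx - ct * ux) / (st * nu)
        gAy = -(vy - ct * uy) / (st * nu)
        gAz = -(vz - ct * uz) / (st * nu)
        gCx = -(ux - ct * vx) / (st * nv)
        gCy = -(uy - ct * vy) / (st * nv)
        gCz = -(uz - ct * vz) / (st * nv)
        F[ia, 0] -= dU * gAx
        F[ia, 1] -= dU * gAy
        F[ia, 2] -= dU * gAz
        F[ic, 0] -= dU * gCx
        F[ic, 1] -= dU * gCy
        F[ic, 2] -= dU * gCz
        F[ib, 0] += dU * (gAx + gCx)
        F[ib, 1] += dU * (gAy + gCy)
        F[ib, 2] += dU * (gAz + gCz)
    for t in range(dihedrals.shape[0]):
        i0, i1, i2, i3 = dihedrals[t, 0], dihedrals[t, 1], dihedrals[t, 2], dihedrals[t, 3]
        b1x = x[i1, 0] - x[i0, 0]
        b1y = x[i1, 1] - x[i0, 1]
        b1z = x[i1, 2] - x[i0, 2]
        b2x = x[i2, 0] - x[i1, 0]
        b2y = x[i2, 1] - x[i1, 1]
        b2z = x[i2, 2] - x[i1, 2]
        b3x = x[i3, 0] - x[i2, 0]
        b3y = x[i3, 1] - x[i2, 1]
        b3z = x[i3, 2] - x[i2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        sin_t = (cx * b2x + cy * b2y + cz * b2z) / nb2
        cos_t = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sin_t, cos_t)
        w = lam ** dih_e[t] if dih_e[t] != 0.0 else 1.0
        energy += w * dih_K[t] * (1.0 + np.cos(dih_n[t] * phi - dih_d[t]))
        dU = -w * dih_K[t] * dih_n[t] * np.sin(dih_n[t] * phi - dih_d[t])
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        fA = -nb2 / n1sq
        tAx = fA * n1x
        tAy = fA * n1y
        tAz = fA * n1z
        fD = nb2 / n2sq
        tDx = fD * n2x
        tDy = fD * n2y
        tDz = fD * n2z
        sc = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        tc = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        gBx = -(1.0 + sc) * tAx + tc * tDx
        gBy = -(1.0 + sc) * tAy + tc * tDy
        gBz = -(1.0 + sc) * tAz + tc * tDz
        gCx = sc * tAx - (1.0 + tc) * tDx
        gCy = sc * tAy - (1.0 + tc) * tDy
        gCz = sc * tAz - (1.0 + tc) * tDz
        F[i0, 0] -= dU * tAx
        F[i0, 1] -= dU * tAy
        F[i0, 2] -= dU * tAz
        F[i1, 0] -= dU * gBx
        F[i1, 1] -= dU * gBy
        F[i1, 2] -= dU * gBz
        F[i2, 0] -= dU * gCx
        F[i2, 1] -= dU * gCy
        F[i2, 2] -= dU * gCz
        F[i3, 0] -= dU * tDx
        F[i3, 1] -= dU * tDy
        F[i3, 2] -= dU * tDz
    for t in range(pairs.shape[0]):
        i, j = pairs[t, 0], pairs[t, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        sr6 = (pair_sig[t] * pair_sig[t] / r2) ** 3
        wv = lam ** vdw_e[t] if vdw_e[t] != 0.0 else 1.0
        we = lam ** elec_e[t] if elec_e[t] != 0.0 else 1.0
        energy += wv * 4.0 * pair_eps[t] * (sr6 * sr6 - sr6) + we * pair_qq[t] / r
        coef = -(wv * 4.0 * pair_eps[t] * (6.0 * sr6 - 12.0 * sr6 * sr6) / r2
                 - we * pair_qq[t] / (r2 * r))
        F[i, 0] += coef * dx
        F[i, 1] += coef * dy
        F[i, 2] += coef * dz
        F[j, 0] -= coef * dx
        F[j, 1] -= coef * dy
        F[j, 2] -= coef * dz
    for t in range(r_atoms.shape[0]):
        i = r_atoms[t]
        dx = x[i, 0] - r_x0[t, 0]
        dy = x[i, 1] - r_x0[t, 1]
        dz = x[i, 2] - r_x0[t, 2]
        energy += 0.5 * r_k[t] * (dx * dx + dy * dy + dz * dz)
        F[i, 0] -= r_k[t] * dx
        F[i, 1] -= r_k[t] * dy
        F[i, 2] -= r_k[t] * dz
    for t in range(c_atoms.shape[0]):
        i = c_atoms[t]
        dx = x[i, 0] - c_x0[t, 0]
        dy = x[i, 1] - c_x0[t, 1]
        dz = x[i, 2] - c_x0[t, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > c_rad[t]:
            ex = r - c_rad[t]
            energy += 0.5 * c_k[t] * ex * ex
            coef = -c_k[t] * ex / r
            F[i, 0] += coef * dx
            F[i, 1] += coef * dy
            F[i, 2] += coef * dz
    return energy


@njit(cache=False)
def forces_into(X, lam, F, args):
    """Scaled forces for a batch of replicas; X, F are (M, N, 3)."""
    (bonds, bond_k, bond_r0, bond_e,
     angles, angle_k, angle_t0, angle_e,
     dihedrals, dih_K, dih_n, dih_d, dih_e,
     pairs, pair_eps, pair_sig, pair_qq, vdw_e, elec_e,
     r_atoms, r_k, r_x0,
     c_atoms, c_k, c_rad, c_x0) = args
    F[:] = 0.0
    for m in range(X.shape[0]):
        _accumulate_forces(X[m], lam[m], F[m],
                           bonds, bond_k, bond_r0, bond_e,
                           angles, angle_k, angle_t0, angle_e,
                           dihedrals, dih_K, dih_n, dih_d, dih_e,
                           pairs, pair_eps, pair_sig, pair_qq, vdw_e, elec_e,
                           r_atoms, r_k, r_x0,
                           c_atoms, c_k, c_rad, c_x0)


@njit(cache=False)
def scaled_energies(X, lam, args):
    """Scaled potential per replica for (M, N, 3) coordinates."""
    (bonds, bond_k, bond_r0, bond_e,
     angles, angle_k, angle_t0, angle_e,
     dihedrals, dih_K, dih_n, dih_d, dih_e,
     pairs, pair_eps, pair_sig, pair_qq, vdw_e, elec_e,
     r_atoms, r_k, r_x0,
     c_atoms, c_k, c_rad, c_x0) = args
    M = X.shape[0]
    out = np.empty(M)
    scratch = np.zeros_like(X[0])
    for m in range(M):
        scratch[:] = 0.0
        out[m] = _accumulate_forces(X[m], lam[m], scratch,
                                    bonds, bond_k, bond_r0, bond_e,
                                    angles, angle_k, angle_t0, angle_e,
                                    dihedrals, dih_K, dih_n, dih_d, dih_e,
                                    pairs, pair_eps, pair_sig, pair_qq, vdw_e, elec_e,
                                    r_atoms, r_k, r_x0,
                           c_atoms, c_k, c_rad, c_x0)
    return out


@njit(cache=False)
def baoab_block(X, V, lam, noise, dt, c1, c2, inv_m, args):
    """BAOAB Langevin steps for all replicas.

    noise is (M, n_steps, N, 3) pre-drawn standard normals (one block per
    replica stream); c2 is (N,) per-atom noise amplitude, inv_m (N,).
    """
    M, n_steps = noise.shape[0], noise.shape[1]
    half = 0.5 * dt
    F = np.zeros_like(X)
    forces_into(X, lam, F, args)
    for s in range(n_steps):
        for m in range(M):
            for i in range(X.shape[1]):
                for d in range(3):
                    V[m, i, d] += half * F[m, i, d] * inv_m[i]
                    X[m, i, d] += half * V[m, i, d]
                    V[m, i, d] = c1 * V[m, i, d] + c2[i] * noise[m, s, i, d]
                    X[m, i, d] += half * V[m, i, d]
        forces_into(X, lam, F, args)
        for m in range(M):
            for i in range(X.shape[1]):
                for d in range(3):
                    V[m, i, d] += half * F[m, i, d] * inv_m[i]


@njit(cache=False)
def energy_components(X, lam_dummy, exponents, term_ei, args):
    """Exponent-grouped energies: (comps (M, E), evv (M)).

    term_ei maps each term (in the fixed order bonds, angles, dihedrals,
    vdw pairs, elec pairs, restraints) to an exponent index, -1 for the
    untempered solvent-solvent bucket.
    """
    (bonds, bond_k, bond_r0, bond_e,
     angles, angle_k, angle_t0, angle_e,
     dihedrals, dih_K, dih_n, dih_d, dih_e,
     pairs, pair_eps, pair_sig, pair_qq, vdw_e, elec_e,
     r_atoms, r_k, r_x0,
     c_atoms, c_k, c_rad, c_x0) = args
    M = X.shape[0]
    E = exponents.shape[0]
    comps = np.zeros((M, E))
    evv = np.zeros(M)
    for m in range(M):
        x = X[m]
        tix = 0
        for t in range(bonds.shape[0]):
            i, j = bonds[t, 0], bonds[t, 1]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            e = 0.5 * bond_k[t] * (r - bond_r0[t]) ** 2
            k = term_ei[tix]
            if k < 0:
                evv[m] += e
            else:
                comps[m, k] += e
            tix += 1
        for t in range(angles.shape[0]):
            ia, ib, ic = angles[t, 0], angles[t, 1], angles[t, 2]
            ux = x[ia, 0] - x[ib, 0]
            uy = x[ia, 1] - x[ib, 1]
            uz = x[ia, 2] - x[ib, 2]
            vx = x[ic, 0] - x[ib, 0]
            vy = x[ic, 1] - x[ib, 1]
            vz = x[ic, 2] - x[ib, 2]
            nu = np.sqrt(ux * ux + uy * uy + uz * uz)
            nv = np.sqrt(vx * vx + vy * vy + vz * vz)
            ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            theta = np.arccos(ct)
            e = 0.5 * angle_k[t] * (theta - angle_t0[t]) ** 2
            k = term_ei[tix]
            if k < 0:
                evv[m] += e
            else:
                comps[m, k] += e
            tix += 1
        for t in range(dihedrals.shape[0]):
            i0, i1, i2, i3 = dihedrals[t, 0], dihedrals[t, 1], dihedrals[t, 2], dihedrals[t, 3]
            b1x = x[i1, 0] - x[i0, 0]
            b1y = x[i1, 1] - x[i0, 1]
            b1z = x[i1, 2] - x[i0, 2]
            b2x = x[i2, 0] - x[i1, 0]
            b2y = x[i2, 1] - x[i1, 1]
            b2z = x[i2, 2] - x[i1, 2]
            b3x = x[i3, 0] - x[i2, 0]
            b3y = x[i3, 1] - x[i2, 1]
            b3z = x[i3, 2] - x[i2, 2]
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            cx = n1y * n2z - n1z * n2y
            cy = n1z * n2x - n1x * n2z
            cz = n1x * n2y - n1y * n2x
            phi = np.arctan2((cx * b2x + cy * b2y + cz * b2z) / nb2,
                             n1x * n2x + n1y * n2y + n1z * n2z)
            e = dih_K[t] * (1.0 + np.cos(dih_n[t] * phi - dih_d[t]))
            k = term_ei[tix]
            if k < 0:
                evv[m] += e
            else:
                comps[m, k] += e
            tix += 1
        for t in range(pairs.shape[0]):
            i, j = pairs[t, 0], pairs[t, 1]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = np.sqrt(r2)
            sr6 = (pair_sig[t] * pair_sig[t] / r2) ** 3
            ev = 4.0 * pair_eps[t] * (sr6 * sr6 - sr6)
            ec = pair_qq[t] / r
            k = term_ei[tix]
            if k < 0:
                evv[m] += ev
            else:
                comps[m, k] += ev
            tix += 1
            k = term_ei[tix]
            if k < 0:
                evv[m] += ec
            else:
                comps[m, k] += ec
            tix += 1
        for t in range(r_atoms.shape[0]):
            i = r_atoms[t]
            dx = x[i, 0] - r_x0[t, 0]
            dy = x[i, 1] - r_x0[t, 1]
            dz = x[i, 2] - r_x0[t, 2]
            evv[m] += 0.5 * r_k[t] * (dx * dx + dy * dy + dz * dz)
        for t in range(c_atoms.shape[0]):
            i = c_atoms[t]
            dx = x[i, 0] - c_x0[t, 0]
            dy = x[i, 1] - c_x0[t, 1]
            dz = x[i, 2] - c_x0[t, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > c_rad[t]:
                evv[m] += 0.5 * c_k[t] * (r - c_rad[t]) ** 2
    return comps, evv
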