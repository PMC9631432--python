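"""Numba force and integrator kernels for the CA structure-based model.

Everything here works on flat numpy arrays so it can be jitted; the public
interface lives in :mod:`tridimer.sbm`.  A Verlet neighbour list over the
candidate repulsive pairs keeps the per-step cost linear.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["energy_forces", "integrate"]

_KB_BOND = 100.0
_KA_ANGLE = 20.0
_KD_DIHEDRAL = 1.0


@njit(cache=True, fastmath=True)
def _bonded_energy_forces(pos, forces,
                          bonds, bond_r0, angles, angle_t0,
                          dihedrals, dihedral_p0, eps):
    e = 0.0
    # bonds: V = kb (r - r0)^2
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e += _KB_BOND * dr * dr
        fmag = -2.0 * _KB_BOND * dr / r
        forces[i, 0] -= fmag * dx
        forces[i, 1] -= fmag * dy
        forces[i, 2] -= fmag * dz
        forces[j, 0] += fmag * dx
        forces[j, 1] += fmag * dy
        forces[j, 2] += fmag * dz
    # angles: V = ka (theta - theta0)^2
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cosv = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if cosv > 1.0:
            cosv = 1.0
        elif cosv < -1.0:
            cosv = -1.0
        theta = np.arccos(cosv)
        dt = theta - angle_t0[a]
        e += _KA_ANGLE * dt * dt
        sin_t = np.sqrt(1.0 - cosv * cosv)
        if sin_t < 1e-8:
            sin_t = 1e-8
        coeff = 2.0 * _KA_ANGLE * dt / sin_t
        # F_i = -dV/dtheta * dtheta/dri = coeff * d(cos theta)/dri
        fix = coeff * (vx / (ru * rv) - cosv * ux / (ru * ru))
        fiy = coeff * (vy / (ru * rv) - cosv * uy / (ru * ru))
        fiz = coeff * (vz / (ru * rv) - cosv * uz / (ru * ru))
        fkx = coeff * (ux / (ru * rv) - cosv * vx / (rv * rv))
        fky = coeff * (uy / (ru * rv) - cosv * vy / (rv * rv))
        fkz = coeff * (uz / (ru * rv) - cosv * vz / (rv * rv))
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
    # dihedrals: V = kd [1 - cos(p - p0)] + kd/2 [1 - cos 3(p - p0)]
    for dd in range(dihedrals.shape[0]):
        i, j, k, l = dihedrals[dd, 0], dihedrals[dd, 1], dihedrals[dd, 2], dihedrals[dd, 3]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        # n1 = b1 x b2, n2 = b2 x b3
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        rb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (mx * n2x + my * n2y + mz * n2z) / rb2
        phi = np.arctan2(y, x)
        dp = phi - dihedral_p0[dd]
        e += _KD_DIHEDRAL * (1.0 - np.cos(dp)) + 0.5 * _KD_DIHEDRAL * (1.0 - np.cos(3.0 * dp))
        dV = _KD_DIHEDRAL * (np.sin(dp) + 1.5 * np.sin(3.0 * dp))
        # torque-based force distribution (standard dihedral derivative)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        fi_c = -dV * rb2 / n1sq
        fl_c = dV * rb2 / n2sq
        fix = fi_c * n1x
        fiy = fi_c * n1y
        fiz = fi_c * n1z
        flx = fl_c * n2x
        fly = fl_c * n2y
        flz = fl_c * n2z
        b1b2 = (b1x * b2x + b1y * b2y + b1z * b2z) / (rb2 * rb2)
        b3b2 = (b3x * b2x + b3y * b2y + b3z * b2z) / (rb2 * rb2)
        tx = b3b2 * flx - b1b2 * fix
        ty = b3b2 * fly - b1b2 * fiy
        tz = b3b2 * flz - b1b2 * fiz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[j, 0] += -fix + tx
        forces[j, 1] += -fiy + ty
        forces[j, 2] += -fiz + tz
        forces[k, 0] += -flx - tx
        forces[k, 1] += -fly - ty
        forces[k, 2] += -flz - tz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz
    return e


@njit(cache=True, fastmath=True)
def _pair_energy_forces(pos, forces, contacts, contact_sigma,
                        rep_pairs, sigma_rep, r_cut, eps):
    e = 0.0
    # native 10-12: V = eps (5 s^12/r^12 - 6 s^10/r^10)
    for c in range(contacts.shape[0]):
        i, j = contacts[c, 0], contacts[c, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s2 = contact_sigma[c] * contact_sigma[c] / r2
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        e += eps * (5.0 * s12 - 6.0 * s10)
        # F_j = -dV/dr * d/r with dV/dr = -60 eps (s^12 - s^10) / r
        fmag = eps * 60.0 * (s12 - s10) / r2
        forces[i, 0] -= fmag * dx
        forces[i, 1] -= fmag * dy
        forces[i, 2] -= fmag * dz
        forces[j, 0] += fmag * dx
        forces[j, 1] += fmag * dy
        forces[j, 2] += fmag * dz
    # non-native repulsion, force-shifted truncation at r_cut
    rc2 = r_cut * r_cut
    src = sigma_rep / r_cut
    v_rc = src ** 12
    dv_rc = -12.0 * v_rc / r_cut  # dV/dr at r_cut
    for p in range(rep_pairs.shape[0]):
        i, j = rep_pairs[p, 0], rep_pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = np.sqrt(r2)
        sr2 = sigma_rep * sigma_rep / r2
        sr12 = sr2 * sr2 * sr2 * sr2 * sr2 * sr2
        e += eps * (sr12 - v_rc - dv_rc * (r - r_cut))
        dV = eps * (-12.0 * sr12 / r - dv_rc)
        fmag = dV / r  # force on j is -dV/dr * unit(ij)
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz
    return e


@njit(cache=True, fastmath=True)
def _total_energy_forces(pos, bonds, bond_r0, angles, angle_t0,
                         dihedrals, dihedral_p0, contacts, contact_sigma,
                         rep_pairs, sigma_rep, r_cut, eps):
    forces = np.zeros_like(pos)
    e = _bonded_energy_forces(pos, forces, bonds, bond_r0, angles, angle_t0,
                              dihedrals, dihedral_p0, eps)
    e += _pair_energy_forces(pos, forces, contacts, contact_sigma,
                             rep_pairs, sigma_rep, r_cut, eps)
    return e, forces


def energy_forces(pos, bonds, bond_r0, angles, angle_t0,
                  dihedrals, dihedral_p0, contacts, contact_sigma,
                  rep_pairs, sigma_rep, r_cut, eps):
    """Python entry point: total potential energy and forces."""
    return _total_energy_forces(
        pos, bonds, bond_r0, angles, angle_t0, dihedrals, dihedral_p0,
        contacts, contact_sigma, rep_pairs, sigma_rep, r_cut, eps)


@njit(cache=True, fastmath=True)
def _build_nlist(pos, rep_pairs, reach):
    reach2 = reach * reach
    count = 0
    keep = np.empty(rep_pairs.shape[0], np.int64)
    for p in range(rep_pairs.shape[0]):
        i, j = rep_pairs[p, 0], rep_pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if dx * dx + dy * dy + dz * dz < reach2:
            keep[count] = p
            count += 1
    out = np.empty((count, 2), np.int64)
    for k in range(count):
        out[k, 0] = rep_pairs[keep[k], 0]
        out[k, 1] = rep_pairs[keep[k], 1]
    return out


@njit(cache=True)
def integrate(pos0, vel0, bonds, bond_r0, angles, angle_t0,
              dihedrals, dihedral_p0, contacts, contact_sigma,
              rep_pairs, sigma_rep, r_cut, eps,
              dt, gamma, temperature, n_steps, save_interval, seed):
    """BAOAB Langevin integrator (velocity Verlet when gamma == 0).

    Saves positions, velocities and energies every ``save_interval`` steps
    (the state *after* that many steps; frame 0 is after the first
    interval).  Returns (frames, velocities, potential, kinetic, ok).
    """
    np.random.seed(seed)
    n = pos0.shape[0]
    pos = pos0.copy()
    vel = vel0.copy()
    n_frames = n_steps // save_interval
    frames = np.zeros((n_frames, n, 3))
    vels = np.zeros((n_frames, n, 3))
    pot = np.zeros(n_frames)
    kin = np.zeros(n_frames)

    skin = 2.0
    nlist_every = 25
    nlist = _build_nlist(pos, rep_pairs, r_cut + skin)
    e, forces = _total_energy_forces(
        pos, bonds, bond_r0, angles, angle_t0, dihedrals, dihedral_p0,
        contacts, contact_sigma, nlist, sigma_rep, r_cut, eps)

    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(temperature * (1.0 - c1 * c1))
    else:
        c1 = 1.0
        c2 = 0.0

    frame = 0
    ok = True
    for step in range(1, n_steps + 1):
        # B: half kick
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
        # A: half drift
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # O: thermostat
        if gamma > 0.0:
            noise = np.random.standard_normal((n, 3))
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[i, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[i, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[i, 2]
        # A: half drift
        for i in range(n):
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # neighbour list refresh
        if step % nlist_every == 0:
            nlist = _build_nlist(pos, rep_pairs, r_cut + skin)
        e, forces = _total_energy_forces(
            pos, bonds, bond_r0, angles, angle_t0, dihedrals, dihedral_p0,
            contacts, contact_sigma, nlist, sigma_rep, r_cut, eps)
        # B: half kick
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]

        if step % save_interval == 0:
            ke = 0.0
            for i in range(n):
                ke += 0.5 * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            frames[frame] = pos
            vels[frame] = vel
            pot[frame] = e
            kin[frame] = ke
            frame += 1
            if (np.abs(pos) > 1e6).any():
                ok = False
                break
    return frames, vels, pot, kin, ok
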