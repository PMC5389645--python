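"""Numba-compiled numerical kernels for the Go model and Langevin pulling.

Everything here works in reduced coarse-grained units: lengths in Å,
energies in ε, masses of 1, time in τ = σ·sqrt(m/ε).  The public modules
(`gomodel`, `pulling`) own all bookkeeping; these functions only crunch
arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def total_energy_forces(
    coords,
    forces,
    bond_idx,
    bond_b0,
    k_bond,
    angle_idx,
    angle_theta0,
    k_angle,
    dihedral_idx,
    dihedral_phi0,
    k_dih1,
    k_dih3,
    contact_idx,
    contact_r0,
    contact_eps,
    repulsion_idx,
    r_rep,
):
    """Accumulate forces (in place) and return the total potential energy.

    Terms: harmonic bonds k(r−b0)² and angles k(θ−θ0)², native-biased
    dihedrals k1[1−cos(φ−φ0)] + k3[1−cos3(φ−φ0)], 12-6 LJ contacts with
    minimum −ε at r0, and (r_rep/r)¹² repulsion between non-contact pairs.
    """
    forces[:] = 0.0
    energy = 0.0

    # bonds
    for b in range(bond_idx.shape[0]):
        i, j = bond_idx[b, 0], bond_idx[b, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_b0[b]
        energy += k_bond * dr * dr
        fmag = -2.0 * k_bond * dr / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # angles
    for a in range(angle_idx.shape[0]):
        i, j, k = angle_idx[a, 0], angle_idx[a, 1], angle_idx[a, 2]
        ux = coords[i, 0] - coords[j, 0]
        uy = coords[i, 1] - coords[j, 1]
        uz = coords[i, 2] - coords[j, 2]
        vx = coords[k, 0] - coords[j, 0]
        vy = coords[k, 1] - coords[j, 1]
        vz = coords[k, 2] - coords[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        dtheta = theta - angle_theta0[a]
        energy += k_angle * dtheta * dtheta
        coef = -2.0 * k_angle * dtheta / s  # = dE/dcosθ
        # d cosθ / d a
        dax = (vx / (nu * nv)) - c * ux / (nu * nu)
        day = (vy / (nu * nv)) - c * uy / (nu * nu)
        daz = (vz / (nu * nv)) - c * uz / (nu * nu)
        dcx = (ux / (nu * nv)) - c * vx / (nv * nv)
        dcy = (uy / (nu * nv)) - c * vy / (nv * nv)
        dcz = (uz / (nu * nv)) - c * vz / (nv * nv)
        fax = coef * dax
        fay = coef * day
        faz = coef * daz
        fcx = coef * dcx
        fcy = coef * dcy
        fcz = coef * dcz
        forces[i, 0] -= fax
        forces[i, 1] -= fay
        forces[i, 2] -= faz
        forces[k, 0] -= fcx
        forces[k, 1] -= fcy
        forces[k, 2] -= fcz
        forces[j, 0] += fax + fcx
        forces[j, 1] += fay + fcy
        forces[j, 2] += faz + fcz

    # dihedrals
    for d in range(dihedral_idx.shape[0]):
        i1, i2 = dihedral_idx[d, 0], dihedral_idx[d, 1]
        i3, i4 = dihedral_idx[d, 2], dihedral_idx[d, 3]
        b1x = coords[i2, 0] - coords[i1, 0]
        b1y = coords[i2, 1] - coords[i1, 1]
        b1z = coords[i2, 2] - coords[i1, 2]
        b2x = coords[i3, 0] - coords[i2, 0]
        b2y = coords[i3, 1] - coords[i2, 1]
        b2z = coords[i3, 2] - coords[i2, 2]
        b3x = coords[i4, 0] - coords[i3, 0]
        b3y = coords[i4, 1] - coords[i3, 1]
        b3z = coords[i4, 2] - coords[i3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # the torsion is undefined for collinear segments; skip the term
        # (energy and force together) when either normal nearly vanishes
        if n1sq < 0.25 or n2sq < 0.25 or b2n < 1e-12:
            continue
        # signed dihedral
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        ydot = (mx * n2x + my * n2y + mz * n2z) / b2n
        xdot = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(ydot, xdot)
        dphi = phi - dihedral_phi0[d]
        energy += k_dih1 * (1.0 - np.cos(dphi)) + k_dih3 * (1.0 - np.cos(3.0 * dphi))
        dV = k_dih1 * np.sin(dphi) + 3.0 * k_dih3 * np.sin(3.0 * dphi)
        # dphi/dr1 = (b2n/n1sq) n1 ; dphi/dr4 = -(b2n/n2sq) n2
        g1x = (b2n / n1sq) * n1x
        g1y = (b2n / n1sq) * n1y
        g1z = (b2n / n1sq) * n1z
        g4x = -(b2n / n2sq) * n2x
        g4y = -(b2n / n2sq) * n2y
        g4z = -(b2n / n2sq) * n2z
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        g2x = -(1.0 + s12) * g1x + s32 * g4x
        g2y = -(1.0 + s12) * g1y + s32 * g4y
        g2z = -(1.0 + s12) * g1z + s32 * g4z
        g3x = s12 * g1x - (1.0 + s32) * g4x
        g3y = s12 * g1y - (1.0 + s32) * g4y
        g3z = s12 * g1z - (1.0 + s32) * g4z
        forces[i1, 0] -= dV * g1x
        forces[i1, 1] -= dV * g1y
        forces[i1, 2] -= dV * g1z
        forces[i2, 0] -= dV * g2x
        forces[i2, 1] -= dV * g2y
        forces[i2, 2] -= dV * g2z
        forces[i3, 0] -= dV * g3x
        forces[i3, 1] -= dV * g3y
        forces[i3, 2] -= dV * g3z
        forces[i4, 0] -= dV * g4x
        forces[i4, 1] -= dV * g4y
        forces[i4, 2] -= dV * g4z

    # native contacts: LJ 12-6 with minimum -eps at r0
    for cpair in range(contact_idx.shape[0]):
        i, j = contact_idx[cpair, 0], contact_idx[cpair, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        sr2 = (contact_r0[cpair] * contact_r0[cpair]) / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        eps = contact_eps[cpair]
        energy += eps * (sr12 - 2.0 * sr6)
        fmag = 12.0 * eps * (sr12 - sr6) / r2  # = -(dE/dr)/r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # excluded-volume repulsion between non-contact pairs
    rr2 = r_rep * r_rep
    for p in range(repulsion_idx.shape[0]):
        i, j = repulsion_idx[p, 0], repulsion_idx[p, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        sr2 = rr2 / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        energy += sr12
        fmag = 12.0 * sr12 / r2
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    return energy


@njit(cache=True)
def run_langevin(
    coords,
    vels,
    bond_idx,
    bond_b0,
    k_bond,
    angle_idx,
    angle_theta0,
    k_angle,
    dihedral_idx,
    dihedral_phi0,
    k_dih1,
    k_dih3,
    contact_idx,
    contact_r0,
    contact_eps,
    repulsion_idx,
    r_rep,
    anchor_idx,
    pull_idx,
    anchor_pos,
    pull_base0,
    axis,
    k_anchor,
    kp,
    v_p,
    dt,
    gamma,
    kT,
    n_steps,
    record_every,
    seed,
):
    """BAOAB Langevin integration with a fixed anchor spring and a pulling
    spring whose base moves at v_p along ``axis``.

    Records (time, pull-spring force along the axis, potential energy,
    kinetic energy) and coordinate snapshots at stride ``record_every``.
    Returns (times, pull_forces, potential, kinetic, snapshots, status);
    status is the 1-based step number of a numeric blow-up, or 0.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    forces = np.zeros((n, 3))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    n_rec = n_steps // record_every
    times = np.empty(n_rec)
    pull_forces = np.empty(n_rec)
    potential = np.empty(n_rec)
    kinetic = np.empty(n_rec)
    snapshots = np.empty((n_rec, n, 3))

    def springs(coords_, forces_, t_):
        e = 0.0
        if k_anchor > 0.0:
            for d in range(3):
                delta = anchor_pos[d] - coords_[anchor_idx, d]
                forces_[anchor_idx, d] += k_anchor * delta
                e += 0.5 * k_anchor * delta * delta
        fpull = 0.0
        if kp > 0.0:
            ext = 0.0
            for d in range(3):
                base = pull_base0[d] + axis[d] * v_p * t_
                delta = base - coords_[pull_idx, d]
                forces_[pull_idx, d] += kp * delta
                e += 0.5 * kp * delta * delta
                ext += delta * axis[d]
            fpull = kp * ext
        return e, fpull

    energy = total_energy_forces(
        coords, forces, bond_idx, bond_b0, k_bond, angle_idx, angle_theta0,
        k_angle, dihedral_idx, dihedral_phi0, k_dih1, k_dih3, contact_idx,
        contact_r0, contact_eps, repulsion_idx, r_rep,
    )
    e_spring, fpull = springs(coords, forces, 0.0)
    energy += e_spring

    rec = 0
    status = 0
    for step in range(n_steps):
        # B: half kick
        for i in range(n):
            for d in range(3):
                vels[i, d] += 0.5 * dt * forces[i, d]
        # A: half drift
        for i in range(n):
            for d in range(3):
                coords[i, d] += 0.5 * dt * vels[i, d]
        # O: friction + noise
        if gamma > 0.0:
            for i in range(n):
                for d in range(3):
                    vels[i, d] = c1 * vels[i, d] + c2 * np.random.normal()
        # A: half drift
        for i in range(n):
            for d in range(3):
                coords[i, d] += 0.5 * dt * vels[i, d]
        # recompute forces at the new positions
        t_now = (step + 1) * dt
        energy = total_energy_forces(
            coords, forces, bond_idx, bond_b0, k_bond, angle_idx, angle_theta0,
            k_angle, dihedral_idx, dihedral_phi0, k_dih1, k_dih3, contact_idx,
            contact_r0, contact_eps, repulsion_idx, r_rep,
        )
        e_spring, fpull = springs(coords, forces, t_now)
        energy += e_spring
        # B: half kick
        for i in range(n):
            for d in range(3):
                vels[i, d] += 0.5 * dt * forces[i, d]

        if (step + 1) % record_every == 0 and rec < n_rec:
            ke = 0.0
            blown = False
            for i in range(n):
                for d in range(3):
                    ke += 0.5 * vels[i, d] * vels[i, d]
                    x = coords[i, d]
                    if not np.isfinite(x) or np.abs(x) > 1e6:
                        blown = True
            if blown:
                status = step + 1
                return (
                    times[:rec], pull_forces[:rec], potential[:rec],
                    kinetic[:rec], snapshots[:rec], status,
                )
            times[rec] = t_now
            pull_forces[rec] = fpull
            potential[rec] = energy
            kinetic[rec] = ke
            snapshots[rec] = coords
            rec += 1

    return times, pull_forces, potential, kinetic, snapshots, status
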