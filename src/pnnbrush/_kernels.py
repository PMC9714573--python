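"""Numba-jitted inner loops: Verlet pair list, forces, BAOAB integration.

The pair list is built brute-force over (mobile bead, any bead) pairs
with a skin, and refreshed when any mobile bead has moved more than half
the skin since the last build; within the force loop every pair is
re-checked against its own LJ/Debye cutoffs, so the result is exact.
The NumPy reference in :mod:`pnnbrush.forcefield` is the oracle these
kernels are tested against.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LJ_MIN_FACTOR = 2.0 ** (1.0 / 6.0)
N_EXCLUDE = 3


@njit(cache=False)
def _build_pairs(pos, mobile_idx, Lx, Ly, rlist, chain_id, chain_pos, pair_i, pair_j):
    """Fill pair arrays with (mobile, any) candidates within rlist.

    Mobile-mobile pairs are stored once (j > i).  Returns the pair count,
    or -1 on capacity overflow.
    """
    n = pos.shape[0]
    is_mobile = np.zeros(n, np.uint8)
    for t in range(mobile_idx.shape[0]):
        is_mobile[mobile_idx[t]] = 1
    rl2 = rlist * rlist
    count = 0
    cap = pair_i.shape[0]
    for t in range(mobile_idx.shape[0]):
        i = mobile_idx[t]
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(n):
            if j == i:
                continue
            if is_mobile[j] and j < i:
                continue
            dz = pos[j, 2] - zi
            if dz > rlist or dz < -rlist:
                continue
            if chain_id[i] >= 0 and chain_id[i] == chain_id[j]:
                sep = chain_pos[i] - chain_pos[j]
                if sep < 0:
                    sep = -sep
                if sep <= N_EXCLUDE:
                    continue
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dx -= Lx * np.rint(dx / Lx)
            dy -= Ly * np.rint(dy / Ly)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rl2:
                if count >= cap:
                    return -1
                pair_i[count] = i
                pair_j[count] = j
                count += 1
    return count


@njit(cache=False)
def _nonbonded_forces(
    pos, pair_i, pair_j, n_pairs, sigma, charge, Lx, Ly,
    eps_lj, coul, kappa, rcut_debye, forces, f_cap,
):
    """Pairwise LJ + Debye forces; f_cap > 0 limits the pair force
    magnitude (push-off mode for overlapping initial configurations)."""
    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= Lx * np.rint(dx / Lx)
        dy -= Ly * np.rint(dy / Ly)
        r2 = dx * dx + dy * dy + dz * dz
        sp = 0.5 * (sigma[i] + sigma[j])
        rc_lj = LJ_MIN_FACTOR * sp
        fmag = 0.0
        if r2 < rc_lj * rc_lj:
            r = np.sqrt(r2)
            sr6 = (sp / r) ** 6
            fmag += 24.0 * eps_lj * (2.0 * sr6 * sr6 - sr6) / r
        qq = charge[i] * charge[j]
        if qq != 0.0 and r2 < rcut_debye * rcut_debye:
            r = np.sqrt(r2)
            u = coul * qq * np.exp(-kappa * r) / r
            fmag += u * (kappa + 1.0 / r)
        if fmag != 0.0:
            if f_cap > 0.0:
                if fmag > f_cap:
                    fmag = f_cap
                elif fmag < -f_cap:
                    fmag = -f_cap
            r = np.sqrt(r2)
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            forces[i, 0] -= fx
            forces[i, 1] -= fy
            forces[i, 2] -= fz
            forces[j, 0] += fx
            forces[j, 1] += fy
            forces[j, 2] += fz


@njit(cache=False)
def _bonded_forces(pos, bonds, angles, k_bond, r0, k_bend, theta0, forces):
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        fmag = -2.0 * k_bond * (r - r0) / r
        forces[i, 0] -= fmag * dx
        forces[i, 1] -= fmag * dy
        forces[i, 2] -= fmag * dz
        forces[j, 0] += fmag * dx
        forces[j, 1] += fmag * dy
        forces[j, 2] += fmag * dz
    if k_bend != 0.0:
        for a in range(angles.shape[0]):
            i = angles[a, 0]
            j = angles[a, 1]
            k = angles[a, 2]
            u1x = pos[i, 0] - pos[j, 0]
            u1y = pos[i, 1] - pos[j, 1]
            u1z = pos[i, 2] - pos[j, 2]
            u2x = pos[k, 0] - pos[j, 0]
            u2y = pos[k, 1] - pos[j, 1]
            u2z = pos[k, 2] - pos[j, 2]
            n1 = np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
            n2 = np.sqrt(u2x * u2x + u2y * u2y + u2z * u2z)
            cth = (u1x * u2x + u1y * u2y + u1z * u2z) / (n1 * n2)
            if cth > 1.0:
                cth = 1.0
            elif cth < -1.0:
                cth = -1.0
            th = np.arccos(cth)
            sth = np.sqrt(1.0 - cth * cth)
            # floor keeps both collinear limits finite: near theta = pi the
            # force vanishes anyway, near theta = 0 the geometric factor
            # would otherwise blow up through float cancellation
            if sth < 1e-3:
                sth = 1e-3
            coef = 2.0 * k_bend * (th - theta0) / sth
            fix = coef * (u2x / n2 - cth * u1x / n1) / n1
            fiy = coef * (u2y / n2 - cth * u1y / n1) / n1
            fiz = coef * (u2z / n2 - cth * u1z / n1) / n1
            fkx = coef * (u1x / n1 - cth * u2x / n2) / n2
            fky = coef * (u1y / n1 - cth * u2y / n2) / n2
            fkz = coef * (u1z / n1 - cth * u2z / n2) / n2
            forces[i, 0] += fix
            forces[i, 1] += fiy
            forces[i, 2] += fiz
            forces[k, 0] += fkx
            forces[k, 1] += fky
            forces[k, 2] += fkz
            forces[j, 0] -= fix + fkx
            forces[j, 1] -= fiy + fky
            forces[j, 2] -= fiz + fkz


@njit(cache=False)
def _energy_scan(
    pos, sigma, charge, chain_id, chain_pos, bonds, angles, Lx, Ly,
    eps_lj, shift_on, k_bond, r0, k_bend, theta0, coul, kappa, rcut_debye,
    tracer_idx, is_chain,
):
    """Full O(N^2) energy evaluation with per-group attribution.

    Returns (u_lj, u_bond, u_bend, u_debye, tracer_nonbonded,
    chain_nonbonded) where the group terms use half-shares per endpoint.
    """
    n = pos.shape[0]
    u_lj = 0.0
    u_db = 0.0
    tracer_e = 0.0
    chain_e = 0.0
    rc_db2 = rcut_debye * rcut_debye
    rz_max = rcut_debye
    if LJ_MIN_FACTOR * sigma.max() > rz_max:
        rz_max = LJ_MIN_FACTOR * sigma.max()
    for i in range(n - 1):
        for j in range(i + 1, n):
            dz = pos[j, 2] - pos[i, 2]
            if dz > rz_max or dz < -rz_max:
                continue
            if chain_id[i] >= 0 and chain_id[i] == chain_id[j]:
                sep = chain_pos[i] - chain_pos[j]
                if sep < 0:
                    sep = -sep
                if sep <= N_EXCLUDE:
                    continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dx -= Lx * np.rint(dx / Lx)
            dy -= Ly * np.rint(dy / Ly)
            r2 = dx * dx + dy * dy + dz * dz
            sp = 0.5 * (sigma[i] + sigma[j])
            rc_lj = LJ_MIN_FACTOR * sp
            u_pair = 0.0
            if r2 < rc_lj * rc_lj:
                r = np.sqrt(r2)
                sr6 = (sp / r) ** 6
                u = 4.0 * eps_lj * (sr6 * sr6 - sr6)
                if shift_on:
                    u += eps_lj
                u_lj += u
                u_pair += u
            qq = charge[i] * charge[j]
            if qq != 0.0 and r2 < rc_db2:
                r = np.sqrt(r2)
                u = coul * qq * np.exp(-kappa * r) / r
                u_db += u
                u_pair += u
            if u_pair != 0.0:
                if i == tracer_idx or j == tracer_idx:
                    tracer_e += u_pair
                if is_chain[i]:
                    chain_e += 0.5 * u_pair
                if is_chain[j]:
                    chain_e += 0.5 * u_pair
    u_bond = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u_bond += k_bond * (r - r0) ** 2
    u_bend = 0.0
    if k_bend != 0.0:
        for a in range(angles.shape[0]):
            i = angles[a, 0]
            j = angles[a, 1]
            k = angles[a, 2]
            u1x = pos[i, 0] - pos[j, 0]
            u1y = pos[i, 1] - pos[j, 1]
            u1z = pos[i, 2] - pos[j, 2]
            u2x = pos[k, 0] - pos[j, 0]
            u2y = pos[k, 1] - pos[j, 1]
            u2z = pos[k, 2] - pos[j, 2]
            n1 = np.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
            n2 = np.sqrt(u2x * u2x + u2y * u2y + u2z * u2z)
            cth = (u1x * u2x + u1y * u2y + u1z * u2z) / (n1 * n2)
            if cth > 1.0:
                cth = 1.0
            elif cth < -1.0:
                cth = -1.0
            th = np.arccos(cth)
            u_bend += k_bend * (th - theta0) ** 2
    return u_lj, u_bond, u_bend, u_db, tracer_e, chain_e


@njit(cache=False)
def _tracer_energy(
    pos, sigma, charge, Lx, Ly, eps_lj, shift_on, coul, kappa, rcut_debye,
    tracer_idx,
):
    """O(N) nonbonded (LJ + Debye) energy of the tracer alone."""
    n = pos.shape[0]
    e = 0.0
    xi, yi, zi = pos[tracer_idx, 0], pos[tracer_idx, 1], pos[tracer_idx, 2]
    for j in range(n):
        if j == tracer_idx:
            continue
        dz = pos[j, 2] - zi
        sp = 0.5 * (sigma[tracer_idx] + sigma[j])
        rc_lj = LJ_MIN_FACTOR * sp
        rz = rcut_debye if rcut_debye > rc_lj else rc_lj
        if dz > rz or dz < -rz:
            continue
        dx = pos[j, 0] - xi
        dy = pos[j, 1] - yi
        dx -= Lx * np.rint(dx / Lx)
        dy -= Ly * np.rint(dy / Ly)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc_lj * rc_lj:
            r = np.sqrt(r2)
            sr6 = (sp / r) ** 6
            e += 4.0 * eps_lj * (sr6 * sr6 - sr6)
            if shift_on:
                e += eps_lj
        qq = charge[tracer_idx] * charge[j]
        if qq != 0.0 and r2 < rcut_debye * rcut_debye:
            r = np.sqrt(r2)
            e += coul * qq * np.exp(-kappa * r) / r
    return e


@njit(cache=False)
def _compute_forces(
    pos, mobile_idx, sigma, charge, chain_id, chain_pos, bonds, angles,
    Lx, Ly, eps_lj, k_bond, r0, k_bend, theta0, coul, kappa, rcut_debye,
    rlist, pair_i, pair_j, ref_pos, forces, f_cap,
):
    """Rebuild-if-needed pair list + full force evaluation.  Returns n_pairs."""
    n_pairs = _build_pairs(
        pos, mobile_idx, Lx, Ly, rlist, chain_id, chain_pos, pair_i, pair_j
    )
    for t in range(mobile_idx.shape[0]):
        i = mobile_idx[t]
        ref_pos[i, 0] = pos[i, 0]
        ref_pos[i, 1] = pos[i, 1]
        ref_pos[i, 2] = pos[i, 2]
    forces[:] = 0.0
    if n_pairs >= 0:
        _nonbonded_forces(
            pos, pair_i, pair_j, n_pairs, sigma, charge, Lx, Ly,
            eps_lj, coul, kappa, rcut_debye, forces, f_cap,
        )
        _bonded_forces(pos, bonds, angles, k_bond, r0, k_bend, theta0, forces)
    return n_pairs


@njit(cache=False)
def _run_chunk(
    pos, vel, forces, mobile_idx, mass, gamma, sigma, charge,
    chain_id, chain_pos, bonds, angles, full_bonds, full_angles, Lx, Ly,
    eps_lj, shift_on, k_bond, r0, k_bend, theta0, coul, kappa, rcut_debye,
    kT, dt, noise, skin, rlist, pair_i, pair_j, n_pairs_in, ref_pos,
    dump_every, step_offset, tracer_idx, is_chain,
    out_tracer, out_energy, out_inbrush, out_maxz, record_energy, f_cap,
):
    """Advance n_steps = noise.shape[0] BAOAB steps; dump per ``dump_every``.

    Returns (n_pairs, n_dumped, error_flag).  error_flag: 0 ok, 1 pair
    overflow, 2 non-finite coordinate.
    """
    n_steps = noise.shape[0]
    n_mob = mobile_idx.shape[0]
    n_pairs = n_pairs_in
    n_dumped = 0
    half_skin2 = (0.5 * skin) ** 2
    for s in range(n_steps):
        # B
        for t in range(n_mob):
            i = mobile_idx[t]
            c = 0.5 * dt / mass[i]
            vel[i, 0] += c * forces[i, 0]
            vel[i, 1] += c * forces[i, 1]
            vel[i, 2] += c * forces[i, 2]
        # A
        for t in range(n_mob):
            i = mobile_idx[t]
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # O
        for t in range(n_mob):
            i = mobile_idx[t]
            g = gamma[i]
            if g > 0.0:
                c1 = np.exp(-g * dt / mass[i])
                c2 = np.sqrt(kT * (1.0 - c1 * c1) / mass[i])
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[s, t, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[s, t, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[s, t, 2]
        # A
        for t in range(n_mob):
            i = mobile_idx[t]
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
        # forces (with rebuild check)
        need = False
        for t in range(n_mob):
            i = mobile_idx[t]
            ddx = pos[i, 0] - ref_pos[i, 0]
            ddy = pos[i, 1] - ref_pos[i, 1]
            ddz = pos[i, 2] - ref_pos[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > half_skin2:
                need = True
                break
        if need:
            n_pairs = _compute_forces(
                pos, mobile_idx, sigma, charge, chain_id, chain_pos, bonds,
                angles, Lx, Ly, eps_lj, k_bond, r0, k_bend, theta0, coul,
                kappa, rcut_debye, rlist, pair_i, pair_j, ref_pos, forces,
                f_cap,
            )
            if n_pairs < 0:
                return n_pairs, n_dumped, 1
        else:
            forces[:] = 0.0
            _nonbonded_forces(
                pos, pair_i, pair_j, n_pairs, sigma, charge, Lx, Ly,
                eps_lj, coul, kappa, rcut_debye, forces, f_cap,
            )
            _bonded_forces(pos, bonds, angles, k_bond, r0, k_bend, theta0, forces)
        # B
        for t in range(n_mob):
            i = mobile_idx[t]
            c = 0.5 * dt / mass[i]
            vel[i, 0] += c * forces[i, 0]
            vel[i, 1] += c * forces[i, 1]
            vel[i, 2] += c * forces[i, 2]
        # dump
        gstep = step_offset + s + 1
        if dump_every > 0 and gstep % dump_every == 0:
            if tracer_idx >= 0:
                if not (
                    np.isfinite(pos[tracer_idx, 0])
                    and np.isfinite(pos[tracer_idx, 1])
                    and np.isfinite(pos[tracer_idx, 2])
                ):
                    return n_pairs, n_dumped, 2
                out_tracer[n_dumped, 0] = pos[tracer_idx, 0]
                out_tracer[n_dumped, 1] = pos[tracer_idx, 1]
                out_tracer[n_dumped, 2] = pos[tracer_idx, 2]
            maxz = 0.0
            for i in range(pos.shape[0]):
                if is_chain[i] and pos[i, 2] > maxz:
                    maxz = pos[i, 2]
            out_maxz[n_dumped] = maxz
            if tracer_idx >= 0:
                out_inbrush[n_dumped] = 1 if pos[tracer_idx, 2] <= maxz else 0
            else:
                out_inbrush[n_dumped] = 1
            if record_energy == 1:
                e = _energy_scan(
                    pos, sigma, charge, chain_id, chain_pos,
                    full_bonds, full_angles,
                    Lx, Ly, eps_lj, shift_on, k_bond, r0, k_bend, theta0,
                    coul, kappa, rcut_debye, tracer_idx, is_chain,
                )
                out_energy[n_dumped, 0] = e[0]
                out_energy[n_dumped, 1] = e[1]
                out_energy[n_dumped, 2] = e[2]
                out_energy[n_dumped, 3] = e[3]
                out_energy[n_dumped, 4] = e[4]
                out_energy[n_dumped, 5] = e[5]
            elif record_energy == 2 and tracer_idx >= 0:
                out_energy[n_dumped, 4] = _tracer_energy(
                    pos, sigma, charge, Lx, Ly, eps_lj, shift_on,
                    coul, kappa, rcut_debye, tracer_idx,
                )
            n_dumped += 1
    # final sanity check on all mobile coordinates
    for t in range(n_mob):
        i = mobile_idx[t]
        if not (
            np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1]) and np.isfinite(pos[i, 2])
        ):
            return n_pairs, n_dumped, 2
    return n_pairs, n_dumped, 0
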