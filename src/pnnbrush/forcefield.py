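"""Pair and bonded interactions: energies, forces, bookkeeping.

Four terms make up the potential: a truncated-and-shifted 12-6
Lennard-Jones repulsion (WCA form, cut at its minimum 2^(1/6) sigma for
good-solvent conditions), a harmonic stretching term K_bond (r - r0)^2,
a harmonic bending term K_bend (theta - theta0)^2, and a Debye-Hueckel
screened Coulomb term A q_i q_j exp(-kappa r)/r cut at 3 sigma.  The
total is their sum.

Nonbonded terms are excluded between beads separated by up to
``n_exclude`` bonds along the same chain (default 3, i.e. 1-2, 1-3 and
1-4 neighbors), the convention of bead-spring MD codes; chain
connectivity is handled entirely by the bond and angle terms.

This module is the plain-NumPy reference path, exact on any system size;
:mod:`pnnbrush._kernels` holds the numba-accelerated neighbor-list twin
used by the integrator.  The two are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ForceFieldParams, LJ_MIN_FACTOR
from .system import SystemState, TRACER, min_image_displacements

#: number of along-chain neighbors excluded from nonbonded terms
N_EXCLUDE = 3


class SingularityError(ZeroDivisionError):
    """Raised when a pair distance of zero reaches a pair potential."""


@dataclass
class EnergyBreakdown:
    """Per-term and per-bead potential-energy bookkeeping (eps_E units).

    ``per_bead`` assigns half of every pair term to each endpoint, half a
    bond to each endpoint and the full bend to the apex bead, so that
    ``per_bead.sum() == u_total``.
    """

    u_lj: float
    u_bond: float
    u_bend: float
    u_debye: float
    per_bead: np.ndarray

    @property
    def u_total(self) -> float:
        return self.u_lj + self.u_bond + self.u_bend + self.u_debye


def lj_pair_energy(
    r: float, eps_lj: float, sigma_lj: float, r_cut: float, shift: bool = True
) -> float:
    """Truncated 12-6 LJ energy; energy-shifted to 0 at the cutoff if ``shift``."""
    r = np.asarray(r, dtype=float)
    if np.any(r == 0):
        raise SingularityError("LJ energy at r = 0")
    sr6 = (sigma_lj / r) ** 6
    u = 4.0 * eps_lj * (sr6**2 - sr6)
    if shift:
        src6 = (sigma_lj / r_cut) ** 6
        u = u - 4.0 * eps_lj * (src6**2 - src6)
    return np.where(r < r_cut, u, 0.0)[()]


def bond_energy(r: float, k_bond: float, r0: float) -> float:
    """Harmonic stretching energy K_bond (r - r0)^2."""
    r = np.asarray(r, dtype=float)
    return (k_bond * (r - r0) ** 2)[()]


def bend_energy(theta: float, k_bend: float, theta0: float = math.pi) -> float:
    """Harmonic bending energy K_bend (theta - theta0)^2."""
    theta = np.asarray(theta, dtype=float)
    return (k_bend * (theta - theta0) ** 2)[()]


def debye_pair_energy(
    r: float,
    qi: float,
    qj: float,
    coulomb_const: float,
    kappa: float,
    r_cut: float,
) -> float:
    """Screened Coulomb energy A q_i q_j exp(-kappa r)/r, zero past the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r == 0):
        raise SingularityError("Debye energy at r = 0")
    if qi == 0.0 or qj == 0.0:
        return np.zeros_like(r)[()]
    u = coulomb_const * qi * qj * np.exp(-kappa * r) / r
    return np.where(r < r_cut, u, 0.0)[()]


def _excluded_matrix(state: SystemState) -> np.ndarray:
    """Boolean (N, N) matrix of nonbonded exclusions (1-2..1-(1+n) neighbors)."""
    same = (state.chain_id[:, None] == state.chain_id[None, :]) & (
        state.chain_id[:, None] >= 0
    )
    sep = np.abs(state.chain_pos[:, None] - state.chain_pos[None, :])
    return same & (sep >= 1) & (sep <= N_EXCLUDE)


def total_energy_forces(
    state: SystemState,
    params: ForceFieldParams,
    n_exclude: int = N_EXCLUDE,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Brute-force O(N^2) energies and forces under x,y minimum image.

    Interactions involving immobile beads are included; only the forces on
    mobile beads are ever used by the integrator.
    """
    pos = state.positions
    n = state.n
    forces = np.zeros_like(pos)
    per_bead = np.zeros(n)

    # --- nonbonded: all pairs, minimum image in x,y ---
    delta = pos[None, :, :] - pos[:, None, :]  # r_j - r_i
    delta = min_image_displacements(delta, state.box)
    r2 = (delta**2).sum(-1)
    iu = np.triu_indices(n, k=1)
    excl = _excluded_matrix(state) if n_exclude else np.zeros((n, n), bool)

    sig_pair = 0.5 * (state.sigmas[:, None] + state.sigmas[None, :])
    rc_lj = LJ_MIN_FACTOR * sig_pair
    qq = state.charges[:, None] * state.charges[None, :]
    rc_max2 = np.maximum(rc_lj, np.where(qq != 0, params.r_cut_debye, 0.0)) ** 2

    ii, jj = iu
    keep = (r2[iu] < rc_max2[iu]) & ~excl[iu]
    ii, jj = ii[keep], jj[keep]
    if len(ii):
        d = delta[ii, jj]
        r2p = r2[ii, jj]
        if np.any(r2p == 0):
            raise SingularityError("coincident beads in nonbonded sum")
        r = np.sqrt(r2p)
        sp = sig_pair[ii, jj]
        # LJ (WCA)
        in_lj = r < rc_lj[ii, jj]
        sr6 = np.where(in_lj, (sp / np.where(in_lj, r, 1.0)) ** 6, 0.0)
        u_lj_pair = np.where(
            in_lj, 4 * params.eps_lj * (sr6**2 - sr6) + (params.eps_lj if params.good_solvent else 0.0), 0.0
        )
        f_lj_mag = np.where(in_lj, 24 * params.eps_lj * (2 * sr6**2 - sr6) / r, 0.0)
        # Debye
        qqp = qq[ii, jj]
        in_db = (qqp != 0) & (r < params.r_cut_debye)
        u_db_pair = np.where(
            in_db, params.coulomb_const * qqp * np.exp(-params.kappa * r) / r, 0.0
        )
        f_db_mag = np.where(in_db, u_db_pair * (params.kappa + 1.0 / r), 0.0)
        # force on i is -(f_mag) * dhat where dhat points i -> j
        f_mag = f_lj_mag + f_db_mag
        fvec = (f_mag / r)[:, None] * d
        np.add.at(forces, ii, -fvec)
        np.add.at(forces, jj, fvec)
        np.add.at(per_bead, ii, 0.5 * (u_lj_pair + u_db_pair))
        np.add.at(per_bead, jj, 0.5 * (u_lj_pair + u_db_pair))
        u_lj = float(u_lj_pair.sum())
        u_debye = float(u_db_pair.sum())
    else:
        u_lj = u_debye = 0.0

    # --- bonds (no minimum image: positions are unwrapped) ---
    u_bond = 0.0
    if len(state.bonds):
        bi, bj = state.bonds[:, 0], state.bonds[:, 1]
        d = pos[bj] - pos[bi]
        r = np.linalg.norm(d, axis=1)
        u_b = params.k_bond * (r - params.r0) ** 2
        fmag = -2.0 * params.k_bond * (r - params.r0)  # >0 means repulsive
        fvec = (fmag / r)[:, None] * d
        np.add.at(forces, bi, -fvec)
        np.add.at(forces, bj, fvec)
        np.add.at(per_bead, bi, 0.5 * u_b)
        np.add.at(per_bead, bj, 0.5 * u_b)
        u_bond = float(u_b.sum())

    # --- angles ---
    u_bend = 0.0
    if len(state.angles) and params.k_bend != 0.0:
        ai, aj, ak = state.angles.T
        u1 = pos[ai] - pos[aj]
        u2 = pos[ak] - pos[aj]
        n1 = np.linalg.norm(u1, axis=1)
        n2 = np.linalg.norm(u2, axis=1)
        cth = np.clip((u1 * u2).sum(1) / (n1 * n2), -1.0, 1.0)
        th = np.arccos(cth)
        u_a = params.k_bend * (th - params.theta0) ** 2
        # same collinear-limit floor as the jitted kernel (see _kernels)
        sth = np.maximum(np.sqrt(1.0 - cth**2), 1e-3)
        coef = 2.0 * params.k_bend * (th - params.theta0) / sth
        fi = coef[:, None] * (u2 / n2[:, None] - cth[:, None] * u1 / n1[:, None]) / n1[:, None]
        fk = coef[:, None] * (u1 / n1[:, None] - cth[:, None] * u2 / n2[:, None]) / n2[:, None]
        np.add.at(forces, ai, fi)
        np.add.at(forces, ak, fk)
        np.add.at(forces, aj, -(fi + fk))
        np.add.at(per_bead, aj, u_a)
        u_bend = float(u_a.sum())

    return EnergyBreakdown(u_lj, u_bond, u_bend, u_debye, per_bead), forces


def tracer_interaction_energy(state: SystemState, params: ForceFieldParams) -> float:
    """Sum of LJ + Debye pair energies involving the tracer."""
    ti = state.tracer_index
    if ti is None:
        return 0.0
    pos = state.positions
    d = min_image_displacements(np.delete(pos, ti, axis=0) - pos[ti], state.box)
    r = np.sqrt((d**2).sum(-1))
    sig = 0.5 * (np.delete(state.sigmas, ti) + state.sigmas[ti])
    u = 0.0
    for rr, sp, q in zip(r, sig, np.delete(state.charges, ti)):
        rc = LJ_MIN_FACTOR * sp
        if rr < rc:
            u += lj_pair_energy(rr, params.eps_lj, sp, rc, shift=params.good_solvent)
        u += debye_pair_energy(
            rr, state.charges[ti], q, params.coulomb_const, params.kappa, params.r_cut_debye
        )
    return float(u)
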