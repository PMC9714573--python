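"""Synthetic trajectory and chain generators with known statistics.

These emulate the statistical structure the analysis stages assume —
linear MSD growth (anisotropic Brownian walkers), a ballistic-to-
diffusive crossover (velocity Ornstein-Uhlenbeck process) and
exponential bond-vector decorrelation (ideal discrete worm-like chains)
— so that every estimator can be validated against closed-form
expectations without running molecular dynamics.  Generators emit the
same :class:`~pnnbrush.dynamics.Trajectory` type as the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad

from .dynamics import Trajectory


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic ensembles (reduced units)."""

    D_par: float = 1.0
    D_perp: float = 1.0
    dt: float = 0.25
    n_steps: int = 400
    n_trajectories: int = 100
    crossover_time: Optional[float] = None   # velocity relaxation time
    exit_rate: float = 0.0                   # hazard of leaving the brush
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_par < 0 or self.D_perp < 0:
            raise ValueError("diffusion constants must be non-negative")
        if self.exit_rate < 0:
            raise ValueError("exit_rate must be non-negative")


def _package(spec: SyntheticSpec, paths: np.ndarray, rng: np.random.Generator) -> list[Trajectory]:
    """Wrap (n_traj, n_frames, 3) paths as trajectories with exit flags."""
    n_traj, n_frames, _ = paths.shape
    times = spec.dt * np.arange(n_frames)
    if spec.exit_rate > 0:
        exit_times = rng.exponential(1.0 / spec.exit_rate, size=n_traj)
    else:
        exit_times = np.full(n_traj, np.inf)
    out = []
    for r in range(n_traj):
        in_brush = times < exit_times[r]
        in_brush[0] = True
        out.append(
            Trajectory(
                times=times,
                tracer_positions=paths[r],
                in_brush=in_brush,
                max_chain_z=np.full(n_frames, np.inf),
                energies=None,
                seed=spec.seed + r,
            )
        )
    return out


def generate_brownian(spec: SyntheticSpec) -> list[Trajectory]:
    """Anisotropic Brownian walkers: Var(dx)=Var(dy)=2 D_par dt, Var(dz)=2 D_perp dt."""
    rng = np.random.default_rng(spec.seed)
    scales = np.array(
        [np.sqrt(2 * spec.D_par * spec.dt)] * 2 + [np.sqrt(2 * spec.D_perp * spec.dt)]
    )
    steps = rng.standard_normal((spec.n_trajectories, spec.n_steps, 3)) * scales
    paths = np.concatenate(
        [np.zeros((spec.n_trajectories, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    return _package(spec, paths, rng)


def generate_ou_crossover(spec: SyntheticSpec) -> list[Trajectory]:
    """Velocity-OU walkers: ballistic for t << crossover_time, diffusive after.

    The velocity relaxes with time constant tau_c = ``crossover_time`` and
    stationary variance D/tau_c per component, giving the asymptotic
    diffusion constants (D_par, D_par, D_perp) per axis.  Positions are
    sub-stepped finely between dump frames so the discrete MSD matches
    the continuous OU closed form.
    """
    if not spec.crossover_time or spec.crossover_time <= 0:
        raise ValueError("crossover_time must be positive")
    rng = np.random.default_rng(spec.seed)
    tau = spec.crossover_time
    n_sub = max(1, int(np.ceil(spec.dt / (0.1 * tau))))
    h = spec.dt / n_sub
    a = np.exp(-h / tau)
    D3 = np.array([spec.D_par, spec.D_par, spec.D_perp])
    v_std = np.sqrt(D3 / tau)
    kick = v_std * np.sqrt(1.0 - a * a)
    n_traj = spec.n_trajectories
    vel = v_std * rng.standard_normal((n_traj, 3))
    pos = np.zeros((n_traj, 3))
    paths = np.zeros((n_traj, spec.n_steps + 1, 3))
    for s in range(spec.n_steps):
        for _ in range(n_sub):
            pos += 0.5 * h * vel
            vel = a * vel + kick * rng.standard_normal((n_traj, 3))
            pos += 0.5 * h * vel
        paths[:, s + 1] = pos
    return _package(spec, paths, rng)


def bend_angle_density(theta: np.ndarray, beta_k_bend: float) -> np.ndarray:
    """Unnormalized Boltzmann density of the bead angle: e^{-bK(th-pi)^2} sin(th)."""
    return np.exp(-beta_k_bend * (theta - np.pi) ** 2) * np.sin(theta)


def expected_cos_theta(beta_k_bend: float) -> float:
    """Quadrature value of <cos theta> under the bend-angle density."""
    num = quad(lambda t: np.cos(t) * bend_angle_density(np.array(t), beta_k_bend), 0, np.pi)[0]
    den = quad(lambda t: bend_angle_density(np.array(t), beta_k_bend), 0, np.pi)[0]
    return num / den


def wlc_persistence_length(beta_k_bend: float, bond_length: float = 1.0) -> float:
    """Ideal discrete-WLC persistence length l_p = -b / ln<u_i . u_i+1>.

    The bond-vector correlation per joint is -<cos theta> (theta = pi is
    straight).  Infinite (returned as inf) for a rigid chain.
    """
    c = -expected_cos_theta(beta_k_bend)
    if c >= 1.0:
        return np.inf
    if c <= 0.0:
        return 0.0
    return -bond_length / np.log(c)


def sample_bend_angles(
    n: int, beta_k_bend: float, rng: np.random.Generator, grid_size: int = 4096
) -> np.ndarray:
    """Draw bead angles from the Boltzmann bend density by inverse CDF."""
    if beta_k_bend < 0:
        raise ValueError("beta_k_bend must be non-negative")
    theta = np.linspace(0.0, np.pi, grid_size)
    pdf = bend_angle_density(theta, beta_k_bend)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(theta))])
    cdf /= cdf[-1]
    return np.interp(rng.uniform(0.0, 1.0, size=n), cdf, theta)


def sample_discrete_wlc(
    n_beads: int,
    beta_k_bend: float,
    n_samples: int,
    seed: int = 0,
    bond_length: float = 1.0,
) -> list[np.ndarray]:
    """Ideal discrete worm-like chains (no excluded volume).

    Chains are grown joint by joint: bead angles from the Boltzmann bend
    density, azimuths uniform.  Returns ``n_samples`` coordinate arrays
    of shape (n_beads, 3).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        dirs = np.zeros((n_beads - 1, 3))
        dirs[0] = (0.0, 0.0, 1.0)
        thetas = sample_bend_angles(n_beads - 2, beta_k_bend, rng)
        phis = rng.uniform(0, 2 * np.pi, size=n_beads - 2)
        for i in range(1, n_beads - 1):
            u = dirs[i - 1]
            alpha = np.pi - thetas[i - 1]
            ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            e1 = np.cross(u, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            dirs[i] = (
                np.cos(alpha) * u
                + np.sin(alpha) * (np.cos(phis[i - 1]) * e1 + np.sin(phis[i - 1]) * e2)
            )
        pos = np.vstack([np.zeros(3), np.cumsum(bond_length * dirs, axis=0)])
        out.append(pos)
    return out
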