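"""Langevin dynamics: BAOAB integration, realization runs, bulk runs.

Mobile beads follow m dv/dt = F - gamma v + B(t), discretized with the
BAOAB splitting (exact velocity-Verlet limit at gamma = 0; the
Ornstein-Uhlenbeck half-step uses the exact exponential damping with
noise variance kT (1 - exp(-2 gamma dt / m)) / m, so the discrete
fluctuation-dissipation balance is exact).  Immobile beads never move
but participate in all interactions.

Randomness comes from a ``numpy.random.Generator`` seeded per
realization (``base_seed + index`` streams via ``default_rng``), so every
trajectory is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels
from .params import BrushConfig, ForceFieldParams, LJ_MIN_FACTOR
from .system import (
    CHAIN,
    TETHER,
    SystemState,
    build_brush_system,
    build_free_chain,
)

NEIGHBOR_SKIN = 0.5
CHUNK_STEPS = 2000
#: steps of reduced-dt integration opening every equilibration (soft start)
SOFT_START_STEPS = 500
SOFT_START_FACTOR = 0.2

ENERGY_MODE = {"none": 0, "full": 1, "tracer": 2}

ENERGY_COLUMNS = ("u_lj", "u_bond", "u_bend", "u_debye", "tracer_e", "chain_e")


class BlowUpError(RuntimeError):
    """Raised when a coordinate becomes non-finite during integration."""


@dataclass
class LangevinSettings:
    """Thermostat parameters of the Langevin integrator.

    ``gamma`` is the baseline friction used when building systems; the
    integrator itself reads the per-bead frictions stored on the state
    (Stokes scaling makes the tracer's differ from the chain beads').
    """

    gamma: float = 1.0
    kT: float = 2.804
    dt: float = 0.005

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.kT < 0 or self.dt <= 0:
            raise ValueError("kT must be >= 0 and dt > 0")


@dataclass
class Trajectory:
    """Time-sampled tracer coordinates and per-frame bookkeeping.

    ``tracer_positions`` are unwrapped (continuous) coordinates; frame 0
    is the production origin.  ``energies`` columns follow
    :data:`ENERGY_COLUMNS`; ``in_brush`` is True while the tracer z lies
    below the instantaneous maximum chain-bead z of its own realization.
    """

    times: np.ndarray
    tracer_positions: np.ndarray
    in_brush: np.ndarray
    max_chain_z: np.ndarray
    energies: Optional[np.ndarray]
    seed: int
    chain_positions_final: Optional[np.ndarray] = None
    chain_frames: Optional[np.ndarray] = None
    n_chain_beads_per_chain: int = 0
    n_chains: int = 0

    def __post_init__(self) -> None:
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)


class LangevinIntegrator:
    """Stateful integrator over a :class:`SystemState`.

    Thin object wrapper over the jitted kernels; `run` advances in noise
    chunks, `step` is the single-step interface.
    """

    def __init__(
        self,
        state: SystemState,
        params: ForceFieldParams,
        settings: LangevinSettings,
        rng: np.random.Generator,
        thermal_velocities: bool = True,
    ):
        self.state = state
        self.params = params
        self.settings = settings
        self.rng = rng
        self.global_step = 0
        self.f_cap = 0.0
        self._k_bend = params.k_bend
        if thermal_velocities and settings.kT > 0:
            mob = state.mobile
            scale = np.sqrt(settings.kT / state.masses[mob])[:, None]
            state.velocities[mob] = scale * rng.standard_normal((mob.sum(), 3))
        self._setup_arrays()

    def _setup_arrays(self) -> None:
        st = self.state
        self.mobile_idx = np.flatnonzero(st.mobile).astype(np.int64)
        # bonded terms that involve at least one mobile bead (forces on
        # immobile beads are never used; energy scans keep the full lists)
        if len(st.bonds):
            bm = st.mobile[st.bonds].any(axis=1)
            self.bonds_active = st.bonds[bm]
        else:
            self.bonds_active = st.bonds
        if len(st.angles):
            am = st.mobile[st.angles].any(axis=1)
            self.angles_active = st.angles[am]
        else:
            self.angles_active = st.angles
        sig_max = float(st.sigmas.max()) if st.n else 1.0
        # few mobile beads -> cheap rebuilds dominated by the fixed scan,
        # so a fatter skin pays for itself
        self.skin = NEIGHBOR_SKIN if len(self.mobile_idx) > 10 else 2.0 * NEIGHBOR_SKIN
        self.rlist = max(LJ_MIN_FACTOR * sig_max, self.params.r_cut_debye) + self.skin
        cap = max(64, int(len(self.mobile_idx) * 140 + st.n))
        self.pair_i = np.zeros(cap, np.int64)
        self.pair_j = np.zeros(cap, np.int64)
        self.ref_pos = st.positions.copy()
        self.forces = np.zeros_like(st.positions)
        self.is_chain = ((st.species == CHAIN) | (st.species == TETHER)).astype(np.uint8)
        ti = st.tracer_index
        self.tracer_idx = -1 if ti is None else ti
        self._refresh_forces()

    def _refresh_forces(self) -> None:
        while True:
            n = _kernels._compute_forces(
                self.state.positions, self.mobile_idx, self.state.sigmas,
                self.state.charges, self.state.chain_id, self.state.chain_pos,
                self.bonds_active, self.angles_active,
                self.state.box[0], self.state.box[1],
                self.params.eps_lj, self.params.k_bond, self.params.r0,
                self._k_bend, self.params.theta0, self.params.coulomb_const,
                self.params.kappa, self.params.r_cut_debye, self.rlist,
                self.pair_i, self.pair_j, self.ref_pos, self.forces,
                self.f_cap,
            )
            if n >= 0:
                self.n_pairs = n
                return
            self._grow_pairs()

    def _grow_pairs(self) -> None:
        cap = 2 * len(self.pair_i)
        self.pair_i = np.zeros(cap, np.int64)
        self.pair_j = np.zeros(cap, np.int64)

    def freeze_chains(self) -> None:
        """Immobilize all chain beads (static mode after equilibration)."""
        st = self.state
        st.mobile[(st.species == CHAIN) | (st.species == TETHER)] = False
        st.velocities[~st.mobile] = 0.0
        self._setup_arrays()

    def run(
        self,
        n_steps: int,
        dump_every: int = 0,
        record_energy: int = 0,
    ) -> dict:
        """Advance ``n_steps``; optionally dump every ``dump_every`` steps.

        Returns a dict of dump arrays (empty when ``dump_every`` is 0).
        """
        st, se = self.state, self.settings
        outs = {k: [] for k in ("tracer", "energy", "in_brush", "max_z")}
        done = 0
        while done < n_steps:
            chunk = min(CHUNK_STEPS, n_steps - done)
            noise = self.rng.standard_normal((chunk, len(self.mobile_idx), 3))
            n_dump_cap = (chunk // max(dump_every, 1)) + 2 if dump_every else 1
            out_tracer = np.zeros((n_dump_cap, 3))
            out_energy = np.zeros((n_dump_cap, 6))
            out_inbrush = np.zeros(n_dump_cap, np.int64)
            out_maxz = np.zeros(n_dump_cap)
            pos_save = st.positions.copy()
            vel_save = st.velocities.copy()
            frc_save = self.forces.copy()
            while True:
                n_pairs, n_dumped, flag = _kernels._run_chunk(
                    st.positions, st.velocities, self.forces, self.mobile_idx,
                    st.masses, st.gammas, st.sigmas, st.charges,
                    st.chain_id, st.chain_pos, self.bonds_active, self.angles_active,
                    st.bonds, st.angles, st.box[0], st.box[1],
                    self.params.eps_lj, self.params.good_solvent,
                    self.params.k_bond, self.params.r0, self._k_bend,
                    self.params.theta0, self.params.coulomb_const,
                    self.params.kappa, self.params.r_cut_debye,
                    se.kT, se.dt, noise, self.skin, self.rlist,
                    self.pair_i, self.pair_j, self.n_pairs, self.ref_pos,
                    dump_every, self.global_step, self.tracer_idx,
                    self.is_chain, out_tracer, out_energy, out_inbrush,
                    out_maxz, int(record_energy), self.f_cap,
                )
                if flag == 1:
                    st.positions[:] = pos_save
                    st.velocities[:] = vel_save
                    self.forces[:] = frc_save
                    self._grow_pairs()
                    self._refresh_forces()
                    continue
                if flag == 2:
                    raise BlowUpError(
                        f"non-finite coordinate near step {self.global_step + chunk}"
                    )
                self.n_pairs = n_pairs
                break
            self.global_step += chunk
            done += chunk
            if dump_every:
                outs["tracer"].append(out_tracer[:n_dumped])
                outs["energy"].append(out_energy[:n_dumped])
                outs["in_brush"].append(out_inbrush[:n_dumped].astype(bool))
                outs["max_z"].append(out_maxz[:n_dumped])
        if dump_every:
            return {k: np.concatenate(v) for k, v in outs.items()}
        return {}

    def step(self, n: int = 1) -> None:
        self.run(n)

    def push_off(
        self,
        n_steps: int = 3000,
        f_cap: float = 50.0,
        v_max: float = 3.0,
    ) -> None:
        """Capped, displacement-limited relaxation of initial overlaps.

        Standard bead-spring equilibration trick: with the pair force
        capped, the timestep reduced, and velocities clamped near the
        thermal scale, interpenetrating starting configurations (relaxed
        worm-like-chain placement in dense brushes) separate smoothly
        instead of exploding.
        """
        st = self.state
        dt0 = self.settings.dt
        self.f_cap = f_cap
        self.settings.dt = dt0 * SOFT_START_FACTOR
        self._refresh_forces()  # recompute under the cap before kicking
        st.velocities[st.mobile] = 0.0
        done = 0
        while done < n_steps:
            self.run(100)
            done += 100
            v = st.velocities[st.mobile]
            speed = np.linalg.norm(v, axis=1)
            fast = speed > v_max
            if fast.any():
                v[fast] *= (v_max / speed[fast])[:, None]
                st.velocities[st.mobile] = v
        self.f_cap = 0.0
        self.settings.dt = dt0
        self._refresh_forces()

    def equilibrate(self, n_steps: int) -> None:
        """Equilibration with a reduced-timestep soft start.

        The first few hundred steps run at a fraction of dt so that any
        residual close contacts of the initial configuration relax
        without kicking the integrator unstable.
        """
        if n_steps <= 0:
            return
        soft = min(SOFT_START_STEPS, n_steps // 2)
        if soft > 0:
            dt0 = self.settings.dt
            self.settings.dt = dt0 * SOFT_START_FACTOR
            self.run(soft)
            self.settings.dt = dt0
        self.run(n_steps - soft)

    def current_tracer_energy(self) -> float:
        st = self.state
        if self.tracer_idx < 0:
            return 0.0
        return float(
            _kernels._tracer_energy(
                st.positions, st.sigmas, st.charges, st.box[0], st.box[1],
                self.params.eps_lj, self.params.good_solvent,
                self.params.coulomb_const, self.params.kappa,
                self.params.r_cut_debye, self.tracer_idx,
            )
        )

    def current_energies(self) -> np.ndarray:
        """Energy terms of the current configuration (ENERGY_COLUMNS order)."""
        st = self.state
        return np.array(
            _kernels._energy_scan(
                st.positions, st.sigmas, st.charges, st.chain_id, st.chain_pos,
                st.bonds, st.angles, st.box[0], st.box[1],
                self.params.eps_lj, self.params.good_solvent,
                self.params.k_bond, self.params.r0, self._k_bend,
                self.params.theta0, self.params.coulomb_const,
                self.params.kappa, self.params.r_cut_debye,
                self.tracer_idx, self.is_chain,
            )
        )


def langevin_step(
    state: SystemState,
    params: ForceFieldParams,
    settings: LangevinSettings,
    rng: np.random.Generator,
    n_steps: int = 1,
) -> SystemState:
    """Advance a state by ``n_steps`` BAOAB steps (convenience wrapper)."""
    integ = LangevinIntegrator(state, params, settings, rng, thermal_velocities=False)
    integ.step(n_steps)
    return integ.state


def realization_seed(base_seed: int, index: int) -> int:
    """Independent per-realization stream seed."""
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def run_realization(
    config: BrushConfig,
    params: ForceFieldParams,
    seed: int,
) -> Trajectory:
    """Equilibrate and produce one trajectory for the configured mode.

    dynamic / no_stiffness: chains and tracer mobile throughout (the
    bending term is dropped in no_stiffness).  static: chains equilibrated
    then frozen before production.  straight: frozen vertical chains, no
    chain equilibration.
    """
    eff_params = params
    if config.mode == "no_stiffness":
        eff_params = replace(params, k_bend=0.0)
    state = build_brush_system(config, eff_params, seed)
    rng = np.random.default_rng(seed)
    settings = LangevinSettings(gamma=config.gamma, kT=config.kT, dt=config.dt)
    integ = LangevinIntegrator(state, eff_params, settings, rng)

    if config.mode in ("dynamic", "static", "no_stiffness") and config.n_equil_steps:
        if config.init_mode == "wlc_relaxed":
            integ.push_off()
        integ.equilibrate(config.n_equil_steps)
    if config.mode == "static":
        integ.freeze_chains()
    return _produce(integ, config, seed)


def _produce(integ: LangevinIntegrator, config: BrushConfig, seed: int) -> Trajectory:
    """Run the production phase and package a Trajectory (frame 0 = origin)."""
    state = integ.state
    emode = ENERGY_MODE[config.energy_record]
    integ.global_step = 0
    ti = state.tracer_index
    frame0_pos = state.positions[ti].copy() if ti is not None else np.zeros(3)
    chain_mask = state.chain_mask
    maxz0 = float(state.positions[chain_mask, 2].max()) if chain_mask.any() else 0.0
    e0 = integ.current_energies() if emode == 1 else np.zeros(6)
    if emode == 2:
        e0[4] = integ.current_tracer_energy()

    out = integ.run(
        config.n_prod_steps, dump_every=config.dump_every, record_energy=emode
    )
    n_frames = len(out["tracer"]) + 1
    times = config.dt * config.dump_every * np.arange(n_frames)
    tracer = np.vstack([frame0_pos, out["tracer"]])
    in_brush = np.concatenate(
        [[ti is None or frame0_pos[2] <= maxz0], out["in_brush"]]
    )
    energies = np.vstack([e0, out["energy"]]) if emode else None
    max_z = np.concatenate([[maxz0], out["max_z"]])

    n_chains = int(chain_mask.sum()) // config.n_beads
    chain_final = state.positions[chain_mask].reshape(n_chains, config.n_beads, 3)
    return Trajectory(
        times=times,
        tracer_positions=tracer,
        in_brush=in_brush,
        max_chain_z=max_z,
        energies=energies,
        seed=seed,
        chain_positions_final=chain_final,
        n_chain_beads_per_chain=config.n_beads,
        n_chains=n_chains,
    )


def equilibrate_brush(
    config: BrushConfig,
    params: ForceFieldParams,
    seed: int,
) -> SystemState:
    """Equilibrate a tracer-free brush and freeze its chains.

    The returned state can host many independent tracer productions via
    :func:`run_static_tracer`, amortizing the chain equilibration — the
    static-mode observation that geometry, not chain dynamics, governs
    tracer diffusion makes this the economical way to sweep (d, charge)
    grids.
    """
    cfg = config.with_updates(with_tracer=False, mode="static")
    state = build_brush_system(cfg, params, seed)
    rng = np.random.default_rng(seed)
    settings = LangevinSettings(gamma=config.gamma, kT=config.kT, dt=config.dt)
    integ = LangevinIntegrator(state, params, settings, rng)
    if config.init_mode == "wlc_relaxed":
        integ.push_off()
    integ.equilibrate(config.n_equil_steps)
    integ.freeze_chains()
    return state


def run_static_tracer(
    frozen: SystemState,
    config: BrushConfig,
    params: ForceFieldParams,
    seed: int,
) -> Trajectory:
    """One tracer production inside a frozen, pre-equilibrated brush."""
    from .system import insert_tracer

    state = insert_tracer(frozen, config, params, seed)
    rng = np.random.default_rng(seed)
    settings = LangevinSettings(gamma=config.gamma, kT=config.kT, dt=config.dt)
    integ = LangevinIntegrator(state, params, settings, rng)
    return _produce(integ, config, seed)


def run_ensemble(config: BrushConfig, params: ForceFieldParams) -> list[Trajectory]:
    """Run ``config.n_realizations`` independent realizations."""
    return [
        run_realization(config, params, realization_seed(config.seed, k))
        for k in range(config.n_realizations)
    ]


def run_bulk(
    tracer_radius: float,
    settings: LangevinSettings,
    n_realizations: int,
    n_steps: int,
    dump_every: int,
    seed: int = 0,
    mass: Optional[float] = None,
    gamma: Optional[float] = None,
) -> list[Trajectory]:
    """Free-particle ensembles (F = 0): the bulk-diffusion reference.

    All realizations are integrated simultaneously with the same BAOAB
    O-step as the interacting code path.  Friction follows the Stokes law
    scaling gamma ~ a, and the mass scales with volume, relative to the
    0.5-sigma chain bead.
    """
    m = (tracer_radius / 0.5) ** 3 if mass is None else mass
    g = settings.gamma * tracer_radius / 0.5 if gamma is None else gamma
    rng = np.random.default_rng(seed)
    dt, kT = settings.dt, settings.kT
    c1 = math.exp(-g * dt / m)
    c2 = math.sqrt(kT * (1.0 - c1 * c1) / m)
    pos = np.zeros((n_realizations, 3))
    vel = math.sqrt(kT / m) * rng.standard_normal((n_realizations, 3))
    n_frames = n_steps // dump_every
    frames = np.zeros((n_frames, n_realizations, 3))
    k = 0
    for s in range(1, n_steps + 1):
        pos += 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.standard_normal((n_realizations, 3))
        pos += 0.5 * dt * vel
        if s % dump_every == 0:
            frames[k] = pos
            k += 1
    times = dt * dump_every * np.arange(n_frames + 1)
    trajs = []
    for r in range(n_realizations):
        trajs.append(
            Trajectory(
                times=times,
                tracer_positions=np.vstack([np.zeros(3), frames[:, r]]),
                in_brush=np.ones(n_frames + 1, bool),
                max_chain_z=np.full(n_frames + 1, np.inf),
                energies=None,
                seed=seed,
            )
        )
    return trajs


def run_free_chain_configs(
    config: BrushConfig,
    params: ForceFieldParams,
    n_samples: int,
    sample_every: int,
    n_burnin: int,
    seed: int = 0,
    charged: bool = False,
    excluded_volume: bool = False,
) -> list[np.ndarray]:
    """Sampled configurations of one free chain (persistence-length runs).

    By default the chain is phantom (stretching + bending only), the
    ensemble the discrete worm-like-chain persistence-length relation
    describes; ``excluded_volume`` switches the WCA repulsion back on,
    which measurably stiffens the apparent l_p at long contour
    separations.
    """
    if not excluded_volume:
        params = replace(params, eps_lj=0.0)
    state = build_free_chain(config.n_beads, config, params, seed, charged=charged)
    rng = np.random.default_rng(seed)
    settings = LangevinSettings(gamma=config.gamma, kT=config.kT, dt=config.dt)
    integ = LangevinIntegrator(state, params, settings, rng)
    integ.run(n_burnin)
    configs = []
    for _ in range(n_samples):
        integ.run(sample_every)
        configs.append(state.positions.copy())
    return configs
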