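"""Initial-configuration builder: wall lattice, tethered chains, tracer.

The substrate is a dense square lattice of immobile neutral beads at
z = 0 spanning the periodic (x, y) box of side ``grid_n * d``.  Each of
the ``grid_n**2`` chains is anchored by two immobile tether beads at
z = r0 and 2 r0 above its lattice point; the remaining beads are grown
upward, either near-vertically with a small seeded jitter or as an
equilibrium discrete worm-like-chain sample.  A single free tracer is
inserted close to the wall.  The box is periodic in x and y only; the
top is open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .params import BrushConfig, ForceFieldParams

WALL, TETHER, CHAIN, TRACER = 0, 1, 2, 3
SPECIES_NAMES = {WALL: "W", TETHER: "T", CHAIN: "C", TRACER: "P"}

#: minimum allowed initial separation, in units of the pair LJ diameter
MIN_SEPARATION_FACTOR = 0.9


class PlacementError(RuntimeError):
    """Raised when overlap-free insertion fails after bounded retries."""


class GeometryError(ValueError):
    """Raised when the requested geometry cannot accommodate the tracer."""


@dataclass
class SystemState:
    """Bead positions, velocities, species and topology of one system.

    Positions are kept unwrapped; the minimum-image convention in x, y is
    applied wherever distances are needed.
    """

    positions: np.ndarray          # (N, 3)
    velocities: np.ndarray         # (N, 3)
    species: np.ndarray            # (N,) int codes WALL/TETHER/CHAIN/TRACER
    mobile: np.ndarray             # (N,) bool
    masses: np.ndarray             # (N,)
    gammas: np.ndarray             # (N,)
    charges: np.ndarray            # (N,)
    sigmas: np.ndarray             # (N,) per-bead LJ diameter
    bonds: np.ndarray              # (Nb, 2) int
    angles: np.ndarray             # (Na, 3) int
    box: tuple[float, float]       # (Lx, Ly); z is open
    chain_id: np.ndarray           # (N,) int, -1 for wall/tracer
    chain_pos: np.ndarray          # (N,) int index along chain, -1 otherwise

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def tracer_index(self) -> Optional[int]:
        idx = np.flatnonzero(self.species == TRACER)
        return int(idx[0]) if len(idx) else None

    @property
    def chain_mask(self) -> np.ndarray:
        """Beads belonging to chains, tether beads included."""
        return (self.species == CHAIN) | (self.species == TETHER)

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            species=self.species.copy(),
            mobile=self.mobile.copy(),
            masses=self.masses.copy(),
            gammas=self.gammas.copy(),
            charges=self.charges.copy(),
            sigmas=self.sigmas.copy(),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            box=self.box,
            chain_id=self.chain_id.copy(),
            chain_pos=self.chain_pos.copy(),
        )


def min_image_displacements(dxy: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    """Apply the minimum-image convention in x, y (z is open)."""
    out = dxy.copy()
    for k, L in enumerate(box):
        out[..., k] -= L * np.rint(out[..., k] / L)
    return out


def _min_pair_distance(positions: np.ndarray, box: tuple[float, float]) -> float:
    d = positions[:, None, :] - positions[None, :, :]
    d = min_image_displacements(d, box)
    r = np.sqrt((d**2).sum(-1))
    np.fill_diagonal(r, np.inf)
    return float(r.min())


def _sample_wlc_directions(n: int, beta_k_bend: float, rng: np.random.Generator) -> np.ndarray:
    """Unit bond vectors of a discrete WLC started along +z.

    Bend angles follow the Boltzmann density ~ exp(-beta K (theta-pi)^2) sin(theta)
    (theta is the bead angle; pi means straight); azimuths are uniform.
    """
    from .synthetic import sample_bend_angles  # local import to avoid cycle

    dirs = np.zeros((n, 3))
    dirs[0] = (0.0, 0.0, 1.0)
    thetas = sample_bend_angles(n - 1, beta_k_bend, rng)
    phis = rng.uniform(0.0, 2.0 * np.pi, size=n - 1)
    for i in range(1, n):
        u = dirs[i - 1]
        # deflection angle between successive bond vectors
        alpha = np.pi - thetas[i - 1]
        # orthonormal frame around u
        a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        dirs[i] = (
            np.cos(alpha) * u
            + np.sin(alpha) * (np.cos(phis[i - 1]) * e1 + np.sin(phis[i - 1]) * e2)
        )
    return dirs


def _chain_coordinates(
    anchor: np.ndarray,
    config: BrushConfig,
    params: ForceFieldParams,
    rng: np.random.Generator,
    placed: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Coordinates of one chain (tether beads first), unwrapped.

    In WLC mode, candidate chains are rejected if they dip toward the
    wall, self-overlap (nonbonded pairs closer than 0.9 sigma) or come
    within 0.9 sigma (minimum image) of already-placed chain beads;
    returns None after bounded retries so the caller can fall back to an
    all-vertical build (rejection pressure is highest in dense brushes,
    exactly where the vertical start is closest to equilibrium).
    """
    n, r0 = config.n_beads, params.r0
    pos = np.zeros((n, 3))
    pos[0] = anchor + np.array([0.0, 0.0, r0])
    pos[1] = anchor + np.array([0.0, 0.0, 2 * r0])
    if config.init_mode == "near_vertical":
        jitter = rng.normal(0.0, 0.05, size=(n - 2, 2))
        for k in range(2, n):
            pos[k] = pos[1] + np.array([jitter[k - 2, 0], jitter[k - 2, 1], (k - 1) * r0])
        return pos
    beta_k = params.k_bend / config.kT
    min_sep = MIN_SEPARATION_FACTOR * params.sigma_lj

    def clashes(trial: np.ndarray) -> bool:
        # relaxed mode leaves interchain overlaps to the capped push-off
        if config.init_mode == "wlc_relaxed":
            return False
        if placed is None or not len(placed):
            return False
        delta = min_image_displacements(
            placed[None, :, :] - trial[:, None, :], config.box
        )
        return bool(np.sqrt((delta**2).sum(-1)).min() < min_sep)

    ii, jj = np.triu_indices(n, k=4)
    for _ in range(200):
        dirs = _sample_wlc_directions(n - 1, beta_k, rng)
        trial = np.empty((n, 3))
        trial[0], trial[1] = pos[0], pos[1]
        for k in range(2, n):
            trial[k] = trial[k - 1] + r0 * dirs[k - 1]
        if trial[2:, 2].min() <= params.r0:
            continue
        # self-overlap of nonbonded (|i-j| > 3) bead pairs
        dself = np.sqrt(((trial[:, None, :] - trial[None, :, :]) ** 2).sum(-1))
        if dself[ii, jj].min() < min_sep:
            continue
        if clashes(trial):
            continue
        return trial
    # this chain's vertical start, if it threads the already-placed coils
    vertical = _chain_coordinates(
        anchor, config.with_updates(init_mode="near_vertical"), params, rng
    )
    if not clashes(vertical):
        return vertical
    return None


def build_brush_system(
    config: BrushConfig,
    params: ForceFieldParams,
    rng_seed: int,
) -> SystemState:
    """Build the full wall + tethered-chains + tracer configuration.

    Deterministic for a given seed.  Raises :class:`GeometryError` when the
    tether spacing cannot accommodate the tracer and
    :class:`PlacementError` if overlap-free tracer insertion fails.
    """
    if config.d < 1.0:
        raise GeometryError("tether spacing d must be at least 1 sigma")
    if config.with_tracer and config.d < 2.0 * config.tracer_radius:
        raise GeometryError(
            f"d = {config.d} too small for tracer radius {config.tracer_radius}"
        )
    rng = np.random.default_rng(rng_seed)
    Lx, Ly = config.box

    # wall lattice: near-1-sigma spacing commensurate with the periodic box
    nwx = max(1, round(Lx / config.wall_spacing))
    nwy = max(1, round(Ly / config.wall_spacing))
    wx, wy = np.meshgrid(np.arange(nwx) * Lx / nwx, np.arange(nwy) * Ly / nwy)
    wall = np.column_stack([wx.ravel(), wy.ravel(), np.zeros(wx.size)])

    anchors = [
        np.array([i * config.d, j * config.d, 0.0])
        for i in range(config.grid_n)
        for j in range(config.grid_n)
    ]
    chains: list[np.ndarray] = []
    for anchor in anchors:
        placed = np.concatenate(chains) if chains else None
        c = _chain_coordinates(anchor, config, params, rng, placed)
        if c is None:  # WLC placement infeasible: rebuild all near-vertical
            vcfg = config.with_updates(init_mode="near_vertical")
            chains = [
                _chain_coordinates(a, vcfg, params, rng) for a in anchors
            ]
            break
        chains.append(c)
    chain_pos_all = np.concatenate(chains) if chains else np.zeros((0, 3))

    parts = [wall, chain_pos_all]
    n_wall = len(wall)
    n_chains = config.grid_n**2
    nb = config.n_beads

    species = np.concatenate(
        [
            np.full(n_wall, WALL),
            np.tile(
                np.concatenate(
                    [np.full(config.n_tether, TETHER), np.full(nb - config.n_tether, CHAIN)]
                ),
                n_chains,
            ),
        ]
    ).astype(np.int64)
    chain_id = np.concatenate(
        [np.full(n_wall, -1), np.repeat(np.arange(n_chains), nb)]
    ).astype(np.int64)
    chain_pos = np.concatenate(
        [np.full(n_wall, -1), np.tile(np.arange(nb), n_chains)]
    ).astype(np.int64)

    if config.with_tracer:
        fixed = np.concatenate(parts)
        sig_pair = 0.5 * (params.sigma_lj + 2.0 * config.tracer_radius)
        tracer = None
        for _ in range(2000):
            cand = np.array(
                [rng.uniform(0, Lx), rng.uniform(0, Ly), rng.uniform(2.0, 5.0)]
            )
            delta = min_image_displacements(fixed - cand, config.box)
            if np.sqrt((delta**2).sum(-1)).min() >= MIN_SEPARATION_FACTOR * sig_pair:
                tracer = cand
                break
        if tracer is None:
            raise PlacementError("could not insert tracer without overlap")
        parts.append(tracer[None, :])
        species = np.concatenate([species, [TRACER]])
        chain_id = np.concatenate([chain_id, [-1]])
        chain_pos = np.concatenate([chain_pos, [-1]])

    positions = np.concatenate(parts)
    n_total = len(positions)

    mobile = np.zeros(n_total, dtype=bool)
    mobile[species == CHAIN] = True
    if config.with_tracer:
        mobile[species == TRACER] = True
    if config.mode == "straight":
        mobile[species == CHAIN] = False

    masses = np.ones(n_total)
    gammas = np.full(n_total, config.gamma)
    charges = np.zeros(n_total)
    charges[(species == CHAIN) | (species == TETHER)] = params.chain_charge
    sigmas = np.full(n_total, params.sigma_lj)
    if config.with_tracer:
        ti = n_total - 1
        masses[ti] = config.tracer_mass
        gammas[ti] = config.tracer_gamma
        charges[ti] = config.tracer_charge
        sigmas[ti] = 2.0 * config.tracer_radius

    bonds, angs = [], []
    for c in range(n_chains):
        base = n_wall + c * nb
        for k in range(nb - 1):
            bonds.append((base + k, base + k + 1))
        for k in range(nb - 2):
            angs.append((base + k, base + k + 1, base + k + 2))
    bonds_a = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles_a = np.array(angs, dtype=np.int64).reshape(-1, 3)

    state = SystemState(
        positions=positions,
        velocities=np.zeros_like(positions),
        species=species,
        mobile=mobile,
        masses=masses,
        gammas=gammas,
        charges=charges,
        sigmas=sigmas,
        bonds=bonds_a,
        angles=angles_a,
        box=config.box,
        chain_id=chain_id,
        chain_pos=chain_pos,
    )
    if config.mode == "straight":
        state = straighten_chains(state, params.r0)
    return state


def straighten_chains(state: SystemState, r0: float = 1.0) -> SystemState:
    """Return a copy with all chains perfectly vertical and immobile.

    Bead k of each chain sits at z = (k + 1) * r0 above its tether lattice
    point, so a 101-bead chain tops out at z = 101 r0.
    """
    out = state.copy()
    for cid in np.unique(out.chain_id[out.chain_id >= 0]):
        idx = np.flatnonzero(out.chain_id == cid)
        idx = idx[np.argsort(out.chain_pos[idx])]
        anchor_xy = out.positions[idx[0], :2]
        for rank, i in enumerate(idx):
            out.positions[i] = (*anchor_xy, (rank + 1) * r0)
    out.mobile[out.chain_mask] = False
    out.velocities[out.chain_mask] = 0.0
    return out


def build_free_chain(
    n_beads: int,
    config: BrushConfig,
    params: ForceFieldParams,
    rng_seed: int,
    charged: bool = False,
) -> SystemState:
    """A single untethered chain in a large open box (no wall, no tracer).

    Used for persistence-length calibration; the chain is neutral unless
    ``charged`` is set.  Initialized from an equilibrium worm-like-chain
    sample so that bond-vector correlations start stationary at every
    contour separation (a straight start would need Rouse-scale
    equilibration before long-range correlations relax).
    """
    rng = np.random.default_rng(rng_seed)
    dirs = _sample_wlc_directions(n_beads - 1, params.k_bend / config.kT, rng)
    pos = np.vstack([np.zeros(3), np.cumsum(params.r0 * dirs, axis=0)])
    pos[:, 2] += 10.0 * params.r0  # keep clear of z = 0 conventions
    box = (1e6, 1e6)
    bonds = np.array([(k, k + 1) for k in range(n_beads - 1)], dtype=np.int64)
    angles = np.array(
        [(k, k + 1, k + 2) for k in range(n_beads - 2)], dtype=np.int64
    ).reshape(-1, 3)
    charges = np.full(n_beads, params.chain_charge if charged else 0.0)
    return SystemState(
        positions=pos,
        velocities=np.zeros_like(pos),
        species=np.full(n_beads, CHAIN, dtype=np.int64),
        mobile=np.ones(n_beads, dtype=bool),
        masses=np.ones(n_beads),
        gammas=np.full(n_beads, config.gamma),
        charges=charges,
        sigmas=np.full(n_beads, params.sigma_lj),
        bonds=bonds,
        angles=angles,
        box=box,
        chain_id=np.zeros(n_beads, dtype=np.int64),
        chain_pos=np.arange(n_beads, dtype=np.int64),
    )


def insert_tracer(
    state: SystemState,
    config: BrushConfig,
    params: ForceFieldParams,
    rng_seed: int,
) -> SystemState:
    """Append an overlap-free tracer close to the wall of an existing state.

    Used for static-brush productions where many tracer realizations
    share one equilibrated (frozen) chain configuration.
    """
    if state.tracer_index is not None:
        raise ValueError("state already contains a tracer")
    rng = np.random.default_rng(rng_seed)
    Lx, Ly = state.box
    sig_pair = 0.5 * (state.sigmas + 2.0 * config.tracer_radius)
    cand = None
    for _ in range(2000):
        trial = np.array(
            [rng.uniform(0, Lx), rng.uniform(0, Ly), rng.uniform(2.0, 5.0)]
        )
        delta = min_image_displacements(state.positions - trial, state.box)
        r = np.sqrt((delta**2).sum(-1))
        if np.all(r >= MIN_SEPARATION_FACTOR * sig_pair):
            cand = trial
            break
    if cand is None:
        raise PlacementError("could not insert tracer without overlap")
    out = state.copy()
    out.positions = np.vstack([out.positions, cand])
    out.velocities = np.vstack([out.velocities, np.zeros(3)])
    out.species = np.concatenate([out.species, [TRACER]])
    out.mobile = np.concatenate([out.mobile, [True]])
    out.masses = np.concatenate([out.masses, [config.tracer_mass]])
    out.gammas = np.concatenate([out.gammas, [config.tracer_gamma]])
    out.charges = np.concatenate([out.charges, [config.tracer_charge]])
    out.sigmas = np.concatenate([out.sigmas, [2.0 * config.tracer_radius]])
    out.chain_id = np.concatenate([out.chain_id, [-1]])
    out.chain_pos = np.concatenate([out.chain_pos, [-1]])
    return out


def minimum_initial_distance(state: SystemState) -> float:
    """Smallest pairwise distance in the configuration (minimum image)."""
    return _min_pair_distance(state.positions, state.box)
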