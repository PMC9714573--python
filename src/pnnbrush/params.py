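"""Force-field constants and brush/run configuration.

Defaults are the calibrated glycosaminoglycan-brush parameters: harmonic
stretching K_bond = 140.2 eps_E/sigma^2 and bending K_bend = 14.02
eps_E/rad^2 (tuned for a 10 nm persistence length at kT = 2.804 eps_E),
a WCA-truncated Lennard-Jones repulsion (eps_LJ = 0.73, cutoff at the
minimum 2^(1/6) sigma, good-solvent conditions) and a Debye-Hueckel
screened Coulomb interaction with screening length 1/kappa = 1 sigma and
cutoff 3 sigma.  Chain beads carry charge -e; the wall is neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .units import DEFAULT_ENERGY_UNIT_J, DEFAULT_KT

#: Bjerrum length of water near physiological temperature, in sigma (nm).
BJERRUM_LENGTH = 0.7

#: Debye prefactor C/eps in reduced units: the Coulomb energy of two unit
#: charges at 1 sigma (1 nm) in water (eps_r ~ 80), expressed in eps_E.
#: Computed from physical constants through the model's energy unit, so it
#: is independent of the reduced simulation temperature.
_E_CHARGE = 1.602176634e-19      # C
_EPS0 = 8.8541878128e-12         # F/m
_EPS_R_WATER = 80.0
COULOMB_CONST_WATER = (
    _E_CHARGE**2 / (4.0 * math.pi * _EPS0 * _EPS_R_WATER * 1e-9)
) / DEFAULT_ENERGY_UNIT_J

#: LJ minimum / WCA cutoff position in units of sigma_LJ.
LJ_MIN_FACTOR = 2.0 ** (1.0 / 6.0)

MODES = ("dynamic", "static", "straight", "no_stiffness")


@dataclass
class ForceFieldParams:
    """All interaction constants, in reduced units."""

    eps_lj: float = 0.73
    sigma_lj: float = 1.0            # chain/wall bead LJ diameter
    k_bond: float = 140.2
    r0: float = 1.0
    k_bend: float = 14.02
    theta0: float = math.pi
    #: Debye prefactor (C/eps in the pair formula), energy*length/charge^2.
    #: Defaults to the physical Coulomb coupling in water (~8.5 eps_E sigma);
    #: set to kT * l_B for a Bjerrum-length parameterization instead.
    coulomb_const: float = COULOMB_CONST_WATER
    kappa: float = 1.0
    r_cut_debye: float = 3.0
    chain_charge: float = -1.0
    good_solvent: bool = True        # WCA truncation + energy shift

    def __post_init__(self) -> None:
        if self.sigma_lj <= 0 or self.r0 < 0:
            raise ValueError("sigma_lj must be positive and r0 non-negative")
        if self.kappa <= 0 or self.r_cut_debye <= 0:
            raise ValueError("kappa and r_cut_debye must be positive")

    @property
    def r_cut_lj(self) -> float:
        """LJ cutoff for the reference (chain-bead) diameter."""
        return LJ_MIN_FACTOR * self.sigma_lj

    def r_cut_lj_pair(self, sigma_pair: float) -> float:
        return LJ_MIN_FACTOR * sigma_pair


@dataclass
class BrushConfig:
    """Geometry and run control for one brush system.

    ``mode`` selects the system type: ``dynamic`` (chains and tracer both
    integrated), ``static`` (chains equilibrated then frozen), ``straight``
    (perfectly vertical frozen chains, no equilibration) or
    ``no_stiffness`` (dynamic with the bending term removed).
    """

    d: float = 3.0                   # tether lattice spacing, sigma
    grid_n: int = 3                  # n x n quadratic tether grid
    n_beads: int = 101               # beads per chain, tether included
    n_tether: int = 2                # immobile beads per chain
    tracer_radius: float = 0.5       # a, sigma
    tracer_charge: float = 0.0       # units of e
    mode: str = "dynamic"
    gamma: float = 1.0               # friction, mass/tau (chain beads)
    kT: float = DEFAULT_KT
    dt: float = 0.005
    n_equil_steps: int = 50_000
    n_prod_steps: int = 20_000
    dump_every: int = 50
    seed: int = 0
    n_realizations: int = 100
    wall_spacing: float = 1.0        # target wall lattice spacing, sigma
    init_mode: str = "near_vertical"  # "wlc" | "wlc_relaxed" also allowed
    with_tracer: bool = True
    record_chain_frames: bool = False
    energy_record: str = "full"      # "full" | "tracer" | "none"

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n_beads < self.n_tether:
            raise ValueError("n_beads must be >= n_tether")
        if self.init_mode not in ("near_vertical", "wlc", "wlc_relaxed"):
            raise ValueError(
                "init_mode must be 'near_vertical', 'wlc' or 'wlc_relaxed'"
            )
        if self.energy_record not in ("full", "tracer", "none"):
            raise ValueError("energy_record must be 'full', 'tracer' or 'none'")
        if self.dt <= 0 or self.dt > self.stability_dt_bound():
            raise ValueError(
                f"dt must be in (0, {self.stability_dt_bound():.4f}] "
                "(a fraction of the bond vibration period)"
            )

    def stability_dt_bound(self, k_bond: float = 140.2) -> float:
        """Conservative timestep bound: 1/10 of the bond angular period."""
        omega = math.sqrt(2.0 * k_bond)  # unit mass
        return 2.0 * math.pi / omega / 10.0

    @property
    def box(self) -> tuple[float, float]:
        return (self.grid_n * self.d, self.grid_n * self.d)

    @property
    def tracer_mass(self) -> float:
        """Tracer mass scales with volume relative to a 0.5-sigma bead."""
        return (self.tracer_radius / 0.5) ** 3

    @property
    def tracer_gamma(self) -> float:
        """Stokes friction is linear in radius: gamma proportional to a."""
        return self.gamma * self.tracer_radius / 0.5

    def with_updates(self, **kw) -> "BrushConfig":
        return replace(self, **kw)
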