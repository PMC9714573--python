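"""Reduced (Lennard-Jones) unit system and the mapping to physical units.

The simulation works in reduced units: the unit of length is the size of
one coarse-grained disaccharide bead (sigma = 1 nm), the unit of mass is
the bead mass, and the unit of energy ``epsilon_E`` is fixed by
identifying the reduced LJ well depth 0.73 with the 0.15 kJ/mol
carbon-carbon interaction used in the underlying GAG coarse-graining.
The derived time unit is ``tau = sigma * sqrt(m / epsilon_E)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Default physical mass of one disaccharide bead, kg (~400 g/mol).
DEFAULT_BEAD_MASS_KG = 400e-3 / N_AVOGADRO

#: Default physical energy unit, J: eps_LJ = 0.73 eps_E <-> 0.15 kJ/mol.
DEFAULT_ENERGY_UNIT_J = (0.15e3 / 0.73) / N_AVOGADRO

#: Reduced temperature kT in units of eps_E.  Chosen so that the discrete
#: worm-like-chain relation l_p ~ 2 K_bend r0 / kT reproduces the
#: calibrated persistence length of 10 nm with K_bend = 14.02.
DEFAULT_KT = 2 * 14.02 / 10.0


@dataclass
class UnitSystem:
    """Reduced unit system with an optional mapping to SI.

    Parameters
    ----------
    length_unit_m:
        Physical length of 1 sigma, metres (1 nm: one disaccharide unit).
    energy_unit_J:
        Physical energy of 1 eps_E, joules.
    mass_unit_kg:
        Physical mass of one chain bead (reduced mass 1), kilograms.
    kT:
        Thermal energy in reduced units (eps_E).
    """

    length_unit_m: float = 1e-9
    energy_unit_J: float = DEFAULT_ENERGY_UNIT_J
    mass_unit_kg: float = DEFAULT_BEAD_MASS_KG
    kT: float = DEFAULT_KT

    def __post_init__(self) -> None:
        for name in ("length_unit_m", "energy_unit_J", "mass_unit_kg", "kT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def time_unit_s(self) -> float:
        """Derived time unit tau = sigma * sqrt(m / eps_E), seconds."""
        return self.length_unit_m * math.sqrt(self.mass_unit_kg / self.energy_unit_J)

    def time_to_seconds(self, t_reduced: float) -> float:
        """Convert a reduced time (units of tau) to seconds."""
        return t_reduced * self.time_unit_s

    def diffusion_to_si(self, d_reduced: float) -> float:
        """Convert a diffusion constant from sigma^2/tau to m^2/s."""
        return d_reduced * self.length_unit_m**2 / self.time_unit_s


def physical_time(n_steps: int, dt: float, units: UnitSystem) -> float:
    """Physical duration, in seconds, of ``n_steps`` integrator steps.

    ``dt`` is the timestep in reduced time units.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    return units.time_to_seconds(n_steps * dt)
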