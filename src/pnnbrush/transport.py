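"""Porosity, tortuosity/effective-diffusion models, scaling fits, and the
conductivity/resistance endpoint.

The brush porosity treats the chain beads as spheres of radius a_f:

    phi = 1 - (4/3) pi a_f^3 N_bead / (d^2 L_z).

Tortuosity models map phi to a path-inflation factor tau with
D_eff = D_bulk / tau^2: hyperbola of revolution (tau^2 = 2 - phi),
ordered packings (tau^2 = (3 - phi)/2), heterogeneous catalyst
(tau^2 = phi / (1 - (1-phi)^(1/3))), cation-exchange resin
(tau = (2 - phi)/phi, the Mackie-Meares lattice walk) and a generalized
random-walk model tau = 1 + p_first/(1 - p_next) with p_first = 1 - phi
and p_next = k + (k - 1)(1 - phi), k a tunable parameter in (0, 1) —
this reduces identically to Mackie-Meares for p_next = (2 - phi)/2.

When a model is fitted to simulated D(d)/D_bulk data, the bead radius
a_f is left free (the models were not built for brushes, so a_f acts as
an effective obstacle size) and phi is evaluated from the simulated
brush height L_z(d); the fitted a_f can push the formal phi below zero,
which these tau(phi) expressions tolerate — only the physical
``porosity`` entry point enforces phi in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import curve_fit

FARADAY = 96485.33212          # C/mol
GAS_CONSTANT = 8.31446         # J/(mol K)

TORTUOSITY_FAMILIES = (
    "hyperbola_of_revolution",
    "ordered_packings",
    "heterogeneous_catalyst",
    "cation_exchange_resin",
    "custom",
)
FIT_FAMILIES = TORTUOSITY_FAMILIES + ("power_law_d", "ratio_power_law", "height_scaling")

#: physical chain-bead radius (sigma) used for phi in the custom-model fit
CUSTOM_MODEL_BEAD_RADIUS = 0.5


class OverpackedGeometryError(ValueError):
    """Porosity came out non-positive: beads overfill the brush volume."""


@dataclass
class ModelFit:
    family: str
    params: dict[str, float]
    param_stds: dict[str, float]
    residual_norm: float
    fit_range_d: tuple[float, float]


@dataclass
class IonMixture:
    """Ionic species as (valency, concentration mol/m^3, D m^2/s) triples."""

    species: Sequence[tuple[int, float, float]]
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("mixture needs at least one species")
        for z, c, D in self.species:
            if c < 0:
                raise ValueError("concentrations must be non-negative")
            if D < 0:
                raise ValueError("diffusion constants must be non-negative")


def porosity_raw(a_f: float, n_bead: int, d: float, L_z: float) -> float:
    """Porosity formula without domain checks (fitting path)."""
    return 1.0 - (4.0 / 3.0) * np.pi * a_f**3 * n_bead / (d**2 * L_z)


def porosity(a_f: float, n_bead: int, d: float, L_z: float) -> float:
    """Fraction of brush volume not occupied by beads; must land in (0, 1]."""
    if a_f < 0 or n_bead < 0 or d <= 0 or L_z <= 0:
        raise ValueError("porosity inputs must be positive")
    phi = porosity_raw(a_f, n_bead, d, L_z)
    if phi <= 0:
        raise OverpackedGeometryError(f"phi = {phi:.4f} <= 0")
    return float(phi)


def generalized_tau(p_first: float, p_next: float) -> float:
    """Closed form of the generalized lattice-walk tortuosity.

    tau = 1 + p_first / (1 - p_next): the geometric sum over consecutive
    obstacle encounters, each adding extra path with probability p_next.
    """
    if not 0.0 <= p_first <= 1.0:
        raise ValueError("p_first must be in [0, 1]")
    if p_next >= 1.0:
        raise ValueError("p_next >= 1 makes the walk series diverge")
    return 1.0 + p_first / (1.0 - p_next)


def generalized_tau_series(p_first: float, p_next: float, n_terms: int) -> float:
    """Truncated-series form of :func:`generalized_tau` (oracle)."""
    n = np.arange(n_terms)
    return 1.0 + p_first * float(np.sum(p_next**n))


def custom_p_next(phi: float, k: float) -> float:
    """Obstacle-continuation probability of the generalized model."""
    return k + (k - 1.0) * (1.0 - phi)


def tau_squared(family: str, phi, params: Optional[dict] = None):
    """tau^2 for one model family; D_eff/D_bulk = 1/tau^2.

    ``phi`` may be a scalar or array.  The ``custom`` family needs
    ``params={'k': ...}`` and requires p_next in (0, 1) for scalar input.
    """
    phi = np.asarray(phi, dtype=float)
    if family == "hyperbola_of_revolution":
        out = 2.0 - phi
    elif family == "ordered_packings":
        out = (3.0 - phi) / 2.0
    elif family == "heterogeneous_catalyst":
        out = phi / (1.0 - np.cbrt(1.0 - phi))
    elif family == "cation_exchange_resin":
        out = ((2.0 - phi) / phi) ** 2
    elif family == "custom":
        k = params["k"]
        p_next = custom_p_next(phi, k)
        if phi.ndim == 0 and not (0.0 < float(p_next) < 1.0):
            raise ValueError(f"custom model p_next = {float(p_next):.4f} not in (0, 1)")
        out = (1.0 + (1.0 - phi) / (1.0 - p_next)) ** 2
    else:
        raise ValueError(f"unknown tortuosity family {family!r}")
    return out[()] if np.ndim(phi) == 0 else out


def _phi_of_d(d, a_f: float, n_bead: int, L_z) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    L = L_z(d) if callable(L_z) else np.asarray(L_z, dtype=float)
    return porosity_raw(a_f, n_bead, d, L)


def fit_D_vs_d(
    d: np.ndarray,
    D_over_Dbulk: np.ndarray,
    family: str,
    L_z,
    n_bead: int = 101,
    fit_range: tuple[float, float] = (2.0, 10.0),
    sigma: Optional[np.ndarray] = None,
    alt_power_law: bool = False,
) -> ModelFit:
    """Fit one effective-diffusion model to a D(d)/D_bulk table.

    Tortuosity families are fitted with the bead radius a_f free
    (Levenberg-Marquardt); the custom family fixes a_f = 0.5 sigma and
    fits k within (0, 1) by bounded trust region; the d power law fits
    D/D_bulk = 1 - d^(-n)/c (or 1 - c d^(-n) with ``alt_power_law``).
    ``L_z`` is the simulated brush height per d (array aligned with d, or
    a callable).
    """
    d = np.asarray(d, float)
    D = np.asarray(D_over_Dbulk, float)
    keep = (d >= fit_range[0]) & (d <= fit_range[1])
    if keep.sum() < 3:
        raise ValueError("need at least 3 points inside the fit range")
    dd, DD = d[keep], D[keep]
    Lk = L_z(dd) if callable(L_z) else np.asarray(L_z, float)[keep]
    sg = None if sigma is None else np.asarray(sigma, float)[keep]
    order = np.argsort(dd)
    dd, DD, Lk = dd[order], DD[order], Lk[order]
    if sg is not None:
        sg = sg[order]

    if family in ("hyperbola_of_revolution", "ordered_packings",
                  "heterogeneous_catalyst", "cation_exchange_resin"):
        def model(x, a_f):
            phi = porosity_raw(a_f, n_bead, x, np.interp(x, dd, Lk))
            return 1.0 / tau_squared(family, phi)

        popt, pcov = curve_fit(model, dd, DD, p0=[1.0], sigma=sg, method="lm", maxfev=20000)
        names = ["a_f"]
    elif family == "custom":
        phi = porosity_raw(CUSTOM_MODEL_BEAD_RADIUS, n_bead, dd, Lk)

        def model(x, k):
            pn = custom_p_next(np.interp(x, dd, phi), k)
            return 1.0 / (1.0 + (1.0 - np.interp(x, dd, phi)) / (1.0 - pn)) ** 2

        popt, pcov = curve_fit(
            model, dd, DD, p0=[0.9], sigma=sg, bounds=(1e-6, 1 - 1e-6), method="trf",
            maxfev=20000,
        )
        names = ["k"]
    elif family == "power_law_d":
        if alt_power_law:
            def model(x, n, c):
                return 1.0 - c * x ** (-n)
        else:
            def model(x, n, c):
                return 1.0 - x ** (-n) / c

        popt, pcov = curve_fit(model, dd, DD, p0=[0.5, 1.0], sigma=sg, method="lm", maxfev=20000)
        names = ["n", "c"]
    else:
        raise ValueError(f"family {family!r} is not a D(d) fit family")
    resid = DD - model(dd, *popt)
    perr = np.sqrt(np.diag(pcov))
    return ModelFit(
        family=family,
        params=dict(zip(names, map(float, popt))),
        param_stds=dict(zip(names, map(float, perr))),
        residual_norm=float(np.linalg.norm(resid)),
        fit_range_d=(float(dd.min()), float(dd.max())),
    )


def fit_ratio_power_law(
    d: np.ndarray,
    ratio: np.ndarray,
    fit_range: tuple[float, float] = (2.5, 25.0),
    sigma: Optional[np.ndarray] = None,
) -> ModelFit:
    """Fit the anisotropy ratio D_perp/D_par to A d^(-l) + 1.

    Points with ratio <= 1 stay in the fit (they only vanish from log-log
    diagnostics).
    """
    d = np.asarray(d, float)
    r = np.asarray(ratio, float)
    keep = (d >= fit_range[0]) & (d <= fit_range[1]) & (r > 0)
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive ratio points in range")
    dd, rr = d[keep], r[keep]
    sg = None if sigma is None else np.asarray(sigma, float)[keep]

    def model(x, A, l):
        return A * x ** (-l) + 1.0

    popt, pcov = curve_fit(model, dd, rr, p0=[10.0, 2.0], sigma=sg, method="lm", maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    return ModelFit(
        family="ratio_power_law",
        params={"A": float(popt[0]), "l": float(popt[1])},
        param_stds={"A": float(perr[0]), "l": float(perr[1])},
        residual_norm=float(np.linalg.norm(rr - model(dd, *popt))),
        fit_range_d=(float(dd.min()), float(dd.max())),
    )


def fit_height_scaling(d: np.ndarray, L_z: np.ndarray) -> ModelFit:
    """One-parameter fit of the mean-field brush-height law L_z = A d^(-2/3)."""
    d = np.asarray(d, float)
    L = np.asarray(L_z, float)
    if len(d) < 3:
        raise ValueError("need at least 3 points")

    def model(x, A):
        return A * x ** (-2.0 / 3.0)

    popt, pcov = curve_fit(model, d, L, p0=[float(L[0] * d[0] ** (2 / 3))], maxfev=20000)
    return ModelFit(
        family="height_scaling",
        params={"A": float(popt[0])},
        param_stds={"A": float(np.sqrt(pcov[0, 0]))},
        residual_norm=float(np.linalg.norm(L - model(d, *popt))),
        fit_range_d=(float(d.min()), float(d.max())),
    )


def conductivity(mixture: IonMixture) -> float:
    """Nernst-Einstein electrolyte conductivity, S/m.

    sigma_e = F^2/(R T) * sum_x D_x z_x^2 [x].
    """
    s = sum(D * z**2 * c for z, c, D in mixture.species)
    return FARADAY**2 / (GAS_CONSTANT * mixture.temperature) * s


def shell_resistance(rho_e: float, r_neuron: float, h: float) -> float:
    """Resistance of a spherical shell of thickness h around radius r.

    R = rho_e h / (4 pi r (r + h)), the integral of rho/(4 pi r'^2) dr'
    over [r, r + h].  SI units throughout.
    """
    if r_neuron <= 0 or h < 0 or rho_e <= 0:
        raise ValueError("rho_e, r_neuron must be positive and h non-negative")
    return rho_e * h / (4.0 * np.pi * r_neuron * (r_neuron + h))


def shell_resistance_quadrature(rho_e: float, r_neuron: float, h: float) -> float:
    """Numeric-quadrature oracle for :func:`shell_resistance`."""
    val, _ = quad(lambda r: rho_e / (4.0 * np.pi * r**2), r_neuron, r_neuron + h)
    return val


def traversal_time(D_perp: float, h: float) -> float:
    """Mean one-dimensional diffusion time across a slab: t = h^2 / (2 D).

    Units are the caller's: pass reduced quantities to get reduced time,
    or convert D via :meth:`pnnbrush.units.UnitSystem.diffusion_to_si`
    first for a physical answer.
    """
    if D_perp <= 0:
        raise ValueError("D_perp must be positive")
    return h**2 / (2.0 * D_perp)


#: CSF-like ionic concentrations (mol/m^3 = mM), grouped by valency.
#: External physiological reference values (interstitial/cerebrospinal
#: fluid): Na+ 145, K+ 3, Ca2+ 1.2, Mg2+ 1, Cl- 120, HCO3- 25.
CSF_CONCENTRATIONS: dict[int, float] = {
    +1: 145.0 + 3.0,
    -1: 120.0 + 25.0,
    +2: 1.2 + 1.0,
}


def csf_like_mixture(D_by_valency: dict[int, float], temperature: float = 310.0) -> IonMixture:
    """Build the CSF-like mixture, one pooled species per valency.

    ``D_by_valency`` maps a signed valency to its diffusion constant in
    m^2/s (typically from charged-tracer simulations at matching charge;
    divalent species fall back to the matching monovalent D scaled by
    nothing — supply +2/-2 entries to override).
    """
    species = []
    for z, c in CSF_CONCENTRATIONS.items():
        D = D_by_valency.get(z)
        if D is None:
            D = D_by_valency.get(int(np.sign(z)))
        if D is None:
            raise ValueError(f"no diffusion constant for valency {z:+d}")
        species.append((z, c, D))
    return IonMixture(species=species, temperature=temperature)
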