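import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnnbrush.transport import (
    CSF_CONCENTRATIONS,
    FARADAY,
    GAS_CONSTANT,
    IonMixture,
    OverpackedGeometryError,
    conductivity,
    csf_like_mixture,
    custom_p_next,
    fit_D_vs_d,
    fit_height_scaling,
    fit_ratio_power_law,
    generalized_tau,
    generalized_tau_series,
    porosity,
    shell_resistance,
    shell_resistance_quadrature,
    tau_squared,
    traversal_time,
)

PHI_GRID = np.linspace(0.05, 1.0, 40)
FAMILIES = [
    "hyperbola_of_revolution",
    "ordered_packings",
    "heterogeneous_catalyst",
    "cation_exchange_resin",
]


def test_porosity_limits_and_example():
    assert porosity(0.0, 101, 3.0, 50.0) == 1.0
    assert porosity(0.5, 101, 1e9, 50.0) == pytest.approx(1.0)
    # direct evaluation: a_f = 0.5, N = 101, d = 3, L_z = 50
    expected = 1 - (4 / 3) * np.pi * 0.125 * 101 / (9 * 50)
    assert porosity(0.5, 101, 3.0, 50.0) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.8825, abs=5e-4)


def test_porosity_overpacked_error():
    with pytest.raises(OverpackedGeometryError):
        porosity(2.0, 101, 2.0, 10.0)


@pytest.mark.parametrize("family", FAMILIES + ["custom"])
def test_tau_squared_bulk_limit(family):
    params = {"k": 0.9} if family == "custom" else None
    assert tau_squared(family, 1.0, params) == pytest.approx(1.0)


@pytest.mark.parametrize("family", FAMILIES)
def test_tau_squared_bounded_and_monotone(family):
    t2 = tau_squared(family, PHI_GRID)
    assert np.all(t2 >= 1.0 - 1e-12)
    assert np.all(np.diff(t2) <= 1e-12)  # non-increasing in phi


def test_custom_model_bounded_and_monotone():
    for k in (0.6, 0.9, 0.98):
        phi = PHI_GRID[custom_p_next(PHI_GRID, k) > 0]
        t2 = tau_squared("custom", phi, {"k": k})
        assert np.all(t2 >= 1.0 - 1e-12)
        assert np.all(np.diff(t2) <= 1e-12)


def test_cation_exchange_value():
    assert tau_squared("cation_exchange_resin", 0.5) == pytest.approx(9.0)


def test_custom_reduces_to_mackie_meares():
    """p_next = (2 - phi)/2 collapses the generalized walk onto tau = (2-phi)/phi."""
    phi = np.linspace(0.05, 0.999, 200)
    k = 0.5 + (1 - phi) / (2 - phi)  # k such that p_next = (2 - phi)/2
    tau = 1 + (1 - phi) / (1 - custom_p_next(phi, k))
    assert np.allclose(tau, (2 - phi) / phi, rtol=1e-12)
    for p, kk in zip(phi[::40], k[::40]):
        assert custom_p_next(p, kk) == pytest.approx((2 - p) / 2, rel=1e-12)


def test_generalized_tau_closed_form_vs_series():
    for pf in (0.0, 0.3, 1.0):
        for pn in (0.0, 0.5, 0.9):
            closed = generalized_tau(pf, pn)
            assert abs(closed - generalized_tau_series(pf, pn, 400)) < 1e-10
    assert generalized_tau(0.0, 0.5) == 1.0
    assert generalized_tau(0.5, 0.75) == pytest.approx(3.0)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    pf=st.floats(0.0, 1.0),
    pn=st.floats(0.0, 0.95),
)
def test_generalized_tau_series_property(pf, pn):
    """Closed form equals the truncated geometric sum for any admissible
    (p_first, p_next), and obstacles never shorten the path."""
    closed = generalized_tau(pf, pn)
    assert closed >= 1.0
    assert abs(closed - generalized_tau_series(pf, pn, 700)) < 1e-9 * max(closed, 1.0)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    phi=st.floats(0.02, 1.0),
    k=st.floats(0.05, 0.99),
)
def test_custom_model_tau_bounded_property(phi, k):
    """Wherever the continuation probability is admissible, tau^2 >= 1."""
    pn = custom_p_next(phi, k)
    if not 0.0 < pn < 1.0:
        return
    assert tau_squared("custom", phi, {"k": k}) >= 1.0 - 1e-12


def test_generalized_tau_divergence_error():
    with pytest.raises(ValueError):
        generalized_tau(0.5, 1.0)
    with pytest.raises(ValueError):
        generalized_tau(1.5, 0.5)


def _synthetic_D(d, family, params, a_f=0.5, L_z=None):
    L = np.full_like(d, 60.0) if L_z is None else L_z
    phi = 1 - (4 / 3) * np.pi * a_f**3 * 101 / (d**2 * L)
    return 1.0 / tau_squared(family, phi, params), L


def test_fit_recovers_custom_k_with_noise():
    rng = np.random.default_rng(0)
    d = np.array([2.0, 3.0, 4.0, 5.0, 7.0, 10.0])
    D, L = _synthetic_D(d, "custom", {"k": 0.96})
    noisy = D * (1 + 0.01 * rng.standard_normal(len(d)))
    fit = fit_D_vs_d(d, noisy, "custom", L)
    assert abs(fit.params["k"] - 0.96) < max(2 * fit.param_stds["k"], 0.01)


@pytest.mark.parametrize("family", FAMILIES[:3])
def test_fit_recovers_af_noiseless(family):
    d = np.array([2.0, 3.0, 4.0, 5.0, 7.0, 10.0])
    D, L = _synthetic_D(d, family, None, a_f=0.8)
    fit = fit_D_vs_d(d, D, family, L)
    assert fit.params["a_f"] == pytest.approx(0.8, rel=1e-5)


def test_power_law_fit_bulk_limit():
    d = np.array([2.0, 3.0, 5.0, 7.0, 10.0])
    fit = fit_D_vs_d(d, np.ones_like(d), "power_law_d", np.full_like(d, 60.0))
    n, c = fit.params["n"], fit.params["c"]
    assert np.allclose(1 - d ** (-n) / c, 1.0, atol=1e-6)


def test_power_law_fit_recovers_parameters():
    d = np.array([2.0, 2.5, 3.0, 4.0, 5.0, 7.0, 10.0])
    D = 1 - d ** (-0.5) / 1.2
    fit = fit_D_vs_d(d, D, "power_law_d", np.full_like(d, 60.0))
    assert fit.params["n"] == pytest.approx(0.5, rel=1e-6)
    assert fit.params["c"] == pytest.approx(1.2, rel=1e-6)


def test_ratio_power_law_exact_and_isotropic():
    d = np.linspace(2.5, 25, 12)
    fit = fit_ratio_power_law(d, 50.0 * d ** (-2.3) + 1.0)
    assert fit.params["A"] == pytest.approx(50.0, rel=1e-7)
    assert fit.params["l"] == pytest.approx(2.3, rel=1e-7)
    iso = fit_ratio_power_law(d, np.ones_like(d))
    # anisotropy amplitude collapses: the fitted curve is flat at 1
    model = iso.params["A"] * d ** (-iso.params["l"]) + 1.0
    assert np.max(np.abs(model - 1.0)) < 1e-6


def test_height_scaling_fit_exact_and_linear():
    d = np.array([2.0, 3.0, 5.0, 10.0, 20.0])
    fit = fit_height_scaling(d, 120.0 * d ** (-2 / 3))
    assert fit.params["A"] == pytest.approx(120.0, rel=1e-9)
    fit2 = fit_height_scaling(d, 240.0 * d ** (-2 / 3))
    assert fit2.params["A"] == pytest.approx(240.0, rel=1e-9)


def test_conductivity_zero_and_linearity():
    assert conductivity(IonMixture([(1, 0.0, 1e-9)], 310.0)) == 0.0
    base = conductivity(IonMixture([(1, 150.0, 1e-9)], 310.0))
    assert conductivity(IonMixture([(1, 150.0, 2e-9)], 310.0)) == pytest.approx(
        2 * base
    )


def test_conductivity_hand_value():
    # single monovalent species: sigma = F^2 D c / (R T)
    sigma = conductivity(IonMixture([(1, 150.0, 1e-9)], 310.0))
    assert sigma == pytest.approx(
        FARADAY**2 * 1e-9 * 150.0 / (GAS_CONSTANT * 310.0), rel=1e-12
    )


def test_csf_mixture_grouping():
    mix = csf_like_mixture({+1: 2e-9, -1: 1e-9, +2: 5e-10})
    assert {z for z, _, _ in mix.species} == set(CSF_CONCENTRATIONS)
    with pytest.raises(ValueError):
        csf_like_mixture({+1: 1e-9})  # no anion diffusion constant


def test_shell_resistance_closed_form_vs_quadrature():
    rho, r, h = 0.05, 5e-6, 5e-7
    closed = shell_resistance(rho, r, h)
    assert closed == pytest.approx(rho * h / (4 * np.pi * r * (r + h)), rel=1e-12)
    assert abs(closed - shell_resistance_quadrature(rho, r, h)) < 1e-10 * closed
    assert shell_resistance(rho, r, 0.0) == 0.0


def test_traversal_time_scalings():
    t0 = traversal_time(1.0, 10.0)
    assert traversal_time(1.0, 20.0) == pytest.approx(4 * t0)
    assert traversal_time(2.0, 10.0) == pytest.approx(t0 / 2)
    with pytest.raises(ValueError):
        traversal_time(0.0, 10.0)


def test_mixture_validation():
    with pytest.raises(ValueError):
        IonMixture([])
    with pytest.raises(ValueError):
        IonMixture([(1, -1.0, 1e-9)])
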