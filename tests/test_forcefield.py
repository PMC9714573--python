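import math

import numpy as np
import pytest

from pnnbrush.dynamics import LangevinIntegrator, LangevinSettings
from pnnbrush.forcefield import (
    SingularityError,
    bend_energy,
    bond_energy,
    debye_pair_energy,
    lj_pair_energy,
    total_energy_forces,
)
from pnnbrush.params import BrushConfig, ForceFieldParams, LJ_MIN_FACTOR
from pnnbrush.system import build_brush_system
from pnnbrush.units import DEFAULT_KT

RCUT = LJ_MIN_FACTOR


@pytest.mark.parametrize(
    "r,shift,expected",
    [
        (LJ_MIN_FACTOR * (1 - 1e-9), False, -0.73),  # unshifted minimum is -eps
        (LJ_MIN_FACTOR * (1 - 1e-9), True, 0.0),     # WCA shift zeroes the minimum
        (1.0, False, 0.0),                   # LJ zero crossing at sigma
        (1.0, True, 0.73),                   # shifted by +eps
        (1.2, True, 0.0),                    # beyond the 1.122-sigma cutoff
        (2.0, False, 0.0),
    ],
)
def test_lj_pair_energy_reference_points(r, shift, expected):
    assert lj_pair_energy(r, 0.73, 1.0, RCUT, shift=shift) == pytest.approx(
        expected, abs=1e-9
    )


def test_bond_energy_values():
    assert bond_energy(1.0, 140.2, 1.0) == 0.0
    assert bond_energy(1.1, 140.2, 1.0) == pytest.approx(1.402, rel=1e-10)
    assert bond_energy(1.0 + 0.07, 140.2, 1.0) == pytest.approx(
        bond_energy(1.0 - 0.07, 140.2, 1.0)
    )


def test_bend_energy_values():
    assert bend_energy(math.pi, 14.02) == 0.0
    assert bend_energy(math.pi / 2, 14.02) == pytest.approx(
        14.02 * (math.pi / 2) ** 2, rel=1e-12
    )
    assert bend_energy(1.0, 0.0) == 0.0  # no-stiffness limit


def test_debye_energy_neutral_and_cutoff():
    assert debye_pair_energy(1.0, 0.0, -1.0, 1.9628, 1.0, 3.0) == 0.0
    assert debye_pair_energy(3.5, -1.0, -1.0, 1.9628, 1.0, 3.0) == 0.0


def test_debye_bjerrum_parameterization():
    # with the prefactor set to kT * l_B, beta*u(r) = l_B exp(-kappa r)/r:
    # at r = sigma two unit charges feel 0.7/e ~ 0.2575 kT
    u = debye_pair_energy(1.0, -1.0, -1.0, DEFAULT_KT * 0.7, 1.0, 3.0)
    assert u / DEFAULT_KT == pytest.approx(0.7 * math.exp(-1.0), rel=1e-10)


def test_debye_default_is_physical_water_coupling():
    # default prefactor: Coulomb energy of two unit charges at 1 nm in
    # water, in eps_E units -- kT-independent, ~8.5 eps_E sigma
    ff = ForceFieldParams()
    assert ff.coulomb_const == pytest.approx(8.45, rel=0.02)


@pytest.mark.parametrize("qi,qj,sign", [(1, 1, 1), (-1, -1, 1), (1, -1, -1)])
def test_debye_sign_follows_charge_product(qi, qj, sign):
    u = debye_pair_energy(1.5, qi, qj, 1.9628, 1.0, 3.0)
    assert np.sign(u) == sign


def test_pair_singularities():
    with pytest.raises(SingularityError):
        lj_pair_energy(0.0, 0.73, 1.0, RCUT)
    with pytest.raises(SingularityError):
        debye_pair_energy(0.0, 1.0, 1.0, 1.0, 1.0, 3.0)


@pytest.fixture()
def small_state(small_config, ff):
    return build_brush_system(small_config, ff, 1)


def test_energy_breakdown_sums_to_total(small_state, ff):
    eb, _ = total_energy_forces(small_state, ff)
    assert eb.per_bead.sum() == pytest.approx(eb.u_total, rel=1e-10)
    assert eb.u_total == pytest.approx(
        eb.u_lj + eb.u_bond + eb.u_bend + eb.u_debye, rel=1e-12
    )


def test_forces_match_finite_differences(small_state, ff):
    """Analytic forces equal the central-difference energy gradient."""
    state = small_state
    _, forces = total_energy_forces(state, ff)
    rng = np.random.default_rng(0)
    mobile = np.flatnonzero(state.mobile)
    eps = 1e-6
    for i in rng.choice(mobile, size=4, replace=False):
        for k in range(3):
            p0 = state.positions[i, k]
            state.positions[i, k] = p0 + eps
            ep, _ = total_energy_forces(state, ff)
            state.positions[i, k] = p0 - eps
            em, _ = total_energy_forces(state, ff)
            state.positions[i, k] = p0
            fd = -(ep.u_total - em.u_total) / (2 * eps)
            assert forces[i, k] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_newtons_third_law_isolated_pair(ff):
    from pnnbrush.system import build_free_chain

    state = build_free_chain(2, BrushConfig(), ff, 0)
    state.positions[1] = state.positions[0] + [0.0, 0.0, 1.07]
    _, forces = total_energy_forces(state, ff)
    assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-12)


def test_lj_minimum_force_free(ff):
    from pnnbrush.system import build_free_chain

    # two isolated neutral beads without a bond, at the LJ minimum
    state = build_free_chain(2, BrushConfig(), ff, 0)
    state.bonds = np.zeros((0, 2), dtype=np.int64)
    state.angles = np.zeros((0, 3), dtype=np.int64)
    state.chain_id[:] = -1
    state.charges[:] = 0.0
    state.positions[1] = state.positions[0] + [0.0, 0.0, LJ_MIN_FACTOR]
    _, forces = total_energy_forces(state, ff)
    assert np.allclose(forces, 0.0, atol=1e-9)


def test_translational_invariance(small_state, ff):
    state = small_state.copy()
    # jitter away from lattice distances that sit exactly on a cutoff,
    # where the strict r < r_cut convention is float-sensitive
    state.positions += 0.01 * np.random.default_rng(0).standard_normal(
        state.positions.shape
    )
    eb0, _ = total_energy_forces(state, ff)
    shifted = state.copy()
    Lx, _ = shifted.box
    shifted.positions = shifted.positions + np.array([Lx + 0.37, -2 * Lx + 0.11, 4.2])
    eb1, _ = total_energy_forces(shifted, ff)
    assert eb1.u_total == pytest.approx(eb0.u_total, rel=1e-10)


def test_cutoff_locality(small_state, ff):
    """Moving a bead far outside every cutoff leaves other forces unchanged."""
    state = small_state.copy()
    _, f0 = total_energy_forces(state, ff)
    ti = state.tracer_index
    state.positions[ti, 2] += 50.0  # z is open: unambiguously out of range
    _, f1 = total_energy_forces(state, ff)
    others = np.arange(state.n) != ti
    assert np.allclose(f0[others], f1[others], atol=1e-12)


def test_neighbor_list_kernel_matches_bruteforce(small_config, ff):
    """The jitted Verlet-list force path equals the O(N^2) reference."""
    for seed in (1, 2):
        state = build_brush_system(small_config, ff, seed)
        _, f_ref = total_energy_forces(state, ff)
        integ = LangevinIntegrator(
            state.copy(), ff, LangevinSettings(kT=DEFAULT_KT),
            np.random.default_rng(0), thermal_velocities=False,
        )
        mob = state.mobile
        assert np.allclose(integ.forces[mob], f_ref[mob], atol=1e-10)
        e = integ.current_energies()
        eb, _ = total_energy_forces(state, ff)
        assert np.allclose(
            e[:4], [eb.u_lj, eb.u_bond, eb.u_bend, eb.u_debye], atol=1e-9
        )
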