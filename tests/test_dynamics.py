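import numpy as np
import pytest

from pnnbrush.dynamics import (
    BlowUpError,
    LangevinIntegrator,
    LangevinSettings,
    Trajectory,
    equilibrate_brush,
    realization_seed,
    run_bulk,
    run_free_chain_configs,
    run_realization,
    run_static_tracer,
)
from pnnbrush.observables import compute_msd, fit_diffusion
from pnnbrush.params import BrushConfig, ForceFieldParams
from pnnbrush.system import CHAIN, SystemState
from pnnbrush.units import DEFAULT_KT

KT = DEFAULT_KT


def _bare_state(n, bonds=(), angles=(), spacing=1.0, gamma=1.0):
    pos = np.zeros((n, 3))
    pos[:, 2] = spacing * np.arange(n)
    return SystemState(
        positions=pos,
        velocities=np.zeros((n, 3)),
        species=np.full(n, CHAIN, np.int64),
        mobile=np.ones(n, bool),
        masses=np.ones(n),
        gammas=np.full(n, float(gamma)),
        charges=np.zeros(n),
        sigmas=np.ones(n),
        bonds=np.array(bonds, np.int64).reshape(-1, 2),
        angles=np.array(angles, np.int64).reshape(-1, 3),
        box=(1e6, 1e6),
        chain_id=np.zeros(n, np.int64),
        chain_pos=np.arange(n, dtype=np.int64),
    )


def test_nve_energy_conservation(ff):
    """gamma = 0 reduces BAOAB to velocity Verlet: tight energy drift."""
    state = _bare_state(2, bonds=[(0, 1)], spacing=1.05, gamma=0.0)
    state.velocities[0] = [0.1, 0.0, -0.05]
    integ = LangevinIntegrator(
        state, ff, LangevinSettings(gamma=0.0, kT=KT, dt=0.005),
        np.random.default_rng(0), thermal_velocities=False,
    )

    def total_energy():
        kin = 0.5 * (state.masses[:, None] * state.velocities**2).sum()
        return kin + integ.current_energies()[:4].sum()

    def window_mean():
        # average over bond periods to remove the bounded O(dt^2)
        # oscillation of the Verlet shadow energy; what must vanish is
        # the secular drift
        vals = []
        for _ in range(60):
            vals.append(total_energy())
            integ.run(5)
        return np.mean(vals)

    e0 = window_mean()
    integ.run(10_000)
    e1 = window_mean()
    assert abs(e1 - e0) / abs(e0) < 1e-4


def test_equipartition_free_ensemble(ff):
    """<v^2> = 3 kT/m for thermostatted non-interacting beads, within 1%."""
    n = 400
    state = _bare_state(n, spacing=10.0)  # all beads beyond every cutoff
    state.chain_id[:] = np.arange(n)  # independent, no exclusions needed
    integ = LangevinIntegrator(
        state, ff, LangevinSettings(gamma=1.0, kT=KT, dt=0.005),
        np.random.default_rng(3),
    )
    integ.run(500)
    samples = []
    for _ in range(25):
        integ.run(150)
        samples.append((state.velocities**2).sum(axis=1).mean())
    assert np.mean(samples) == pytest.approx(3 * KT, rel=0.01)


def test_harmonic_tether_fluctuation(ff):
    """A bead bonded (r0 = 0) to a fixed anchor: <x^2> = kT / (2 K_bond)."""
    from dataclasses import replace

    params = replace(ff, r0=0.0, k_bend=0.0)
    state = _bare_state(2, bonds=[(0, 1)], spacing=0.0)
    state.positions[1] = [0.01, 0.0, 0.0]
    state.mobile[0] = False
    integ = LangevinIntegrator(
        state, params, LangevinSettings(gamma=1.0, kT=KT, dt=0.002),
        np.random.default_rng(4),
    )
    integ.run(2_000)
    acc = []
    for _ in range(3_000):
        integ.run(10)
        acc.append(state.positions[1].copy())
    var = np.asarray(acc).var(axis=0).mean()
    assert var == pytest.approx(KT / (2 * ff.k_bond), rel=0.1)


def test_bulk_free_particle_diffusion(ff):
    """Long-time MSD slope of the free Langevin particle gives D = kT/gamma."""
    settings = LangevinSettings(gamma=1.0, kT=KT, dt=0.005)
    trajs = run_bulk(0.5, settings, n_realizations=300, n_steps=20_000,
                     dump_every=50, seed=8)
    est = fit_diffusion(compute_msd(trajs), trajs)
    d_theory = KT / 1.0
    for d, s in [(est.D_par, est.D_par_std), (est.D_perp, est.D_perp_std),
                 (est.D_total, est.D_total_std)]:
        assert abs(d - d_theory) < 3 * max(s, 0.05 * d_theory)
    # directional estimates mutually consistent (bulk isotropy)
    assert abs(est.D_par - est.D_perp) < 3 * (est.D_par_std + est.D_perp_std)


def test_bulk_zero_temperature_never_moves(ff):
    trajs = run_bulk(0.5, LangevinSettings(gamma=1.0, kT=0.0, dt=0.005),
                     n_realizations=2, n_steps=500, dump_every=50, seed=0)
    for tr in trajs:
        assert np.all(tr.tracer_positions == 0.0)


def test_same_seed_reproduces_trajectory(ff, small_config):
    t1 = run_realization(small_config, ff, 13)
    t2 = run_realization(small_config, ff, 13)
    assert np.array_equal(t1.tracer_positions, t2.tracer_positions)
    assert np.array_equal(t1.energies, t2.energies)


def test_static_mode_freezes_chains(ff, small_config):
    cfg = small_config.with_updates(mode="static", record_chain_frames=False)
    tr = run_realization(cfg, ff, 5)
    # frozen chains: the brush ceiling never changes during production
    assert np.all(tr.max_chain_z == tr.max_chain_z[0])


def test_no_stiffness_mode_has_zero_bend_energy(ff, small_config):
    cfg = small_config.with_updates(mode="no_stiffness")
    tr = run_realization(cfg, ff, 5)
    assert np.all(tr.energies[:, 2] == 0.0)
    dyn = run_realization(small_config, ff, 5)
    assert dyn.energies[1:, 2].max() > 0.0


def test_realization_seeds_are_distinct():
    seeds = [realization_seed(42, k) for k in range(100)]
    assert len(set(seeds)) == 100
    assert all(0 <= s < 2**31 for s in seeds)


def test_blowup_reported(ff):
    # undamped bond integrated far beyond the stability limit (omega dt > 2)
    state = _bare_state(2, bonds=[(0, 1)], spacing=1.3, gamma=0.0)
    integ = LangevinIntegrator(
        state, ff, LangevinSettings(gamma=0.0, kT=KT, dt=0.2),
        np.random.default_rng(0), thermal_velocities=False,
    )
    with pytest.raises(BlowUpError):
        integ.run(10_000)


def test_shared_static_brush_productions(ff):
    cfg = BrushConfig(
        d=3.0, grid_n=2, n_beads=11, init_mode="wlc",
        n_equil_steps=400, n_prod_steps=400, dump_every=20,
        energy_record="tracer",
    )
    frozen = equilibrate_brush(cfg, ff, 1)
    assert frozen.tracer_index is None
    assert not frozen.mobile.any()
    t1 = run_static_tracer(frozen, cfg, ff, 10)
    t2 = run_static_tracer(frozen, cfg, ff, 11)
    t1b = run_static_tracer(frozen, cfg, ff, 10)
    assert np.array_equal(t1.tracer_positions, t1b.tracer_positions)
    assert not np.array_equal(t1.tracer_positions, t2.tracer_positions)
    # the host brush is untouched by the production runs
    assert np.all(frozen.velocities == 0.0)
    assert np.all(t1.max_chain_z == t1.max_chain_z[0])


def test_trajectory_times_strictly_increasing(ff, small_config):
    tr = run_realization(small_config, ff, 3)
    assert np.all(np.diff(tr.times) > 0)
    with pytest.raises(ValueError):
        Trajectory(
            times=np.array([0.0, 1.0, 1.0]),
            tracer_positions=np.zeros((3, 3)),
            in_brush=np.ones(3, bool),
            max_chain_z=np.ones(3),
            energies=None,
            seed=0,
        )


def test_free_chain_configs_deterministic(ff):
    cfg = BrushConfig(n_beads=21)
    a = run_free_chain_configs(cfg, ff, 3, 50, 100, seed=2)
    b = run_free_chain_configs(cfg, ff, 3, 50, 100, seed=2)
    assert all(np.array_equal(x, y) for x, y in zip(a, b))
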