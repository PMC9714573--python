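"""Measured quantities: dual MSD curves, anisotropic diffusion constants,
brush structure (Rg, height, correlation length, persistence length) and
potential-energy statistics.

The dual-MSD procedure computes two ensemble curves from a common
production origin: one over all realizations, and one restricted to
realizations whose tracer has remained inside the brush (z below the
instantaneous maximum chain-bead height) up to that time.  Diffusion
constants come from straight-line fits <dx^2+dy^2> = 4 D_par t and
<dz^2> = 2 D_perp t on a window chosen after the ballistic transient
where the two curves have similar log-log slopes; the ensemble is split
into ten groups to obtain a mean and standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial import cKDTree

from .dynamics import Trajectory

N_GROUPS = 10
#: frames to skip before the fit window may start (inertial transient)
MIN_WINDOW_START_FRAMES = 20
#: maximum relative log-log slope mismatch between the two MSD curves
SLOPE_MISMATCH_TOL = 0.10
#: acceptable band for the local log-log slope of a diffusive curve
DIFFUSIVE_SLOPE_BAND = (0.7, 1.3)


class WindowSelectionError(RuntimeError):
    """No time window satisfies the slope-similarity rule."""


class FitRangeError(RuntimeError):
    """Bond-vector correlations decay too fast to fit."""


@dataclass
class MSDResult:
    times: np.ndarray
    msd_xy_all: np.ndarray
    msd_z_all: np.ndarray
    msd_xy_inbrush: np.ndarray
    msd_z_inbrush: np.ndarray
    n_inbrush: np.ndarray
    n_total: int

    @property
    def msd_total_all(self) -> np.ndarray:
        return self.msd_xy_all + self.msd_z_all


@dataclass
class DiffusionEstimate:
    D_par: float
    D_par_std: float
    D_perp: float
    D_perp_std: float
    D_total: float
    D_total_std: float
    fit_window: tuple[float, float]
    n_groups: int


@dataclass
class BrushObservables:
    Rg_mean: float
    Rg_std: float
    L_z: float
    xi: float
    d: float

    @property
    def regime(self) -> str:
        return "brush" if self.d < 2.0 * self.Rg_mean else "mushroom"


@dataclass
class EnergyStats:
    """Tracer/chain potential-energy statistics over a production run.

    ``mean_energy_per_step`` is the tracer interaction energy averaged
    over every frame; ``mean_energy_when_interacting`` averages only over
    frames with a nonzero interaction, of which there is a fraction
    ``interacting_fraction`` — so the first equals the product of the
    other two by construction.
    """

    mean_energy_per_step: float
    mean_energy_when_interacting: float
    interacting_fraction: float
    chain_mean_energy_per_bead: float
    never_interacting: bool = False


def _survivor_mask(traj: Trajectory) -> np.ndarray:
    """In-brush up to each frame: exiting is absorbing for the bookkeeping."""
    return np.logical_and.accumulate(traj.in_brush)


def compute_msd(trajectories: Sequence[Trajectory]) -> MSDResult:
    """Ensemble MSD curves (all realizations and in-brush survivors).

    All trajectories must share the same time grid, measured from the
    production origin.  Times where no realization remains in the brush
    yield NaN in the in-brush curves (with a warning).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    times = trajectories[0].times
    disp2 = np.empty((len(trajectories), len(times), 2))
    surv = np.empty((len(trajectories), len(times)), dtype=bool)
    for k, tr in enumerate(trajectories):
        if len(tr.times) != len(times) or not np.allclose(tr.times, times):
            raise ValueError("trajectories must share a common time grid")
        d = tr.tracer_positions - tr.tracer_positions[0]
        disp2[k, :, 0] = d[:, 0] ** 2 + d[:, 1] ** 2
        disp2[k, :, 1] = d[:, 2] ** 2
        surv[k] = _survivor_mask(tr)
    n_in = surv.sum(0)
    with np.errstate(invalid="ignore"):
        msd_in = np.where(
            (n_in > 0)[:, None],
            (disp2 * surv[:, :, None]).sum(0) / np.maximum(n_in, 1)[:, None],
            np.nan,
        )
    if np.any(n_in == 0):
        warnings.warn("in-brush ensemble empty at late times; curves truncated")
    return MSDResult(
        times=times,
        msd_xy_all=disp2[:, :, 0].mean(0),
        msd_z_all=disp2[:, :, 1].mean(0),
        msd_xy_inbrush=msd_in[:, 0],
        msd_z_inbrush=msd_in[:, 1],
        n_inbrush=n_in,
        n_total=len(trajectories),
    )


def _local_loglog_slope(
    t: np.ndarray, y: np.ndarray, half_width: float = 0.5
) -> np.ndarray:
    """Local log-log slope by windowed regression (half-width in ln t).

    A regression over a ~factor-1.6 neighborhood keeps the estimate
    usable on noisy small-ensemble MSD curves, where a pointwise
    gradient swings wildly.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        lt, ly = np.log(t), np.log(y)
    out = np.full(len(t), np.nan)
    ok = np.isfinite(lt) & np.isfinite(ly)
    for i in range(len(t)):
        if not ok[i]:
            continue
        sel = ok & (np.abs(lt - lt[i]) <= half_width)
        if sel.sum() < 3:
            continue
        x, z = lt[sel], ly[sel]
        xm, zm = x.mean(), z.mean()
        denom = ((x - xm) ** 2).sum()
        if denom > 0:
            out[i] = ((x - xm) * (z - zm)).sum() / denom
    return out


def select_fit_window(msd: MSDResult) -> tuple[int, int]:
    """Earliest decade-wide window satisfying the slope rules.

    Conditions at every frame of the window, for both the lateral and the
    vertical curve pair: the all-realizations and in-brush log-log slopes
    agree within 10%, each is within [0.8, 1.2] (diffusive, i.e. past the
    ballistic transient), the in-brush ensemble is not depleted, and the
    window starts after frame 20.
    """
    t = msd.times
    n = len(t)
    valid = np.ones(n, dtype=bool)
    valid[: MIN_WINDOW_START_FRAMES + 1] = False
    valid &= msd.n_inbrush >= max(2, int(0.1 * msd.n_total))
    lo, hi = DIFFUSIVE_SLOPE_BAND
    for all_c, in_c in (
        (msd.msd_xy_all, msd.msd_xy_inbrush),
        (msd.msd_z_all, msd.msd_z_inbrush),
    ):
        with np.errstate(all="ignore"):
            s_all = _local_loglog_slope(t[1:], all_c[1:])
            s_in = _local_loglog_slope(t[1:], in_c[1:])
            ok = (
                np.isfinite(s_all)
                & np.isfinite(s_in)
                & (np.abs(s_all - s_in) <= SLOPE_MISMATCH_TOL * np.abs(s_all))
                & (s_all >= lo)
                & (s_all <= hi)
            )
        valid[1:] &= ok
    for i0 in range(MIN_WINDOW_START_FRAMES + 1, n):
        if not valid[i0]:
            continue
        i1 = np.searchsorted(t, 10.0 * t[i0], side="right") - 1
        i1 = min(i1, n - 1)
        if i1 - i0 < 4:
            i1 = min(i0 + 4, n - 1)
        # accept if the window ends are valid and most of its interior is
        if valid[i1] and np.mean(valid[i0 : i1 + 1]) >= 0.8:
            return i0, i1
    # fall back: longest valid stretch of at least 5 frames
    best = None
    run = 0
    for i in range(n):
        run = run + 1 if valid[i] else 0
        if run >= 5 and (best is None or run > best[1] - best[0] + 1):
            best = (i - run + 1, i)
    if best:
        return best
    raise WindowSelectionError("no window satisfies the slope-similarity rule")


def _slope_fit(t: np.ndarray, y: np.ndarray) -> float:
    keep = np.isfinite(y)
    if keep.sum() < 2:
        return np.nan
    return float(np.polyfit(t[keep], y[keep], 1)[0])


def fit_diffusion(
    msd: MSDResult,
    trajectories: Optional[Sequence[Trajectory]] = None,
    n_groups: int = N_GROUPS,
    window: Optional[tuple[int, int]] = None,
) -> DiffusionEstimate:
    """Group-wise linear fits of the MSD slopes on the selected window.

    With ``trajectories`` given, the ensemble is split into ``n_groups``
    groups of equal size and the in-brush MSD of each group is fitted
    separately, yielding a mean and standard deviation; without, the
    ensemble curves are fitted as a single group (std 0).
    """
    i0, i1 = window if window is not None else select_fit_window(msd)
    t = msd.times[i0 : i1 + 1]
    if trajectories is None or len(trajectories) < n_groups:
        groups = [None]
    else:
        size = len(trajectories) // n_groups
        groups = [trajectories[g * size : (g + 1) * size] for g in range(n_groups)]
    d_par, d_perp, d_tot = [], [], []
    for g in groups:
        if g is None:
            xy, z = msd.msd_xy_inbrush, msd.msd_z_inbrush
            if not np.any(np.isfinite(xy[i0 : i1 + 1])):
                xy, z = msd.msd_xy_all, msd.msd_z_all
        else:
            gm = compute_msd(g)
            xy, z = gm.msd_xy_inbrush, gm.msd_z_inbrush
            if not np.any(np.isfinite(xy[i0 : i1 + 1])):
                xy, z = gm.msd_xy_all, gm.msd_z_all
        d_par.append(_slope_fit(t, xy[i0 : i1 + 1]) / 4.0)
        d_perp.append(_slope_fit(t, z[i0 : i1 + 1]) / 2.0)
        d_tot.append(_slope_fit(t, (xy + z)[i0 : i1 + 1]) / 6.0)
    d_par, d_perp, d_tot = map(np.asarray, (d_par, d_perp, d_tot))
    std = (lambda a: float(np.nanstd(a)) if len(a) > 1 else 0.0)
    return DiffusionEstimate(
        D_par=float(np.nanmean(d_par)),
        D_par_std=std(d_par),
        D_perp=float(np.nanmean(d_perp)),
        D_perp_std=std(d_perp),
        D_total=float(np.nanmean(d_tot)),
        D_total_std=std(d_tot),
        fit_window=(float(msd.times[i0]), float(msd.times[i1])),
        n_groups=len(groups),
    )


def gyration_radii(chain_positions: np.ndarray) -> np.ndarray:
    """Per-chain root-mean-square distance from the chain center of mass.

    ``chain_positions`` has shape (n_chains, n_beads, 3).
    """
    com = chain_positions.mean(axis=1, keepdims=True)
    return np.sqrt(((chain_positions - com) ** 2).sum(-1).mean(-1))


def radius_of_gyration(trajectories: Sequence[Trajectory]) -> tuple[float, float]:
    """Mean and std of Rg over all chains and realizations (final frames)."""
    rgs = np.concatenate(
        [gyration_radii(tr.chain_positions_final) for tr in trajectories]
    )
    return float(rgs.mean()), float(rgs.std())


def brush_height(trajectories: Sequence[Trajectory]) -> float:
    """Mean over realizations of the maximal chain-bead z (final frame)."""
    return float(
        np.mean([tr.chain_positions_final[:, :, 2].max() for tr in trajectories])
    )


def correlation_length(
    chain_positions: np.ndarray, box: tuple[float, float]
) -> float:
    """Mean distance from each chain bead to the closest bead of another
    chain, under the x,y minimum image (KD-tree over periodic images)."""
    n_chains = chain_positions.shape[0]
    if n_chains < 2:
        raise ValueError("correlation length needs at least two chains")
    Lx, Ly = box
    shifts = [
        np.array([ix * Lx, iy * Ly, 0.0]) for ix in (-1, 0, 1) for iy in (-1, 0, 1)
    ]
    dists = []
    for c in range(n_chains):
        others = np.concatenate(
            [chain_positions[k] for k in range(n_chains) if k != c]
        )
        images = np.concatenate([others + s for s in shifts])
        tree = cKDTree(images)
        dd, _ = tree.query(chain_positions[c], k=1)
        dists.append(dd)
    return float(np.concatenate(dists).mean())


def correlation_length_bruteforce(
    chain_positions: np.ndarray, box: tuple[float, float]
) -> float:
    """O(N^2) reference for :func:`correlation_length`."""
    n_chains, n_beads, _ = chain_positions.shape
    if n_chains < 2:
        raise ValueError("correlation length needs at least two chains")
    flat = chain_positions.reshape(-1, 3)
    cid = np.repeat(np.arange(n_chains), n_beads)
    d = flat[None, :, :] - flat[:, None, :]
    for k, L in enumerate(box):
        d[..., k] -= L * np.rint(d[..., k] / L)
    r = np.sqrt((d**2).sum(-1))
    r[cid[:, None] == cid[None, :]] = np.inf
    return float(r.min(axis=1).mean())


def bond_correlation(chain_configs: Sequence[np.ndarray]) -> tuple[np.ndarray, float]:
    """<u_i . u_{i+s}> averaged over positions and configurations.

    Returns (C(s) for s = 1..n_bonds-1, mean bond length).
    """
    n_bonds = len(chain_configs[0]) - 1
    acc = np.zeros(n_bonds - 1)
    cnt = np.zeros(n_bonds - 1)
    blen = []
    for pos in chain_configs:
        b = np.diff(pos, axis=0)
        norm = np.linalg.norm(b, axis=1)
        blen.append(norm.mean())
        u = b / norm[:, None]
        for s in range(1, n_bonds):
            acc[s - 1] += (u[:-s] * u[s:]).sum()
            cnt[s - 1] += n_bonds - s
    return acc / cnt, float(np.mean(blen))


def persistence_length(
    chain_configs: Sequence[np.ndarray],
    s_max_factor: float = 3.0,
    n_groups: Optional[int] = None,
) -> tuple[float, float]:
    """Persistence length from the exponential bond-vector decorrelation.

    Fits log <cos theta(s)> against the contour separation s (bond-length
    units) over s in [1, s_max_factor * l_p_initial], where the initial
    estimate comes from the s = 1 correlation.  Returns (l_p, fit std);
    l_p is infinite for a rigid straight chain.

    With ``n_groups``, the configurations are split into that many
    consecutive blocks (e.g. one block per independent chain) and each s
    is weighted by the inverse scatter of C(s) across blocks — the honest
    weighting when configurations within a block are time-correlated,
    which tames the noisy large-s tail.  Without it, points get the
    nominal counting weight C sqrt(n_pairs), appropriate for
    independently drawn configurations.
    """
    corr, b = bond_correlation(chain_configs)
    if corr[0] >= 1.0 - 1e-12:
        return np.inf, 0.0
    if corr[0] <= 0.0 or (len(corr) > 1 and corr[1] <= 0.0):
        raise FitRangeError("bond correlations non-positive before s = 2")
    lp0 = -1.0 / np.log(corr[0])
    s_hi = int(min(max(3, round(s_max_factor * lp0)), len(corr)))
    s = np.arange(1, s_hi + 1)
    c = corr[:s_hi]
    if n_groups and n_groups >= 3 and len(chain_configs) >= n_groups:
        size = len(chain_configs) // n_groups
        gc = np.array(
            [
                bond_correlation(chain_configs[g * size : (g + 1) * size])[0][:s_hi]
                for g in range(n_groups)
            ]
        )
        se = gc.std(axis=0, ddof=1) / np.sqrt(n_groups)
        w = np.where(c > 0, c, 0.0) / np.maximum(se, 1e-9)
    else:
        n_bonds = len(chain_configs[0]) - 1
        w = np.where(c > 0, c, 0.0) * np.sqrt(len(chain_configs) * (n_bonds - s))
    keep = (c > 0) & (w > 0)
    if keep.sum() < 3:
        raise FitRangeError("fewer than three positive correlation points")
    coef, cov = np.polyfit(s[keep], np.log(c[keep]), 1, w=w[keep], cov=True)
    slope = coef[0]
    lp = -b / slope
    lp_std = b * np.sqrt(cov[0, 0]) / slope**2
    return float(lp), float(lp_std)


def energy_stats(traj: Trajectory, tol: float = 1e-12) -> EnergyStats:
    """Tracer/chain energy statistics for one trajectory (see class doc)."""
    if traj.energies is None:
        raise ValueError("trajectory carries no energy record")
    tracer_e = traj.energies[:, 4]
    chain_e = traj.energies[:, 5]
    interacting = np.abs(tracer_e) > tol
    frac = float(interacting.mean())
    mean_all = float(tracer_e.mean())
    if interacting.any():
        mean_int = float(tracer_e[interacting].mean())
        flag = False
    else:
        mean_int = 0.0
        flag = True
    n_chain_beads = max(traj.n_chains * traj.n_chain_beads_per_chain, 1)
    return EnergyStats(
        mean_energy_per_step=mean_all,
        mean_energy_when_interacting=mean_int,
        interacting_fraction=frac,
        chain_mean_energy_per_bead=float(chain_e.mean()) / n_chain_beads,
        never_interacting=flag,
    )


def brush_observables(
    trajectories: Sequence[Trajectory], d: float, box: tuple[float, float]
) -> BrushObservables:
    """Structure summary over an ensemble (final frames)."""
    rg_mean, rg_std = radius_of_gyration(trajectories)
    xi = float(
        np.mean([correlation_length(tr.chain_positions_final, box) for tr in trajectories])
    )
    return BrushObservables(
        Rg_mean=rg_mean,
        Rg_std=rg_std,
        L_z=brush_height(trajectories),
        xi=xi,
        d=d,
    )
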