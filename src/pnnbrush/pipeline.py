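"""Study orchestration: sweep (d, mode, charge, radius) cells, analyze,
and assemble summary tables.

Each cell of a :class:`StudyPlan` runs an ensemble of realizations,
estimates the anisotropic diffusion constants from the dual-MSD
procedure, measures brush structure, and writes its results (plus a
manifest with every seed) into its own directory; completed cells are
skipped on re-run, so an interrupted study resumes where it stopped.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import (
    LangevinSettings,
    Trajectory,
    realization_seed,
    run_bulk,
    run_ensemble,
    run_realization,
)
from .io import read_manifest, read_tsv, write_manifest, write_tsv
from .observables import (
    WindowSelectionError,
    brush_observables,
    compute_msd,
    energy_stats,
    fit_diffusion,
)
from .params import BrushConfig, ForceFieldParams

logger = logging.getLogger("pnnbrush")

DESK_D_GRID = (2.0, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 25.0, 50.0)
FULL_D_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 7.0, 8.0,
               10.0, 15.0, 25.0, 50.0, 100.0)


@dataclass
class StudyPlan:
    """The sweep grid: one cell per (d, mode, charge, radius)."""

    d_grid: Sequence[float] = DESK_D_GRID
    modes: Sequence[str] = ("dynamic",)
    charges: Sequence[float] = (0.0,)
    radii: Sequence[float] = (0.5,)
    n_realizations: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.d_grid) and len(self.modes) and len(self.charges) and len(self.radii)):
            raise ValueError("plan grids must be non-empty")
        if len(set(self.cells())) != len(self.cells()):
            raise ValueError("duplicate cells in plan")

    def cells(self) -> list[tuple[float, str, float, float]]:
        return [
            (d, m, q, a)
            for d in self.d_grid
            for m in self.modes
            for q in self.charges
            for a in self.radii
        ]


def cell_dirname(d: float, mode: str, charge: float, radius: float) -> str:
    return f"d{d:g}_{mode}_q{charge:g}_a{radius:g}"


def run_cell(
    config: BrushConfig,
    params: ForceFieldParams,
    outdir: Path,
) -> dict:
    """Run one cell's ensemble and write msd.tsv, cell.tsv and manifest.json."""
    outdir.mkdir(parents=True, exist_ok=True)
    trajs = run_ensemble(config, params)
    msd = compute_msd(trajs)
    row: dict = {
        "d": config.d, "mode": config.mode, "charge": config.tracer_charge,
        "radius": config.tracer_radius, "n_realizations": config.n_realizations,
    }
    try:
        est = fit_diffusion(msd, trajs)
        row.update(
            D_par=est.D_par, D_par_std=est.D_par_std,
            D_perp=est.D_perp, D_perp_std=est.D_perp_std,
            D_total=est.D_total, D_total_std=est.D_total_std,
            t_fit_lo=est.fit_window[0], t_fit_hi=est.fit_window[1],
        )
    except WindowSelectionError as err:
        logger.warning("cell %s: %s", outdir.name, err)
        row.update(D_par=np.nan, D_par_std=np.nan, D_perp=np.nan,
                   D_perp_std=np.nan, D_total=np.nan, D_total_std=np.nan,
                   t_fit_lo=np.nan, t_fit_hi=np.nan)
    obs = brush_observables(trajs, config.d, config.box)
    es = [energy_stats(tr) for tr in trajs if tr.energies is not None]
    row.update(
        Rg_mean=obs.Rg_mean, Rg_std=obs.Rg_std, L_z=obs.L_z, xi=obs.xi,
        regime=obs.regime,
        tracer_E_per_step=float(np.mean([e.mean_energy_per_step for e in es])),
        tracer_E_interacting=float(np.mean([e.mean_energy_when_interacting for e in es])),
        tracer_N_E=float(np.mean([e.interacting_fraction for e in es])),
        chain_E_per_bead=float(np.mean([e.chain_mean_energy_per_bead for e in es])),
    )
    write_tsv(
        outdir / "msd.tsv",
        pd.DataFrame(
            {
                "t": msd.times, "msd_xy_all": msd.msd_xy_all,
                "msd_z_all": msd.msd_z_all, "msd_xy_in": msd.msd_xy_inbrush,
                "msd_z_in": msd.msd_z_inbrush, "n_in": msd.n_inbrush,
            }
        ),
        comment=f"dual MSD curves, {config.n_realizations} realizations",
    )
    write_tsv(outdir / "cell.tsv", pd.DataFrame([row]))
    write_manifest(
        outdir / "manifest.json",
        {
            "complete": True,
            "version": __version__,
            "config": {k: (v if not isinstance(v, tuple) else list(v))
                       for k, v in dataclasses.asdict(config).items()},
            "seeds": [realization_seed(config.seed, k)
                      for k in range(config.n_realizations)],
        },
    )
    return row


def run_study(
    plan: StudyPlan,
    config: BrushConfig,
    params: ForceFieldParams,
    outdir,
) -> pd.DataFrame:
    """Run every incomplete cell of the plan; returns the estimates table."""
    outdir = Path(outdir)
    rows = []
    for idx, (d, mode, q, a) in enumerate(plan.cells()):
        cdir = outdir / cell_dirname(d, mode, q, a)
        man = cdir / "manifest.json"
        if man.exists() and read_manifest(man).get("complete"):
            logger.info("cell %s already complete, skipping", cdir.name)
            rows.append(read_tsv(cdir / "cell.tsv").iloc[0].to_dict())
            continue
        cell_cfg = config.with_updates(
            d=d, mode=mode, tracer_charge=q, tracer_radius=a,
            n_realizations=plan.n_realizations,
            seed=realization_seed(plan.base_seed, idx),
        )
        logger.info("running cell %s", cdir.name)
        rows.append(run_cell(cell_cfg, params, cdir))
    df = pd.DataFrame(rows)
    write_tsv(outdir / "estimates.tsv", df)
    return df


def run_bulk_reference(
    radii: Sequence[float],
    settings: LangevinSettings,
    n_realizations: int,
    n_steps: int,
    dump_every: int,
    seed: int,
    outdir=None,
) -> pd.DataFrame:
    """Free-particle D_bulk estimates per tracer radius."""
    rows = []
    for i, a in enumerate(radii):
        trajs = run_bulk(
            a, settings, n_realizations, n_steps, dump_every,
            seed=realization_seed(seed, i),
        )
        msd = compute_msd(trajs)
        try:
            est = fit_diffusion(msd, trajs)
        except WindowSelectionError:
            # small/noisy ensembles: fall back to the post-transient half
            nf = len(msd.times)
            t_ballistic = 5.0 * (a / 0.5) ** 3 / max(settings.gamma * a / 0.5, 1e-9)
            i0 = max(21, int(np.searchsorted(msd.times, t_ballistic)))
            est = fit_diffusion(msd, trajs, window=(min(i0, nf - 6), nf - 1))
        rows.append(
            {
                "radius": a,
                "D_par": est.D_par, "D_par_std": est.D_par_std,
                "D_perp": est.D_perp, "D_perp_std": est.D_perp_std,
                "D_total": est.D_total, "D_total_std": est.D_total_std,
                "D_theory": settings.kT / (settings.gamma * a / 0.5),
            }
        )
    df = pd.DataFrame(rows)
    if outdir is not None:
        write_tsv(Path(outdir) / "bulk.tsv", df, comment="free-particle reference")
    return df


def report(estimates: pd.DataFrame, bulk: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summary tables: normalized diffusion, anisotropy flags, Rg phase table.

    Pure function of its inputs: identical tables for identical inputs.
    """
    est = estimates.copy().sort_values(["mode", "charge", "radius", "d"]).reset_index(drop=True)
    dbulk = bulk.set_index("radius")["D_total"]
    est["D_bulk"] = est["radius"].map(dbulk)
    est["D_par_rel"] = est["D_par"] / est["D_bulk"]
    est["D_perp_rel"] = est["D_perp"] / est["D_bulk"]
    est["ratio_perp_par"] = est["D_perp"] / est["D_par"]
    d_max = est["d"].max()
    est["bulk_converged"] = (est["d"] == d_max) & (
        np.abs(est["D_par_rel"] - 1.0) < 3 * est["D_par_std"] / est["D_bulk"] + 0.2
    )
    est["anisotropic"] = (est["d"] >= 2) & (est["d"] <= 10) & (est["D_par"] < est["D_perp"])
    phase = est[["d", "mode", "Rg_mean", "Rg_std", "L_z", "xi", "regime"]].drop_duplicates(
        subset=["d", "mode"]
    )
    return {"diffusion": est, "phase": phase}
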