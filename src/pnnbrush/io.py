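"""Plain-text I/O: extended-XYZ snapshots and TSV tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .system import SPECIES_NAMES, SystemState


def write_extxyz(
    path, state: SystemState, time: float = 0.0, append: bool = False
) -> None:
    """Write one frame in extended-XYZ form.

    The comment line carries an orthorhombic lattice (x,y periodic, a tall
    open z) and the frame time; species use single-letter labels.
    """
    Lx, Ly = state.box
    Lz = max(float(state.positions[:, 2].max()) * 2.0, 1.0)
    lines = [f"{state.n}\n"]
    lines.append(
        f'Lattice="{Lx} 0 0 0 {Ly} 0 0 0 {Lz}" '
        f'Properties=species:S:1:pos:R:3 Time={time}\n'
    )
    for sp, p in zip(state.species, state.positions):
        lines.append(
            f"{SPECIES_NAMES[int(sp)]} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n"
        )
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.writelines(lines)


def read_extxyz_frames(path) -> list[dict]:
    """Read all frames back as dicts with 'species', 'positions', 'box', 'time'."""
    frames = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head.strip():
                break
            n = int(head)
            comment = fh.readline()
            lat = comment.split('Lattice="')[1].split('"')[0].split()
            box = (float(lat[0]), float(lat[4]))
            time = 0.0
            for tok in comment.split():
                if tok.startswith("Time="):
                    time = float(tok[5:])
            species, pos = [], []
            for _ in range(n):
                parts = fh.readline().split()
                species.append(parts[0])
                pos.append([float(x) for x in parts[1:4]])
            frames.append(
                {
                    "species": species,
                    "positions": np.array(pos),
                    "box": box,
                    "time": time,
                }
            )
    return frames


def write_tsv(path, df: pd.DataFrame, comment: Optional[str] = None) -> None:
    """TSV with an optional '#'-prefixed header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_manifest(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
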