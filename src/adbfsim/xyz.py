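"""Extended-XYZ trajectory reader/writer.

Frames carry per-atom columns species, position, velocity, molecule id
and region label, with the cell and step in a ``Lattice=... Properties=...``
comment line (the widely used extended-XYZ dialect).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .core import SystemState
from .regions import LABEL_NAMES, RegionLabels

__all__ = ["write_extxyz", "read_extxyz"]

_PROPS = "species:S:1:pos:R:3:velo:R:3:molecule_id:I:1:region_label:S:1"
_NAME_TO_CODE = {v: k for k, v in LABEL_NAMES.items()}


def _frame_lines(state: SystemState, labels: RegionLabels | None, step: int | None):
    lat = np.zeros((3, 3))
    np.fill_diagonal(lat, state.cell)
    lat_str = " ".join(f"{x:.10g}" for x in lat.reshape(-1))
    pbc_str = " ".join("T" if p else "F" for p in state.pbc)
    comment = f'Lattice="{lat_str}" Properties={_PROPS} pbc="{pbc_str}"'
    if step is not None:
        comment += f" step={step}"
    yield f"{state.n_atoms}"
    yield comment
    names = ([LABEL_NAMES[int(c)] for c in labels.label] if labels is not None
             else ["-"] * state.n_atoms)
    for i in range(state.n_atoms):
        x, y, z = state.positions[i]
        vx, vy, vz = state.velocities[i]
        yield (f"{state.species[i]:2s} {x: .10f} {y: .10f} {z: .10f}"
               f" {vx: .10e} {vy: .10e} {vz: .10e}"
               f" {state.molecule_id[i]:d} {names[i]}")


def write_extxyz(path, frames, append: bool = False) -> None:
    """Write one or more frames.

    ``frames`` may be a single SystemState, a (step, state, labels) tuple,
    or an iterable of either.
    """
    if isinstance(frames, (SystemState, tuple)):
        frames = [frames]
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for fr in frames:
            if isinstance(fr, SystemState):
                step, state, labels = None, fr, None
            else:
                step, state, labels = fr
            for line in _frame_lines(state, labels, step):
                fh.write(line + "\n")


_MASS = {"O": 16.0, "H": 1.0}


def read_extxyz(path) -> list[tuple[int | None, SystemState, RegionLabels | None]]:
    """Read all frames; returns (step, state, labels-or-None) tuples."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comment = lines[i + 1]
        m = re.search(r'Lattice="([^"]+)"', comment)
        lat = np.array(m.group(1).split(), dtype=float).reshape(3, 3)
        cell = np.diag(lat)
        m = re.search(r'pbc="([^"]+)"', comment)
        pbc = np.array([t == "T" for t in m.group(1).split()]) if m else np.ones(3, bool)
        m = re.search(r"step=(\d+)", comment)
        step = int(m.group(1)) if m else None
        rows = [lines[i + 2 + k].split() for k in range(n)]
        species = np.array([r[0] for r in rows])
        pos = np.array([[float(v) for v in r[1:4]] for r in rows])
        vel = np.array([[float(v) for v in r[4:7]] for r in rows])
        mid = np.array([int(r[7]) for r in rows])
        label_names = [r[8] for r in rows]
        masses = np.array([_MASS.get(s, 1.0) for s in species])
        state = SystemState(pos, vel, masses, species, mid, cell, pbc)
        labels = None
        if all(nm in _NAME_TO_CODE for nm in label_names):
            labels = RegionLabels(np.array([_NAME_TO_CODE[nm] for nm in label_names],
                                           dtype=np.int8))
        frames.append((step, state, labels))
        i += 2 + n
    return frames
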