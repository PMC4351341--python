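"""Synthetic test systems: water-like boxes and solute embedding.

All fixtures used by the tests and validation studies are generated here,
deterministically from a seed -- no external data.  Boxes are built by
placing molecules on a jittered cubic lattice at the target number
density with random orientations, followed by a short damped relaxation
under the cheap model to remove residual close contacts, and
Maxwell-Boltzmann velocities at the target temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB, KE_TO_KCAL
from .core import SystemState, minimum_image_displacement
from .forcefields import DEFAULT_WATER_LIKE, WaterForceField, WaterModelParams

__all__ = ["BoxSpec", "build_box", "embed_solute", "water_molecule"]

#: Default number density, molecules per A^3 (ambient-water-like).
DEFAULT_DENSITY = 0.0334

O_MASS = 16.0
H_MASS = 1.0


@dataclass(frozen=True)
class BoxSpec:
    n_molecules: int = 93
    density: float = DEFAULT_DENSITY   # molecules / A^3
    temperature: float = 300.0
    seed: int = 0
    relax_steps: int = 200
    params: WaterModelParams = DEFAULT_WATER_LIKE


def water_molecule(params: WaterModelParams = DEFAULT_WATER_LIKE) -> np.ndarray:
    """Rest-geometry positions (3, 3) of one molecule: O at the origin."""
    b0, th = params.b0, params.theta0
    h1 = b0 * np.array([np.sin(th / 2), np.cos(th / 2), 0.0])
    h2 = b0 * np.array([-np.sin(th / 2), np.cos(th / 2), 0.0])
    return np.stack([np.zeros(3), h1, h2])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator,
                                 zero_momentum: bool = True) -> np.ndarray:
    sigma = np.sqrt(KB * temperature / (masses[:, None] * KE_TO_KCAL))
    v = sigma * rng.standard_normal((len(masses), 3))
    if zero_momentum and len(masses):
        v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


def build_box(spec: BoxSpec) -> SystemState:
    """Periodic water-like box at the target density."""
    M = spec.n_molecules
    if M < 1:
        raise ValueError("need at least one molecule")
    edge = (M / spec.density) ** (1.0 / 3.0)
    rng = np.random.default_rng(spec.seed)
    ncell = int(np.ceil(M ** (1.0 / 3.0)))
    spacing = edge / ncell
    sites = np.array([(i, j, k) for i in range(ncell) for j in range(ncell)
                      for k in range(ncell)], dtype=float)
    sites = (sites + 0.5) * spacing
    chosen = sites[rng.permutation(len(sites))[:M]]
    chosen += rng.uniform(-0.12, 0.12, chosen.shape) * spacing

    template = water_molecule(spec.params)
    pos = np.empty((3 * M, 3))
    for m in range(M):
        R = _random_rotation(rng)
        pos[3 * m: 3 * m + 3] = chosen[m] + template @ R.T
    species = np.tile(["O", "H", "H"], M)
    masses = np.tile([O_MASS, H_MASS, H_MASS], M)
    molecule_id = np.repeat(np.arange(M), 3)
    cell = np.full(3, edge)
    state = SystemState(pos, np.zeros_like(pos), masses, species, molecule_id,
                        cell, np.ones(3, bool))
    if M > 1 and spec.relax_steps:
        _relax(state, WaterForceField(spec.params), spec.relax_steps)
    state.velocities = maxwell_boltzmann_velocities(state.masses, spec.temperature, rng)
    return state


def _relax(state: SystemState, ff: WaterForceField, n_steps: int,
           max_move: float = 0.05) -> None:
    """Displacement-capped steepest descent to remove close contacts."""
    for _ in range(n_steps):
        f = ff.evaluate(state).forces
        step = 1e-3 * f
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step = np.where(norm > max_move, step / np.maximum(norm, 1e-12) * max_move, step)
        state.positions += step


def min_intermolecular_heavy_distance(state: SystemState) -> float:
    """Smallest O-O minimum-image distance (packing diagnostic)."""
    O = np.flatnonzero(state.species == "O")
    if len(O) < 2:
        return np.inf
    d = minimum_image_displacement(
        state.positions[O][:, None, :] - state.positions[O][None, :, :],
        state.cell, state.pbc)
    r = np.linalg.norm(d, axis=-1)
    iu = np.triu_indices(len(O), k=1)
    return float(r[iu].min())


def embed_solute(box: SystemState, solute_positions: np.ndarray,
                 solute_species, solute_masses, position,
                 exclusion_radius: float = 2.4) -> tuple[SystemState, np.ndarray]:
    """Insert a solute, removing overlapping solvent molecules.

    The solute template positions are relative to its own origin; it is
    placed at ``position`` (must lie inside the cell) with a fresh
    molecule id.  Any solvent molecule with an atom within
    ``exclusion_radius`` of a solute atom is removed whole.  Returns the
    new state and the solute atom indices (the natural default fixed-core
    list).
    """
    position = np.asarray(position, dtype=float)
    if np.any(position < 0) or np.any(position > box.cell):
        raise ValueError("solute position outside the cell")
    sol_pos = np.asarray(solute_positions, dtype=float) + position
    span = sol_pos.max(axis=0) - sol_pos.min(axis=0)
    if np.any(span > box.cell):
        raise ValueError("solute larger than the cell")
    keep = np.ones(box.n_atoms, dtype=bool)
    for atoms in box.molecule_indices():
        d = minimum_image_displacement(
            box.positions[atoms][:, None, :] - sol_pos[None, :, :], box.cell, box.pbc)
        if np.linalg.norm(d, axis=-1).min() < exclusion_radius:
            keep[atoms] = False
    new_mol = (box.molecule_id.max() + 1) if box.n_atoms else 0
    n_sol = len(sol_pos)
    positions = np.vstack([box.positions[keep], sol_pos])
    velocities = np.vstack([box.velocities[keep], np.zeros((n_sol, 3))])
    masses = np.concatenate([box.masses[keep], np.asarray(solute_masses, float)])
    species = np.concatenate([box.species[keep], np.asarray(solute_species)])
    molecule_id = np.concatenate([box.molecule_id[keep], np.full(n_sol, new_mol)])
    state = SystemState(positions, velocities, masses, species, molecule_id,
                        box.cell.copy(), box.pbc.copy())
    solute_idx = np.arange(state.n_atoms - n_sol, state.n_atoms)
    return state, solute_idx
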