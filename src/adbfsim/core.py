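"""Simulation state, periodic geometry and the force-provider contract.

``SystemState`` is the single in-memory container shared by every other
module: positions/velocities/masses/species/molecule ids in an orthorhombic
periodic cell.  Forces are exchanged through ``ForceResult`` objects
produced by *force providers* -- any object with an
``evaluate(state, qm_atoms) -> ForceResult`` method.  The ``qm_atoms`` set
selects which atoms are treated with the higher-level ("QM") model in a
composite evaluation; pure single-model providers ignore it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .constants import KE_TO_KCAL

__all__ = [
    "SystemState",
    "ForceRequest",
    "ForceResult",
    "ForceProvider",
    "minimum_image_displacement",
    "minimum_image_distance",
    "evaluate_forces",
    "kinetic_energy",
]


@dataclass
class SystemState:
    """Atomic configuration in an orthorhombic (optionally periodic) cell.

    Parameters
    ----------
    positions : (N, 3) float array, A
    velocities : (N, 3) float array, A/fs
    masses : (N,) float array, amu
    species : (N,) str array, element symbols
    molecule_id : (N,) int array; atoms of a molecule must be contiguous
    cell : (3,) float array, orthorhombic edge lengths in A
    pbc : (3,) bool array, per-axis periodicity
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    species: np.ndarray
    molecule_id: np.ndarray
    cell: np.ndarray
    pbc: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.species = np.asarray(self.species, dtype="U4")
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.cell = np.asarray(self.cell, dtype=float)
        self.pbc = np.asarray(self.pbc, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = len(self.positions)
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions/velocities must have shape (N, 3)")
        for name in ("masses", "species", "molecule_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match atom count")
        if not np.all(self.masses > 0):
            raise ValueError("all masses must be positive")
        if self.cell.shape != (3,) or self.pbc.shape != (3,):
            raise ValueError("cell and pbc must have shape (3,)")
        if np.any(self.pbc & ~(self.cell > 0)):
            raise ValueError("periodic axes require positive cell edges")
        # molecule ids must partition atoms into contiguous runs
        mid = self.molecule_id
        if n and np.any(np.diff(np.flatnonzero(np.r_[True, np.diff(mid) != 0])) < 0):
            raise ValueError("molecule_id must be contiguous")
        if n:
            _, first = np.unique(mid, return_index=True)
            runs = np.r_[True, np.diff(mid) != 0]
            if runs.sum() != len(first):
                raise ValueError("molecule_id groups must be contiguous")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.molecule_id))

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(),
            self.velocities.copy(),
            self.masses.copy(),
            self.species.copy(),
            self.molecule_id.copy(),
            self.cell.copy(),
            self.pbc.copy(),
        )

    def molecule_indices(self) -> list[np.ndarray]:
        """Atom index arrays, one per molecule, in molecule-id order."""
        ids = np.unique(self.molecule_id)
        return [np.flatnonzero(self.molecule_id == m) for m in ids]


@dataclass(frozen=True)
class ForceRequest:
    """Which atoms are 'QM' in a composite evaluation.

    ``label`` is free text used for bookkeeping only; the convention is
    "extended" for the buffered large-QM evaluation and "reduced" for the
    small-QM (possibly empty, i.e. pure-MM) one.
    """

    qm_atoms: frozenset = frozenset()
    label: str = ""


@dataclass
class ForceResult:
    forces: np.ndarray  # (N, 3), kcal mol^-1 A^-1
    potential_energy: float | None = None  # kcal/mol; undefined for mixed forces

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("non-finite forces")


@runtime_checkable
class ForceProvider(Protocol):
    def evaluate(self, state: SystemState, qm_atoms: frozenset = frozenset()) -> ForceResult: ...


def minimum_image_displacement(d: np.ndarray, cell: np.ndarray, pbc: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention.

    Works on any (..., 3) array.  Non-periodic axes pass through unchanged.
    """
    d = np.asarray(d, dtype=float)
    out = d.copy()
    for ax in range(3):
        if pbc[ax]:
            L = cell[ax]
            out[..., ax] -= L * np.round(out[..., ax] / L)
    return out


def minimum_image_distance(a, b, cell, pbc) -> float:
    """Shortest |a - b| over all periodic images (orthorhombic cell)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    d = minimum_image_displacement(a - b, np.asarray(cell, float), np.asarray(pbc, bool))
    return float(np.linalg.norm(d, axis=-1))


def evaluate_forces(state: SystemState, request: ForceRequest, provider: ForceProvider) -> ForceResult:
    """Run a provider for one QM-set request, with contract checks."""
    n = state.n_atoms
    if request.qm_atoms and (min(request.qm_atoms) < 0 or max(request.qm_atoms) >= n):
        raise IndexError("qm_atoms out of range")
    supported = getattr(provider, "supported_species", None)
    if supported is not None:
        unknown = set(np.unique(state.species)) - set(supported)
        if unknown:
            raise ValueError(f"provider does not support species: {sorted(unknown)}")
    result = provider.evaluate(state, frozenset(request.qm_atoms))
    if result.forces.shape != (n, 3):
        raise ValueError("provider returned wrong force array shape")
    return result


def kinetic_energy(state: SystemState) -> float:
    """Total kinetic energy in kcal/mol."""
    return float(0.5 * np.sum(state.masses[:, None] * state.velocities**2) * KE_TO_KCAL)


def numerical_forces(state: SystemState, provider: ForceProvider,
                     qm_atoms: frozenset = frozenset(), h: float = 1e-5) -> np.ndarray:
    """Central finite-difference forces -dE/dx; test oracle for providers."""
    f = np.zeros((state.n_atoms, 3))
    work = state.copy()
    for i in range(state.n_atoms):
        for ax in range(3):
            work.positions[i, ax] += h
            ep = provider.evaluate(work, qm_atoms).potential_energy
            work.positions[i, ax] -= 2 * h
            em = provider.evaluate(work, qm_atoms).potential_energy
            work.positions[i, ax] += h
            f[i, ax] = -(ep - em) / (2 * h)
    return f
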