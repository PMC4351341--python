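"""Adaptive, hysteretic partitioning of atoms into CORE / DYN_QM / BUFFER / MM.

The partition is rebuilt every step in three sequential selections, each
with hysteretic inner/outer radii: the core grows around the fixed core
list, the dynamical QM region grows around the core, and the buffer grows
around the dynamical QM region.  Hysteresis means an atom must come closer
than ``r_in`` to enter a region but farther than ``r_out`` to leave it,
which suppresses membership flicker for atoms hovering near a boundary.

When ``whole_molecules`` is set (the default, and the only mode used for
the water systems) any molecule with at least one selected atom is
promoted wholly to the innermost region reached by any of its atoms;
hysteresis memory is then effectively per (region, molecule).  The
"previously a member" test uses the previous step's post-promotion labels,
and membership in any *inner* region counts (an atom that was CORE last
step is a previous member of the dynamical QM region too).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SystemState, minimum_image_displacement

__all__ = [
    "CORE", "DYN_QM", "BUFFER", "MM", "LABEL_NAMES",
    "RegionSpec", "RegionLabels", "hysteretic_select", "partition",
]

CORE, DYN_QM, BUFFER, MM = 0, 1, 2, 3
LABEL_NAMES = {CORE: "CORE", DYN_QM: "DYN_QM", BUFFER: "BUFFER", MM: "MM"}


@dataclass(frozen=True)
class RegionSpec:
    """Fixed lists, hysteretic radii and selection options.

    Radii are (inner, outer) pairs in A with inner <= outer; a (0, 0) pair
    disables the corresponding adaptive selection.  ``species_filter``
    optionally restricts which interatomic distances are tested, e.g.
    ("O", "O") reproduces oxygen-oxygen-only selection for water.
    """

    fixed_core: tuple = ()
    fixed_qm: tuple = ()
    fixed_buffer: tuple = ()
    r_core: tuple = (0.0, 0.0)
    r_qm: tuple = (0.0, 0.0)
    r_buffer: tuple = (0.0, 0.0)
    species_filter: tuple | None = None
    whole_molecules: bool = True
    seed_is_only_fixed_core: bool = False
    max_extended_atoms: int | None = None

    def __post_init__(self) -> None:
        for name in ("r_core", "r_qm", "r_buffer"):
            r_in, r_out = getattr(self, name)
            if r_in > r_out:
                raise ValueError(f"{name}: inner radius exceeds outer radius")
            if r_in < 0:
                raise ValueError(f"{name}: negative radius")
        sets = [set(self.fixed_core), set(self.fixed_qm), set(self.fixed_buffer)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("fixed lists must be pairwise disjoint")


@dataclass
class RegionLabels:
    """Per-atom labels, retained between steps for hysteresis."""

    label: np.ndarray  # (N,) int8 in {CORE, DYN_QM, BUFFER, MM}

    @classmethod
    def initial(cls, n_atoms: int, spec: RegionSpec | None = None) -> "RegionLabels":
        lab = np.full(n_atoms, MM, dtype=np.int8)
        if spec is not None:
            lab[list(spec.fixed_buffer)] = BUFFER
            lab[list(spec.fixed_qm)] = DYN_QM
            lab[list(spec.fixed_core)] = CORE
        return cls(lab)

    def atoms(self, *labels: int) -> np.ndarray:
        return np.flatnonzero(np.isin(self.label, labels))

    @property
    def core(self) -> np.ndarray:
        return self.atoms(CORE)

    @property
    def dyn_qm(self) -> np.ndarray:
        """Dynamical QM region (includes the core)."""
        return self.atoms(CORE, DYN_QM)

    @property
    def buffer(self) -> np.ndarray:
        return self.atoms(BUFFER)

    @property
    def extended_qm(self) -> np.ndarray:
        """QM set of the extended calculation: dynamical QM plus buffer."""
        return self.atoms(CORE, DYN_QM, BUFFER)

    def counts(self) -> dict[str, int]:
        return {
            "n_core": int(np.sum(self.label == CORE)),
            "n_dyn_qm": int(np.sum(self.label <= DYN_QM)),
            "n_buffer": int(np.sum(self.label == BUFFER)),
            "n_extended": int(np.sum(self.label <= BUFFER)),
        }

    def copy(self) -> "RegionLabels":
        return RegionLabels(self.label.copy())


def _pair_min_distances(state: SystemState, cand: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """min over ref atoms of the minimum-image distance, per candidate."""
    d = minimum_image_displacement(
        state.positions[cand][:, None, :] - state.positions[ref][None, :, :],
        state.cell, state.pbc)
    return np.sqrt(np.sum(d * d, axis=-1)).min(axis=1)


def hysteretic_select(candidates, reference, prev_members, r_in: float, r_out: float,
                      state: SystemState, species_filter: tuple | None = None) -> np.ndarray:
    """Hysteretic cutoff selection.

    Returns the sorted atom indices
    ``{a in candidates : d(a, reference) <= r_in}
      union {a in prev_members & candidates : d(a, reference) <= r_out}``
    where ``d`` is the minimum over reference atoms of the minimum-image
    distance, restricted to the species filter when set: only candidate
    atoms of the filter species are distance-tested, and only against
    reference atoms of the filter species.
    """
    if r_in > r_out:
        raise ValueError("r_in exceeds r_out")
    cand = np.asarray(sorted(candidates), dtype=np.int64)
    ref = np.asarray(sorted(reference), dtype=np.int64)
    prev = np.asarray(sorted(prev_members), dtype=np.int64)
    if len(ref) == 0:
        raise ValueError("reference set must be nonempty")
    if len(cand) == 0 or r_out <= 0.0:
        return np.empty(0, dtype=np.int64)
    if species_filter is not None:
        s1, s2 = species_filter
        cand_ok = np.isin(state.species[cand], (s1, s2))
        ref_ok = np.isin(state.species[ref], (s1, s2))
        cand = cand[cand_ok]
        ref = ref[ref_ok]
        if len(cand) == 0 or len(ref) == 0:
            return np.empty(0, dtype=np.int64)
    dmin = _pair_min_distances(state, cand, ref)
    in_prev = np.isin(cand, prev)
    keep = (dmin <= r_in) | (in_prev & (dmin <= r_out))
    return cand[keep]


def _prev_members_of(prev: RegionLabels, region: int) -> np.ndarray:
    # membership in the region or any inner (enclosing-towards-core) region
    return np.flatnonzero(prev.label <= region)


def partition(state: SystemState, spec: RegionSpec, prev: RegionLabels) -> RegionLabels:
    """One full region assignment for the current configuration."""
    n = state.n_atoms
    all_atoms = np.arange(n)

    core = set(spec.fixed_core)
    if len(spec.fixed_core) and spec.r_core[1] > 0:
        sel = hysteretic_select(all_atoms, np.asarray(spec.fixed_core), _prev_members_of(prev, CORE),
                                *spec.r_core, state, spec.species_filter)
        core |= set(sel.tolist())

    qm = set(core) | set(spec.fixed_qm)
    qm_seed = np.asarray(sorted(spec.fixed_core if spec.seed_is_only_fixed_core else core),
                         dtype=np.int64)
    if len(qm_seed) and spec.r_qm[1] > 0:
        sel = hysteretic_select(all_atoms, qm_seed, _prev_members_of(prev, DYN_QM),
                                *spec.r_qm, state, spec.species_filter)
        qm |= set(sel.tolist())

    buf = set(spec.fixed_buffer)
    if len(qm) and spec.r_buffer[1] > 0:
        sel = hysteretic_select(all_atoms, np.asarray(sorted(qm)), _prev_members_of(prev, BUFFER),
                                *spec.r_buffer, state, spec.species_filter)
        buf |= set(sel.tolist())

    label = np.full(n, MM, dtype=np.int8)
    label[sorted(buf)] = BUFFER
    label[sorted(qm)] = DYN_QM     # precedence: inner labels overwrite outer
    label[sorted(core)] = CORE

    if spec.whole_molecules and n:
        # promote each molecule to the innermost label among its atoms
        mid = state.molecule_id
        order = np.argsort(mid, kind="stable")
        sorted_mid = mid[order]
        boundaries = np.r_[0, np.flatnonzero(np.diff(sorted_mid) != 0) + 1, n]
        for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
            atoms = order[b0:b1]
            label[atoms] = label[atoms].min()

    out = RegionLabels(label)
    if spec.max_extended_atoms is not None:
        n_ext = out.counts()["n_extended"]
        if n_ext > spec.max_extended_atoms:
            raise RuntimeError(
                f"extended QM region has {n_ext} atoms, exceeding the "
                f"max_extended_atoms cap of {spec.max_extended_atoms}")
    return out
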