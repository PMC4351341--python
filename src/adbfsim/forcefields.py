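"""Two deliberately mismatched classical water-like force models.

Model "A" plays the role of the expensive, accurate description ("QM") and
model "B" the cheap far-field one ("MM").  Both are classical: a water-like
molecule is one heavy atom ("O") and two light atoms ("H") held together by
harmonic bonds and a harmonic angle; molecules interact through a
shifted-force Lennard-Jones term between heavy atoms plus a short-range
Gaussian attraction between heavy and light atoms of different molecules,
which gives the liquid a structured, hydrogen-bond-like first neighbour
shell.  The models differ by a single dimensionless mismatch ``delta``
that scales model A's intermolecular well depths and length parameters by
(1 + delta); ``delta = 0`` makes the two models bitwise identical, which is
the controlled analogue of a QM model whose chemical potential matches the
MM one.

A composite evaluation assigns every pair interaction whose two atoms are
both in the QM set to model A and every other pair to model B;
intramolecular terms follow model A only when the whole molecule is in the
QM set.  This "both-in => A, else B" rule concentrates the model mismatch
exactly at the QM/MM boundary -- the error structure the buffered
force-mixing machinery is designed to bury inside the buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import ForceResult, SystemState, minimum_image_displacement

__all__ = [
    "WaterModelParams",
    "MismatchSpec",
    "DEFAULT_WATER_LIKE",
    "WaterTopology",
    "WaterForceField",
    "CompositeQMMM",
    "make_model_pair",
    "composite_qmmm_forces",
    "DoubleWell1D",
    "HarmonicWell",
]


@dataclass(frozen=True)
class WaterModelParams:
    """Parameters of one water-like model.

    ``rm_oo`` is the O-O Lennard-Jones minimum position (the "equilibrium
    distance"); the potential and force are shifted so both go continuously
    to zero at the cutoffs.
    """

    eps_oo: float = 0.20     # kcal/mol, O-O well depth
    rm_oo: float = 2.95      # A, O-O minimum-energy distance
    rcut_oo: float = 6.5     # A
    eps_oh: float = 0.75     # kcal/mol, intermolecular O...H well depth
    r_oh: float = 1.9        # A, O...H well position
    w_oh: float = 0.28       # A, O...H well width
    rcut_oh: float = 4.5     # A
    k_bond: float = 450.0    # kcal/mol/A^2
    b0: float = 1.0          # A
    k_angle: float = 55.0    # kcal/mol/rad^2
    theta0: float = 1.82421  # rad (104.52 deg)

    def scaled(self, delta: float) -> "WaterModelParams":
        """Scale intermolecular well depths and lengths by (1 + delta)."""
        s = 1.0 + delta
        if self.eps_oo * s < 0 or self.eps_oh * s < 0:
            raise ValueError("mismatch delta yields negative well depth")
        return replace(
            self,
            eps_oo=self.eps_oo * s, rm_oo=self.rm_oo * s, rcut_oo=self.rcut_oo * s,
            eps_oh=self.eps_oh * s, r_oh=self.r_oh * s, w_oh=self.w_oh * s,
            rcut_oh=self.rcut_oh * s,
        )


DEFAULT_WATER_LIKE = WaterModelParams()


@dataclass(frozen=True)
class MismatchSpec:
    """Dimensionless scale applied to model A's intermolecular parameters."""

    delta: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")


class WaterTopology:
    """Per-molecule O/H bookkeeping derived from species and molecule ids."""

    def __init__(self, state: SystemState):
        mol_arrays = state.molecule_indices()
        o_idx, h_idx = [], []
        for atoms in mol_arrays:
            sp = state.species[atoms]
            o = atoms[sp == "O"]
            h = atoms[sp == "H"]
            if len(o) != 1 or len(h) != 2 or len(atoms) != 3:
                raise ValueError("water-like model requires molecules of 1 O + 2 H")
            o_idx.append(o[0])
            h_idx.append(h)
        self.O = np.asarray(o_idx)               # (M,)
        self.H = np.asarray(h_idx)               # (M, 2)
        self.n_molecules = len(self.O)
        self.mol_of_atom = np.empty(state.n_atoms, dtype=np.int64)
        for m, atoms in enumerate(mol_arrays):
            self.mol_of_atom[atoms] = m

    @classmethod
    def from_state(cls, state: SystemState) -> "WaterTopology":
        return cls(state)


def _sf_lj(r, eps, rm, rcut):
    """Shifted-force 12-6 LJ in r_min form: energy and dU/dr, zero beyond cut."""
    inside = r < rcut
    rs = np.where(inside, r, rcut)  # avoid overflow warnings outside cut
    x6 = (rm / rs) ** 6
    u = eps * (x6 * x6 - 2.0 * x6)
    du = -12.0 * eps / rs * (x6 * x6 - x6)
    xc6 = (rm / rcut) ** 6
    uc = eps * (xc6 * xc6 - 2.0 * xc6)
    duc = -12.0 * eps / rcut * (xc6 * xc6 - xc6)
    u_sf = np.where(inside, u - uc - (rs - rcut) * duc, 0.0)
    du_sf = np.where(inside, du - duc, 0.0)
    return u_sf, du_sf


def _sf_gauss(r, eps, r0, w, rcut):
    """Shifted-force Gaussian well -eps*exp(-(r-r0)^2/2w^2); energy and dU/dr."""
    inside = r < rcut
    rs = np.where(inside, r, rcut)
    g = np.exp(-((rs - r0) ** 2) / (2.0 * w**2))
    u = -eps * g
    du = eps * (rs - r0) / w**2 * g
    gc = np.exp(-((rcut - r0) ** 2) / (2.0 * w**2))
    uc = -eps * gc
    duc = eps * (rcut - r0) / w**2 * gc
    u_sf = np.where(inside, u - uc - (rs - rcut) * duc, 0.0)
    du_sf = np.where(inside, du - duc, 0.0)
    return u_sf, du_sf


def _per_pair(maskA, a, b):
    """Select parameter a where maskA else b (scalars broadcast fine)."""
    return np.where(maskA, a, b)


def water_forces(state: SystemState, topo: WaterTopology,
                 pA: WaterModelParams, pB: WaterModelParams,
                 qm_atom: np.ndarray) -> ForceResult:
    """Composite force/energy kernel.

    ``qm_atom`` is an (N,) boolean mask.  A pair term uses model A's
    parameters iff both its atoms are flagged; intramolecular terms use A
    iff the whole molecule is flagged.  Pure single-model evaluations run
    through this same kernel (with a uniform mask), so that a zero-mismatch
    composite is bitwise identical to a single-model call.
    """
    pos = state.positions
    cell, pbc = state.cell, state.pbc
    n = state.n_atoms
    forces = np.zeros((n, 3))
    energy = 0.0
    O, H = topo.O, topo.H
    M = topo.n_molecules

    qm_atom = np.asarray(qm_atom, dtype=bool)
    qmO = qm_atom[O]
    qm_mol_full = qm_atom[O] & qm_atom[H[:, 0]] & qm_atom[H[:, 1]]

    # ---- intermolecular O-O (shifted-force LJ) ----
    if M > 1:
        d = minimum_image_displacement(pos[O][:, None, :] - pos[O][None, :, :], cell, pbc)
        r = np.sqrt(np.sum(d * d, axis=-1))
        np.fill_diagonal(r, np.inf)  # self pairs: beyond any cutoff
        bothA = qmO[:, None] & qmO[None, :]
        eps = _per_pair(bothA, pA.eps_oo, pB.eps_oo)
        rm = _per_pair(bothA, pA.rm_oo, pB.rm_oo)
        rc = _per_pair(bothA, pA.rcut_oo, pB.rcut_oo)
        u, du = _sf_lj(r, eps, rm, rc)
        energy += 0.5 * float(np.sum(u))  # full matrix counts each pair twice
        # force on i along +d (d = ri - rj): f_i = -du/dr * d/r
        forces[O] += np.einsum("ij,ijk->ik", -du / r, d)

        # ---- intermolecular O...H (Gaussian well) ----
        Hflat = H.reshape(-1)                      # (2M,)
        molH = np.repeat(np.arange(M), 2)
        d = minimum_image_displacement(pos[O][:, None, :] - pos[Hflat][None, :, :], cell, pbc)
        r = np.sqrt(np.sum(d * d, axis=-1))
        same = np.arange(M)[:, None] == molH[None, :]
        r[same] = np.inf  # intramolecular pairs carry no nonbonded term
        bothA = qmO[:, None] & qm_atom[Hflat][None, :]
        eps = _per_pair(bothA, pA.eps_oh, pB.eps_oh)
        r0 = _per_pair(bothA, pA.r_oh, pB.r_oh)
        w = _per_pair(bothA, pA.w_oh, pB.w_oh)
        rc = _per_pair(bothA, pA.rcut_oh, pB.rcut_oh)
        u, du = _sf_gauss(r, eps, r0, w, rc)
        energy += float(np.sum(u))
        coef = -du / r
        forces[O] += np.einsum("ij,ijk->ik", coef, d)
        forces[Hflat] -= np.einsum("ij,ijk->jk", coef, d)

    # ---- intramolecular bonds (O-H harmonic) ----
    for col in (0, 1):
        d = minimum_image_displacement(pos[O] - pos[H[:, col]], cell, pbc)
        r = np.linalg.norm(d, axis=-1)
        kb = _per_pair(qm_mol_full, pA.k_bond, pB.k_bond)
        b0 = _per_pair(qm_mol_full, pA.b0, pB.b0)
        energy += float(np.sum(0.5 * kb * (r - b0) ** 2))
        fpair = (-(kb * (r - b0)) / np.maximum(r, 1e-12))[:, None] * d
        forces[O] += fpair
        forces[H[:, col]] -= fpair

    # ---- intramolecular angle (H-O-H harmonic) ----
    u = minimum_image_displacement(pos[H[:, 0]] - pos[O], cell, pbc)
    v = minimum_image_displacement(pos[H[:, 1]] - pos[O], cell, pbc)
    lu = np.linalg.norm(u, axis=-1)
    lv = np.linalg.norm(v, axis=-1)
    cos_t = np.clip(np.sum(u * v, axis=-1) / (lu * lv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), 1e-8)
    ka = _per_pair(qm_mol_full, pA.k_angle, pB.k_angle)
    t0 = _per_pair(qm_mol_full, pA.theta0, pB.theta0)
    energy += float(np.sum(0.5 * ka * (theta - t0) ** 2))
    dU_dtheta = ka * (theta - t0)
    # dtheta/dr_H1 = -(1/sin) * d(cos)/dr_H1, d(cos)/du = v/(lu lv) - cos*u/lu^2
    coef = (dU_dtheta / sin_t)[:, None]
    g1 = coef * (v / (lu * lv)[:, None] - cos_t[:, None] * u / (lu**2)[:, None])
    g2 = coef * (u / (lu * lv)[:, None] - cos_t[:, None] * v / (lv**2)[:, None])
    forces[H[:, 0]] += g1
    forces[H[:, 1]] += g2
    forces[O] -= g1 + g2

    return ForceResult(forces=forces, potential_energy=energy)


class WaterForceField:
    """Pure single-model provider over water-like molecules."""

    supported_species = ("O", "H")

    def __init__(self, params: WaterModelParams = DEFAULT_WATER_LIKE):
        self.params = params
        self._topo_cache: tuple[int, WaterTopology] | None = None

    def _topo(self, state: SystemState) -> WaterTopology:
        # cache keyed on atom count: adequate because a provider is reused
        # across steps of one system, whose topology never changes
        if self._topo_cache is None or self._topo_cache[0] != state.n_atoms:
            self._topo_cache = (state.n_atoms, WaterTopology(state))
        return self._topo_cache[1]

    def evaluate(self, state: SystemState, qm_atoms: frozenset = frozenset()) -> ForceResult:
        mask = np.zeros(state.n_atoms, dtype=bool)
        return water_forces(state, self._topo(state), self.params, self.params, mask)


class CompositeQMMM:
    """Composite evaluator: both-atoms-QM pairs use A, all others B."""

    supported_species = ("O", "H")

    def __init__(self, A: WaterForceField, B: WaterForceField):
        self.A = A
        self.B = B
        self._topo_cache: tuple[int, WaterTopology] | None = None

    def _topo(self, state: SystemState) -> WaterTopology:
        if self._topo_cache is None or self._topo_cache[0] != state.n_atoms:
            self._topo_cache = (state.n_atoms, WaterTopology(state))
        return self._topo_cache[1]

    def evaluate(self, state: SystemState, qm_atoms: frozenset = frozenset()) -> ForceResult:
        mask = np.zeros(state.n_atoms, dtype=bool)
        if qm_atoms:
            idx = np.fromiter(qm_atoms, dtype=np.int64)
            if idx.min() < 0 or idx.max() >= state.n_atoms:
                raise IndexError("qm_atoms out of range")
            mask[idx] = True
        # The energy of a composite evaluation is well defined for a FIXED
        # qm set; callers that mix forces across evaluations discard it.
        return water_forces(state, self._topo(state), self.A.params, self.B.params, mask)


def make_model_pair(mismatch: MismatchSpec | float = MismatchSpec(0.0),
                    base: WaterModelParams = DEFAULT_WATER_LIKE,
                    ) -> tuple[WaterForceField, WaterForceField]:
    """Build the (A, B) provider pair for a given mismatch."""
    if not isinstance(mismatch, MismatchSpec):
        mismatch = MismatchSpec(float(mismatch))
    return WaterForceField(base.scaled(mismatch.delta)), WaterForceField(base)


def composite_qmmm_forces(state: SystemState, qm_atoms: frozenset,
                          A: WaterForceField, B: WaterForceField) -> ForceResult:
    return CompositeQMMM(A, B).evaluate(state, frozenset(qm_atoms))


class DoubleWell1D:
    """External double-well U = a (x^2 - 1)^2 on one coordinate of each atom.

    Used for the single-particle free-energy benchmarks; coordinates on the
    other axes are force-free.
    """

    def __init__(self, a: float = 5.0, axis: int = 0):
        self.a = a
        self.axis = axis

    def evaluate(self, state: SystemState, qm_atoms: frozenset = frozenset()) -> ForceResult:
        x = state.positions[:, self.axis]
        f = np.zeros_like(state.positions)
        f[:, self.axis] = -4.0 * self.a * x * (x**2 - 1.0)
        e = float(np.sum(self.a * (x**2 - 1.0) ** 2))
        return ForceResult(forces=f, potential_energy=e)


class HarmonicWell:
    """Isotropic harmonic tether U = k/2 |r - center|^2 on every atom."""

    def __init__(self, k: float, center=(0.0, 0.0, 0.0)):
        self.k = k
        self.center = np.asarray(center, dtype=float)

    def evaluate(self, state: SystemState, qm_atoms: frozenset = frozenset()) -> ForceResult:
        d = state.positions - self.center
        return ForceResult(forces=-self.k * d,
                           potential_energy=float(0.5 * self.k * np.sum(d * d)))
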