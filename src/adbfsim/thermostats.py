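"""Adaptive thermostats for nonconservative mixed-force dynamics.

Force mixing produces forces that are not the gradient of any energy, so
the dynamics continuously generates (or absorbs) heat near the region
boundaries.  An ordinary Nose-Hoover thermostat compensates such steady
heat fluxes but is not ergodic; a Langevin thermostat is ergodic but
cannot adapt its friction.  The adaptive Langevin thermostat runs both in
parallel: per degree of freedom,

    dq = (p/m) dt
    dp = F dt - (chi + gamma) p dt + sqrt(2 gamma m kB T) dW
    dchi = (p^2/m - n kB T) / Q dt,          Q = n kB T tau_NH^2,

so the Nose-Hoover variable chi drifts until the *effective* friction
(chi + gamma) dissipates exactly the injected heat, while the Langevin
noise/friction pair guarantees sampling of the canonical distribution.
The adaptive Nose-Hoover-chains-Langevin variant replaces the direct
Langevin coupling by a Nose-Hoover chain whose last element is
(optionally) Langevin-thermalized.

Both thermostats are *massive*: one independent control variable (or
chain) per Cartesian degree of freedom, because force-mixing heat is
generated locally near the QM-MM boundary and the required dissipation
varies in space.

Discretization: symmetric splitting B(dt/2) A(dt/2) [thermostat](dt)
A(dt/2) B(dt/2), with the Ornstein-Uhlenbeck part integrated exactly for
the instantaneous friction and the control-variable coupling applied by
symmetric half-updates around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ACC_PER_FORCE, KB, KE_TO_KCAL
from .core import SystemState

__all__ = [
    "AdLangevinState", "AdNHCLState", "ad_langevin_step", "ad_nhcl_step",
    "kinetic_temperature", "THERMOSTAT_PRESETS",
]

#: Named time-constant presets (fs): one matched to slow, gentle coupling
#: used for the proton-transfer runs, one stiffer for the hydrolysis runs.
THERMOSTAT_PRESETS = {
    "autoprotolysis": {"tau_langevin": 200.0, "tau_nh": 200.0},
    "hydrolysis": {"tau_langevin": 300.0, "tau_nh": 74.0},
}


@dataclass
class AdLangevinState:
    """Per-DOF adaptive Langevin thermostat state.

    ``chi`` has one entry per Cartesian DOF (massive mode, n = 1), units
    fs^-1.  ``gamma = 1/tau_langevin`` is the Langevin friction and
    ``Q = kB T tau_nh^2`` the Nose-Hoover fictitious mass.
    """

    temperature: float
    tau_langevin: float
    tau_nh: float
    rng: np.random.Generator
    chi: np.ndarray | None = None  # lazily shaped (N, 3) on first step

    def __post_init__(self) -> None:
        if self.tau_nh <= 0:
            raise ValueError("tau_nh must be positive")
        if self.tau_langevin < 0:
            raise ValueError("tau_langevin must be nonnegative")

    @property
    def gamma(self) -> float:
        return 0.0 if self.tau_langevin == 0 else 1.0 / self.tau_langevin

    @property
    def Q(self) -> float:
        return KB * self.temperature * self.tau_nh**2

    def _ensure(self, shape) -> None:
        if self.chi is None or self.chi.shape != shape:
            self.chi = np.zeros(shape)


def _chi_half_update(chi, v, m, kbt, Q, dt):
    # per-DOF kinetic energy in kcal/mol is m v^2 * KE_TO_KCAL
    chi += 0.5 * dt * (m * v**2 * KE_TO_KCAL - kbt) / Q


def _ou_step(v, friction, gamma, m, kbt, dt, rng, frozen_chi=False):
    """Exact OU update of v with total friction ``friction`` and Langevin
    fluctuation strength set by ``gamma`` alone (fluctuation-dissipation
    holds for the Langevin part; the Nose-Hoover part is deterministic)."""
    a = friction
    decay = np.exp(-a * dt)
    # integral factor (1 - exp(-2 a dt)) / a, stable for small |a|
    small = np.abs(a * dt) < 1e-8
    factor = np.where(small, 2.0 * dt * (1.0 - a * dt), -np.expm1(-2.0 * a * dt) / np.where(small, 1.0, a))
    var = (kbt / (m * KE_TO_KCAL)) * gamma * factor
    noise = rng.standard_normal(v.shape) if gamma > 0 else 0.0
    return decay * v + np.sqrt(np.maximum(var, 0.0)) * noise


def ad_langevin_step(state: SystemState, th: AdLangevinState, forces: np.ndarray,
                     dt: float, force_fn=None):
    """Advance one adaptive-Langevin step (BAOAB-style).

    ``forces`` are the forces at the current positions.  If ``force_fn`` is
    given it is called once at the new positions and its result is used for
    the final half-kick and returned (one evaluation per step, as in a
    velocity-Verlet loop); otherwise the entry forces are reused.
    Mutates ``state`` and ``th`` in place and returns (state, th, forces).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    m = state.masses[:, None]
    th._ensure(state.velocities.shape)
    kbt = KB * th.temperature

    state.velocities += 0.5 * dt * forces / m * ACC_PER_FORCE          # B
    state.positions += 0.5 * dt * state.velocities                     # A
    _chi_half_update(th.chi, state.velocities, m, kbt, th.Q, dt)
    state.velocities = _ou_step(state.velocities, th.chi + th.gamma,
                                th.gamma, m, kbt, dt, th.rng)          # O
    _chi_half_update(th.chi, state.velocities, m, kbt, th.Q, dt)
    state.positions += 0.5 * dt * state.velocities                     # A
    if force_fn is not None:
        forces = force_fn(state)
    state.velocities += 0.5 * dt * forces / m * ACC_PER_FORCE          # B
    return state, th, forces


@dataclass
class AdNHCLState:
    """Per-DOF adaptive Nose-Hoover-chains-Langevin thermostat state.

    ``xi`` is shaped (r, N, 3): chain variable i for every Cartesian DOF.
    ``gamma_l`` thermalizes the last chain element; r = 1 gives the
    adaptive Nose-Hoover-Langevin thermostat and gamma_l = 0 with r > 1
    the plain adaptive Nose-Hoover chain.
    """

    temperature: float
    tau_nh: float
    chain_length: int
    gamma_l: float
    rng: np.random.Generator
    xi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ValueError("chain length must be >= 1")
        if self.gamma_l < 0:
            raise ValueError("gamma_l must be nonnegative")

    @property
    def Q(self) -> np.ndarray:
        return np.full(self.chain_length, KB * self.temperature * self.tau_nh**2)

    def _ensure(self, shape) -> None:
        full = (self.chain_length,) + shape
        if self.xi is None or self.xi.shape != full:
            self.xi = np.zeros(full)


def _nhc_half(v, xi, Q, m, kbt, dt):
    """Half-step of the deterministic chain couplings (innermost last)."""
    r = len(xi)
    # update from the outermost chain element inwards
    for i in range(r - 1, 0, -1):
        G = (Q[i - 1] * xi[i - 1] ** 2 - kbt) / Q[i]
        xi[i] += 0.5 * dt * G
        xi[i - 1] *= np.exp(-0.5 * dt * xi[i])
    G0 = (m * v**2 * KE_TO_KCAL - kbt) / Q[0]
    xi[0] += 0.5 * dt * G0


def ad_nhcl_step(state: SystemState, th: AdNHCLState, forces: np.ndarray,
                 dt: float, force_fn=None):
    """Advance one adaptive NHC-Langevin step (same splitting skeleton as
    the adaptive Langevin step; the O-part scales v by exp(-xi_1 dt) and
    applies an exact OU step to the terminal chain variable)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    m = state.masses[:, None]
    th._ensure(state.velocities.shape)
    kbt = KB * th.temperature
    Q = th.Q

    state.velocities += 0.5 * dt * forces / m * ACC_PER_FORCE          # B
    state.positions += 0.5 * dt * state.velocities                     # A

    _nhc_half(state.velocities, th.xi, Q, m, kbt, dt)
    state.velocities *= np.exp(-dt * th.xi[0])
    if th.gamma_l > 0:
        c = np.exp(-th.gamma_l * dt)
        sigma = np.sqrt(kbt / Q[-1] * (1.0 - c**2))
        th.xi[-1] = c * th.xi[-1] + sigma * th.rng.standard_normal(th.xi[-1].shape)
    _nhc_half(state.velocities, th.xi, Q, m, kbt, dt)

    state.positions += 0.5 * dt * state.velocities                     # A
    if force_fn is not None:
        forces = force_fn(state)
    state.velocities += 0.5 * dt * forces / m * ACC_PER_FORCE          # B
    return state, th, forces


def kinetic_temperature(state: SystemState, per_dof: bool = False):
    """Instantaneous kinetic temperature in K (total or per Cartesian DOF)."""
    per = state.masses[:, None] * state.velocities**2 * KE_TO_KCAL / KB
    if per_dof:
        return per
    return float(per.mean())
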