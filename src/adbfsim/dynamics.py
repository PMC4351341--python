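"""The simulation loop: partitioning, force mixing, bias/restraints,
momentum correction and thermostatted integration.

Per step the pipeline is: (1) partition regions with hysteresis, (2) run
the extended and (if the variant requires it) reduced composite
evaluations, (3) mix forces abruptly, (4) add restraint and bias forces,
(5) apply the momentum correction, (6) advance one thermostatted
integrator step.  The region update happens at every force evaluation
(once per step), and the momentum correction acts on the total dynamical
force, bias included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ACC_PER_FORCE
from .core import ForceResult, SystemState
from .cvs import CVValue, axis_coordinate, distance_cv, distance_difference, drcn
from .mixing import (MixedForces, MomentumCorrectionSpec, correct_momentum,
                     run_variant_step)
from .regions import RegionLabels, RegionSpec
from .thermostats import (AdLangevinState, AdNHCLState, ad_langevin_step,
                          ad_nhcl_step, kinetic_temperature)

__all__ = [
    "RestraintSpec", "restraint_forces", "SimulationConfig", "Trajectory",
    "run_md", "steered_schedule", "run_steered",
]


def resolve_cv(spec: dict):
    """Build a CV engine (state -> CVValue) from a small dict description."""
    kind = spec["kind"]
    if kind == "distance":
        i, j = spec["atoms"]
        return lambda s: distance_cv(s, i, j)
    if kind == "drcn":
        return lambda s: drcn(s, spec["donor_O"], spec["acceptor_O"], spec["hydrogens"])
    if kind == "distance_difference":
        return lambda s: distance_difference(s, spec["P"], spec["O_leaving"], spec["O_attacking"])
    if kind == "axis":
        return lambda s: axis_coordinate(s, spec["atom"], spec.get("axis", 0))
    raise ValueError(f"unknown CV kind {kind!r}")


@dataclass
class RestraintSpec:
    """One-sided distance restraint or harmonic CV bias.

    ``one_sided_distance`` applies U = (k/2)(d - threshold)^2 only when the
    distance is beyond the threshold on the active side ("above" keeps
    atoms together, "below" keeps them apart); the force is continuous at
    the threshold.  ``harmonic_cv`` applies U = (k/2)(x - x0)^2 to any CV;
    ``x0`` is mutable so steering schedules can move it.
    """

    kind: str
    k: float
    atoms: tuple | None = None       # one_sided_distance
    threshold: float | None = None   # one_sided_distance
    side: str = "above"              # restraint active when d > threshold ("above") or d < ("below")
    cv: dict | None = None           # harmonic_cv
    x0: float | None = None          # harmonic_cv center

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant must be nonnegative")
        if self.kind not in ("one_sided_distance", "harmonic_cv"):
            raise ValueError(f"unknown restraint kind {self.kind!r}")
        if self.kind == "harmonic_cv":
            self._engine = resolve_cv(self.cv)

    def cv_value(self, state: SystemState) -> CVValue:
        if self.kind == "one_sided_distance":
            return distance_cv(state, *self.atoms)
        return self._engine(state)


def restraint_forces(state: SystemState, spec: RestraintSpec) -> ForceResult:
    """Force and energy of one restraint on the current configuration."""
    cv = spec.cv_value(state)
    if spec.kind == "one_sided_distance":
        d = cv.value
        active = d > spec.threshold if spec.side == "above" else d < spec.threshold
        if not active:
            return ForceResult(np.zeros_like(state.positions), 0.0)
        dx = d - spec.threshold
    else:
        dx = cv.value - spec.x0
    return ForceResult(forces=-spec.k * dx * cv.gradient,
                       potential_energy=float(0.5 * spec.k * dx**2))


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run (given providers and a state)."""

    dt: float = 0.5                       # fs
    n_steps: int = 1000
    variant: str = "AdBF"                 # or Conv/AdConv/AdUF/"single"
    region_spec: RegionSpec | None = None
    thermostat: str = "ad_langevin"       # ad_langevin | ad_nhl | ad_nhc | ad_nhcl | none
    temperature: float = 300.0            # K
    tau_langevin: float = 200.0           # fs
    tau_nh: float = 200.0                 # fs
    chain_length: int = 2
    momentum: MomentumCorrectionSpec = field(default_factory=MomentumCorrectionSpec)
    restraints: list = field(default_factory=list)
    frame_interval: int = 100             # 0 disables frame storage
    log_interval: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")


@dataclass
class Trajectory:
    frames: list                 # (step, SystemState, RegionLabels | None)
    logs: dict                   # column -> list
    final_state: SystemState
    final_labels: RegionLabels | None

    def log_array(self, key: str) -> np.ndarray:
        return np.asarray(self.logs[key])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.logs)


def _make_thermostat(config: SimulationConfig):
    rng = np.random.default_rng(config.seed)
    if config.thermostat == "none":
        return None
    if config.thermostat == "ad_langevin":
        return AdLangevinState(config.temperature, config.tau_langevin, config.tau_nh, rng)
    if config.thermostat in ("ad_nhl", "ad_nhc", "ad_nhcl"):
        gamma_l = 0.0 if config.thermostat == "ad_nhc" else (
            1.0 / config.tau_langevin if config.tau_langevin > 0 else 0.0)
        r = 1 if config.thermostat == "ad_nhl" else config.chain_length
        return AdNHCLState(config.temperature, config.tau_nh, r, gamma_l, rng)
    raise ValueError(f"unknown thermostat {config.thermostat!r}")


def run_md(initial: SystemState, config: SimulationConfig,
           provider=None, A=None, B=None,
           x0_of_step=None) -> Trajectory:
    """Run the full adaptive force-mixing MD loop.

    ``provider`` is the force provider for ``variant="single"`` runs; the
    adaptive variants need the (A, B) model pair.  ``x0_of_step`` is an
    optional callable step -> x0 that moves every harmonic_cv restraint
    center (used by the steering schedule).  Bit-reproducible for a fixed
    config and initial state.
    """
    state = initial.copy()
    spec = config.region_spec
    variant = config.variant
    labels = (RegionLabels.initial(state.n_atoms, spec) if variant != "single" and spec is not None
              else None)
    harmonic = [r for r in config.restraints if r.kind == "harmonic_cv"]

    diag: dict = {}

    current_step = [0]

    def compute(s: SystemState) -> np.ndarray:
        nonlocal labels
        if not (np.all(np.isfinite(s.positions)) and np.all(np.isfinite(s.velocities))):
            raise RuntimeError(
                f"non-finite positions at step {current_step[0]} (dynamics blew up)")
        try:
            if variant == "single":
                res = provider.evaluate(s)
                mixed = MixedForces(res.forces.copy(),
                                    np.zeros(s.n_atoms, dtype=np.int8),
                                    res.forces.sum(axis=0))
                pe = res.potential_energy
            else:
                mixed, labels, _ = run_variant_step(s, spec, variant, A, B, labels)
                pe = None  # mixed forces have no well-defined total energy
        except ValueError as err:
            if "non-finite" in str(err):
                raise RuntimeError(
                    f"non-finite forces at step {current_step[0]} (dynamics blew up)"
                ) from err
            raise
        for r in config.restraints:
            rf = restraint_forces(s, r)
            mixed.forces += rf.forces
            if pe is not None:
                pe += rf.potential_energy
        diag["potential_energy"] = pe
        mixed.net_force_before_correction = mixed.forces.sum(axis=0)
        corrected = correct_momentum(mixed, s.masses, config.momentum, labels)
        diag["net_before"] = mixed.net_force_before_correction
        diag["net_after"] = corrected.forces.sum(axis=0)
        return corrected.forces

    th = _make_thermostat(config)
    logs: dict[str, list] = {k: [] for k in
                             ("step", "temperature", "potential_energy",
                              "net_force_before", "net_force_after")}
    if labels is not None:
        for k in ("n_core", "n_dyn_qm", "n_buffer", "n_extended"):
            logs[k] = []
    if harmonic:
        logs["cv"] = []
        logs["x0"] = []
    frames: list = []

    def log_step(step: int) -> None:
        if config.log_interval and step % config.log_interval == 0:
            logs["step"].append(step)
            logs["temperature"].append(kinetic_temperature(state))
            logs["potential_energy"].append(diag.get("potential_energy"))
            logs["net_force_before"].append(float(np.max(np.abs(diag["net_before"]))))
            logs["net_force_after"].append(float(np.max(np.abs(diag["net_after"]))))
            if labels is not None:
                for k, v in labels.counts().items():
                    logs[k].append(v)
            if harmonic:
                logs["cv"].append(harmonic[0].cv_value(state).value)
                logs["x0"].append(harmonic[0].x0)
        if config.frame_interval and step % config.frame_interval == 0:
            frames.append((step, state.copy(), labels.copy() if labels is not None else None))

    forces = compute(state)
    log_step(0)
    m = state.masses[:, None]
    for step in range(1, config.n_steps + 1):
        current_step[0] = step
        if x0_of_step is not None:
            x0 = x0_of_step(step)
            for r in harmonic:
                r.x0 = x0
        if th is None:  # velocity Verlet
            state.velocities += 0.5 * config.dt * forces / m * ACC_PER_FORCE
            state.positions += config.dt * state.velocities
            forces = compute(state)
            state.velocities += 0.5 * config.dt * forces / m * ACC_PER_FORCE
        elif isinstance(th, AdLangevinState):
            _, _, forces = ad_langevin_step(state, th, forces, config.dt, force_fn=compute)
        else:
            _, _, forces = ad_nhcl_step(state, th, forces, config.dt, force_fn=compute)
        if not np.all(np.isfinite(state.positions)):
            raise RuntimeError(f"non-finite positions at step {step} (dynamics blew up)")
        log_step(step)
    return Trajectory(frames=frames, logs=logs, final_state=state,
                      final_labels=labels.copy() if labels is not None else None)


def steered_schedule(x0_start: float, x0_end: float, increment: float,
                     move_steps: int, hold_steps: int):
    """Window list for a steered umbrella run.

    The restraint center moves linearly from one window value to the next
    over ``move_steps`` steps, then holds for ``hold_steps`` steps during
    which samples are collected.  Returns a list of dicts with the window
    center and the (start, end) step ranges of its hold period.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    n_win = int(round(abs(x0_end - x0_start) / increment)) + 1
    sgn = 1.0 if x0_end >= x0_start else -1.0
    windows = []
    step = 0
    for w in range(n_win):
        x0 = x0_start + sgn * w * increment
        move = move_steps if w > 0 else 0
        windows.append({"x0": float(x0), "move_start": step, "hold_start": step + move,
                        "hold_end": step + move + hold_steps})
        step += move + hold_steps
    return windows


def run_steered(initial: SystemState, config: SimulationConfig, windows: list,
                provider=None, A=None, B=None, equilibration_drop: int = 0):
    """Run a steered umbrella schedule and collect per-window CV samples.

    The harmonic restraint in ``config.restraints`` is moved according to
    ``windows`` (from :func:`steered_schedule`).  Returns the trajectory
    and a list of (x0, samples) pairs, samples taken every log interval
    during each window's hold period after dropping ``equilibration_drop``
    initial samples.
    """
    total = windows[-1]["hold_end"]
    bounds = [(w["move_start"], w["hold_start"], w["hold_end"], w["x0"]) for w in windows]
    x0_prev = [windows[0]["x0"]] + [w["x0"] for w in windows[:-1]]

    def x0_of_step(step):
        for (m0, h0, h1, x0), xp in zip(bounds, x0_prev):
            if step <= h1:
                if step >= h0 or h0 == m0:
                    return x0
                frac = (step - m0) / (h0 - m0)
                return xp + frac * (x0 - xp)
        return bounds[-1][3]

    cfg = replace(config, n_steps=total, log_interval=1)
    traj = run_md(initial, cfg, provider=provider, A=A, B=B, x0_of_step=x0_of_step)
    steps = traj.log_array("step")
    cv = traj.log_array("cv")
    out = []
    for w in windows:
        sel = (steps >= w["hold_start"]) & (steps < w["hold_end"])
        samples = cv[sel][equilibration_drop:]
        out.append((w["x0"], samples))
    return traj, out
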