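"""Abrupt force mixing of the extended and reduced evaluations.

Atoms in the dynamical QM region (core included) take their forces from
the extended evaluation, whose QM set is enlarged by the buffer; all other
atoms take forces from the reduced evaluation, whose QM set is the core
(possibly empty, i.e. a pure-MM call).  There is no transition region:
forces switch abruptly from one description to the other.  Because the
mixed force field is not the gradient of any energy, the total force does
not sum exactly to zero; an explicit momentum correction restores it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ForceResult, SystemState
from .forcefields import WaterForceField
from .regions import DYN_QM, RegionLabels, RegionSpec, partition

__all__ = [
    "MixedForces", "MomentumCorrectionSpec", "VARIANTS",
    "mix_forces", "correct_momentum", "validate_variant_spec", "run_variant_step",
]

EXTENDED, REDUCED = 0, 1

#: Method variants: Conv (fixed QM set, single evaluation), AdConv (adaptive
#: QM set, single evaluation), AdUF (force mixing, no buffer), AdBF (force
#: mixing with buffer).
VARIANTS = ("Conv", "AdConv", "AdUF", "AdBF")


@dataclass
class MixedForces:
    forces: np.ndarray                     # (N, 3)
    source: np.ndarray                     # (N,) int8: 0 extended, 1 reduced
    net_force_before_correction: np.ndarray  # (3,)


@dataclass(frozen=True)
class MomentumCorrectionSpec:
    """How to remove the net force of the mixed field.

    ``mode``: "none", "uniform" (same correction vector per atom) or
    "mass_weighted" (correction proportional to the atom's mass).
    ``region``: which atoms absorb the correction -- "all", "extended_qm"
    (dynamical QM + buffer) or "dynamical_qm".
    """

    mode: str = "mass_weighted"
    region: str = "all"

    def __post_init__(self) -> None:
        if self.mode not in ("none", "uniform", "mass_weighted"):
            raise ValueError(f"unknown momentum correction mode {self.mode!r}")
        if self.region not in ("all", "extended_qm", "dynamical_qm"):
            raise ValueError(f"unknown momentum correction region {self.region!r}")


def mix_forces(f_extended: ForceResult, f_reduced: ForceResult,
               labels: RegionLabels) -> MixedForces:
    """Per-atom abrupt selection: dynamical QM from extended, rest reduced."""
    fe, fr = f_extended.forces, f_reduced.forces
    if fe.shape != fr.shape:
        raise ValueError("extended and reduced force arrays differ in shape")
    take_ext = labels.label <= DYN_QM
    forces = np.where(take_ext[:, None], fe, fr)
    source = np.where(take_ext, EXTENDED, REDUCED).astype(np.int8)
    return MixedForces(forces=forces, source=source,
                       net_force_before_correction=forces.sum(axis=0))


def correct_momentum(mixed: MixedForces, masses: np.ndarray,
                     spec: MomentumCorrectionSpec,
                     labels: RegionLabels | None = None) -> MixedForces:
    """Subtract the net force so that sum(F) = 0 exactly (to roundoff)."""
    if spec.mode == "none":
        return mixed
    n = len(mixed.forces)
    if spec.region == "all":
        region = np.arange(n)
    else:
        if labels is None:
            raise ValueError("region-restricted correction requires labels")
        region = labels.extended_qm if spec.region == "extended_qm" else labels.dyn_qm
    if len(region) == 0:
        raise ValueError("momentum correction region is empty")
    f = mixed.forces.copy()
    fnet = f.sum(axis=0)
    if spec.mode == "uniform":
        f[region] -= fnet / len(region)
    else:  # mass_weighted
        m = np.asarray(masses, dtype=float)[region]
        f[region] -= (m / m.sum())[:, None] * fnet
    return MixedForces(forces=f, source=mixed.source,
                       net_force_before_correction=mixed.net_force_before_correction)


def validate_variant_spec(variant: str, spec: RegionSpec) -> None:
    """Reject region specifications inconsistent with the method variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown method variant {variant!r}")
    no_buffer = spec.r_buffer == (0.0, 0.0) and not spec.fixed_buffer
    if variant == "Conv":
        if (spec.r_core[1] or spec.r_qm[1]) or not no_buffer:
            raise ValueError("Conv requires all adaptive radii zero and an empty buffer")
    elif variant == "AdConv":
        if not no_buffer:
            raise ValueError("AdConv requires an empty buffer region")
        if spec.r_qm[1] > 0:
            raise ValueError("AdConv requires the core and dynamical QM regions to coincide "
                             "(r_qm must be zero; use r_core for the adaptive selection)")
    elif variant == "AdUF":
        if not no_buffer:
            raise ValueError("AdUF requires an empty buffer region")


def run_variant_step(state: SystemState, spec: RegionSpec, variant: str,
                     A: WaterForceField, B: WaterForceField,
                     prev: RegionLabels, provider=None,
                     ) -> tuple[MixedForces, RegionLabels, int]:
    """Partition + force evaluation(s) + mixing for one step.

    Returns the (uncorrected) mixed forces, the new labels, and the number
    of composite evaluations performed (1 for Conv/AdConv, 2 for AdUF/AdBF).
    ``provider`` may override the composite evaluator (defaults to the
    A/B water composite).
    """
    from .forcefields import CompositeQMMM

    validate_variant_spec(variant, spec)
    labels = partition(state, spec, prev)
    comp = provider if provider is not None else CompositeQMMM(A, B)

    if variant in ("Conv", "AdConv"):
        qm = frozenset(labels.dyn_qm.tolist())
        res = comp.evaluate(state, qm)
        mixed = MixedForces(forces=res.forces.copy(),
                            source=np.full(state.n_atoms, EXTENDED, dtype=np.int8),
                            net_force_before_correction=res.forces.sum(axis=0))
        return mixed, labels, 1

    ext_qm = frozenset((labels.extended_qm if variant == "AdBF" else labels.dyn_qm).tolist())
    red_qm = frozenset(labels.core.tolist())
    f_ext = comp.evaluate(state, ext_qm)
    f_red = comp.evaluate(state, red_qm)
    return mix_forces(f_ext, f_red, labels), labels, 2
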