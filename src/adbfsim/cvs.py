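"""Differentiable collective variables.

Two reaction coordinates are provided, with analytic gradients:

* ``drcn`` -- the difference of rational coordination numbers of an
  acceptor and a donor oxygen with respect to a set of transferable
  hydrogens.  The switching function n(r) = (1-(r/r0)^a)/(1-(r/r0)^b) with
  even exponents a < b decays smoothly from 1 at r = 0 to 0 at large r and
  counts a hydrogen as "bound" when it sits within ~r0 of the oxygen, so
  the difference tracks proton transfer: 0 in the reactant state, ~2 after
  both protons have moved.
* ``distance_difference`` -- d(leaving O, P) - d(attacking O, P), the
  phosphoryl-transfer coordinate; 0 at the symmetric (transition-like)
  arrangement.

Plain interatomic ``distance`` is included for restraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SystemState, minimum_image_displacement

__all__ = ["SwitchingParams", "CVValue", "rational_n", "rational_n_and_derivative",
           "drcn", "distance_difference", "distance_cv", "axis_coordinate"]


@dataclass(frozen=True)
class SwitchingParams:
    alpha: int = 6
    beta: int = 18
    r0: float = 1.6  # A

    def __post_init__(self) -> None:
        if not (0 < self.alpha < self.beta):
            raise ValueError("require 0 < alpha < beta")
        if self.alpha % 2 or self.beta % 2:
            raise ValueError("alpha and beta must be even")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")


@dataclass
class CVValue:
    value: float
    gradient: np.ndarray  # (N, 3), nonzero only on member atoms


# Near x = r/r0 = 1 both numerator and denominator vanish; expand
# (1-x^a)/(1-x^b) in t = x - 1 to second order to avoid 0/0.
_SERIES_HALFWIDTH = 1e-4


def rational_n_and_derivative(r: float, p: SwitchingParams) -> tuple[float, float]:
    """Rational coordination count n(r) and dn/dr."""
    if r < 0:
        raise ValueError("negative distance")
    a, b, r0 = p.alpha, p.beta, p.r0
    x = r / r0
    if x == 0.0:
        return 1.0, 0.0
    t = x - 1.0
    if abs(t) < _SERIES_HALFWIDTH:
        # n(1+t) = (a/b)[1 + (a-b)t/2 + O(t^2)]; truncation error ~1e-8 here
        c1 = (a - b) / 2.0
        return (a / b) * (1.0 + c1 * t), (a / b) * c1 / r0
    num = 1.0 - x**a
    den = 1.0 - x**b
    n = num / den
    dn = (-a * x ** (a - 1) * den + b * x ** (b - 1) * num) / den**2 / r0
    return n, dn


def rational_n(r: float, p: SwitchingParams) -> float:
    """n(r) in (0, 1]; equals alpha/beta at the removable point r = r0."""
    return rational_n_and_derivative(r, p)[0]


def _mi_vec(state: SystemState, i: int, j: int) -> np.ndarray:
    return minimum_image_displacement(state.positions[i] - state.positions[j],
                                      state.cell, state.pbc)


def drcn(state: SystemState, donor_O: int, acceptor_O: int, hydrogens,
         p: SwitchingParams = SwitchingParams()) -> CVValue:
    """Difference of rational coordination numbers, acceptor minus donor."""
    hydrogens = list(hydrogens)
    if not hydrogens:
        raise ValueError("empty hydrogen list")
    ids = {donor_O, acceptor_O, *hydrogens}
    if len(ids) != 2 + len(hydrogens):
        raise ValueError("donor, acceptor and hydrogens must be distinct")
    grad = np.zeros_like(state.positions)
    value = 0.0
    for O, sign in ((acceptor_O, +1.0), (donor_O, -1.0)):
        for h in hydrogens:
            d = _mi_vec(state, O, h)
            r = float(np.linalg.norm(d))
            n, dn = rational_n_and_derivative(r, p)
            value += sign * n
            if r > 0:
                g = sign * dn * d / r
                grad[O] += g
                grad[h] -= g
    return CVValue(value=value, gradient=grad)


def distance_difference(state: SystemState, P: int, O_leaving: int, O_attacking: int) -> CVValue:
    """d(O_leaving, P) - d(O_attacking, P), minimum-image, in A."""
    if len({P, O_leaving, O_attacking}) != 3:
        raise ValueError("indices must be distinct")
    grad = np.zeros_like(state.positions)
    value = 0.0
    for O, sign in ((O_leaving, +1.0), (O_attacking, -1.0)):
        d = _mi_vec(state, O, P)
        r = float(np.linalg.norm(d))
        if r == 0.0:
            raise ValueError("coincident atoms: gradient undefined")
        value += sign * r
        grad[O] += sign * d / r
        grad[P] -= sign * d / r
    return CVValue(value=value, gradient=grad)


def distance_cv(state: SystemState, i: int, j: int) -> CVValue:
    """Plain minimum-image distance with gradient."""
    d = _mi_vec(state, i, j)
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("coincident atoms: gradient undefined")
    grad = np.zeros_like(state.positions)
    grad[i] = d / r
    grad[j] = -d / r
    return CVValue(value=r, gradient=grad)


def axis_coordinate(state: SystemState, atom: int, axis: int = 0) -> CVValue:
    """Cartesian coordinate of one atom (used by the 1-D benchmarks)."""
    grad = np.zeros_like(state.positions)
    grad[atom, axis] = 1.0
    return CVValue(value=float(state.positions[atom, axis]), gradient=grad)
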