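"""Collective variables with analytic gradients.

Two CVs drive the free-energy machinery: an interatomic distance (the
metal–ligand dissociation coordinate) and a coordination number built from
the rational switching function

    s(r) = (1 - (r/r0)^p) / (1 - (r/r0)^q),    N = sum_ligands s(r),

with the removable singularity at r = r0 evaluated as its p/q limit.  Both
CVs return value and the full position gradient, so they can be biased
harmonically during MD and unbiased by WHAM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DistanceCV:
    """Distance between two atoms (non-periodic; cluster systems)."""

    i: int
    j: int
    kind: str = "interatomic-distance"

    def value_and_gradient(self, positions: np.ndarray):
        d = positions[self.i] - positions[self.j]
        r = float(np.linalg.norm(d))
        grad = np.zeros_like(positions)
        u = d / r
        grad[self.i] = u
        grad[self.j] = -u
        return r, grad

    def value(self, positions: np.ndarray) -> float:
        return self.value_and_gradient(positions)[0]


def switching_function(r: np.ndarray, r0: float, p: int, q: int):
    """Rational switch s(r) and ds/dr, stable through r = r0.

    Near x = r/r0 = 1 both numerator and denominator vanish; the limit is
    s -> p/q with slope (p/q)(p-q)/2 / r0, which the series branch uses.
    """
    x = np.asarray(r, dtype=float) / r0
    s = np.empty_like(x)
    ds = np.empty_like(x)
    near = np.abs(x - 1.0) < 1e-6
    xn = x[~near]
    xp = xn**p
    xq = xn**q
    denom = 1.0 - xq
    s[~near] = (1.0 - xp) / denom
    # d/dx [(1-x^p)/(1-x^q)] = (-p x^{p-1} (1-x^q) + q x^{q-1} (1-x^p)) / (1-x^q)^2
    ds[~near] = (-p * xn ** (p - 1) * denom + q * xn ** (q - 1) * (1.0 - xp)) / denom**2
    if np.any(near):
        eps = x[near] - 1.0
        # s = (p/q)(1 + (p-q)/2 eps + O(eps^2))
        s[near] = (p / q) * (1.0 + 0.5 * (p - q) * eps)
        ds[near] = (p / q) * 0.5 * (p - q)
    return s, ds / r0


@dataclass
class CoordinationCV:
    """Coordination number of ``center`` by ``ligands`` with a rational switch."""

    center: int
    ligands: np.ndarray
    r0: float
    p: int = 6
    q: int = 12
    kind: str = "coordination-number"

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.p >= self.q or self.p % 2 or self.q % 2:
            raise ValueError("need even exponents with p < q")
        self.ligands = np.asarray(self.ligands, dtype=np.int64)

    def value_and_gradient(self, positions: np.ndarray):
        d = positions[self.ligands] - positions[self.center]
        r = np.linalg.norm(d, axis=1)
        s, ds = switching_function(r, self.r0, self.p, self.q)
        grad = np.zeros_like(positions)
        gvec = (ds / r)[:, None] * d
        np.add.at(grad, self.ligands, gvec)
        grad[self.center] -= gvec.sum(axis=0)
        return float(s.sum()), grad

    def value(self, positions: np.ndarray) -> float:
        return self.value_and_gradient(positions)[0]


def coordination_number(config_or_positions, selection, r0: float, p: int = 6, q: int = 12):
    """Coordination number and its gradient for (center, ligand indices)."""
    pos = getattr(config_or_positions, "positions", config_or_positions)
    center, ligands = selection
    cv = CoordinationCV(center=center, ligands=np.asarray(ligands), r0=r0, p=p, q=q)
    return cv.value_and_gradient(np.asarray(pos, dtype=float))
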