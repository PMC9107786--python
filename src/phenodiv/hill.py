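"""Phenological Hill numbers (qPD) from distances and relative intensities.

The measure follows the attribute-diversity extension of Hill numbers to
species-pairwise distances. With relative intensities p_i (curve areas
normalized to sum to 1) and overlap distances O_ij, the standardizing
factor is the Rao-type quadratic sum

    Q = sum_i sum_j O_ij p_i p_j,

and the phenological Hill number of order q >= 0 is

    qPD = [ sum_i sum_j (O_ij / Q) (p_i p_j)^q ] ^ (1 / (2 (1 - q)))

with the Shannon-limit form at q = 1:

    1PD = exp( -1/2 * sum_i sum_j (O_ij / Q) p_i p_j log(p_i p_j) ).

qPD is the effective number of equally abundant, phenologically
completely distinct curves: S pairwise-disjoint equal-area curves give
qPD = S at every q, and a community of identical curves has Q = 0 and
is assigned qPD = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CommunityPhenology, OverlapDistanceMatrix
from .overlap import curve_integral

__all__ = [
    "IntensityWeights",
    "PDProfile",
    "relative_intensities",
    "rao_factor",
    "pd",
    "pd_profile",
]

#: half-width of the q = 1 neighborhood in which the Shannon-limit form is used
Q1_EPS = 1e-6


@dataclass(frozen=True)
class IntensityWeights:
    """Relative intensities p_i of the phenological event, one per species."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if np.any(p <= 0):
            raise ValueError("all relative intensities must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"relative intensities sum to {p.sum()!r}, not 1")


@dataclass(frozen=True)
class PDProfile:
    """qPD evaluated on a grid of orders q, with the S and Q used."""

    orders: np.ndarray
    pd_values: np.ndarray
    S: int
    Q: float

    def __iter__(self):
        return iter(zip(self.orders.tolist(), self.pd_values.tolist()))


def relative_intensities(comm: CommunityPhenology) -> IntensityWeights:
    """p_i = area of curve i / total area over all curves (trapezoidal)."""
    areas = np.array([curve_integral(c, comm.grid) for c in comm.curves])
    zero = [comm.species[i] for i in np.flatnonzero(areas <= 0)]
    if zero:
        raise ValueError(
            f"species with zero integral must be dropped upstream: {', '.join(zero)}"
        )
    return IntensityWeights(areas / areas.sum())


def rao_factor(d: OverlapDistanceMatrix, w: IntensityWeights) -> float:
    """Q = sum over all ordered pairs (including i = j) of O_ij p_i p_j."""
    if d.S != w.p.size:
        raise ValueError(f"distance matrix has {d.S} species but weights have {w.p.size}")
    return float(w.p @ d.values @ w.p)


def pd(d: OverlapDistanceMatrix, w: IntensityWeights, q: float) -> float:
    """Phenological Hill number of order q.

    Q = 0 (all curves identical) returns 0. Within 1e-6 of q = 1 the
    Shannon-limit form is used; elsewhere the order-q form. Diagonal
    terms are harmless in both sums because O_ii = 0.
    """
    if q < 0:
        raise ValueError(f"order q must be nonnegative, got {q}")
    Q = rao_factor(d, w)
    if Q == 0.0:
        return 0.0
    pp = np.outer(w.p, w.p)
    if abs(q - 1.0) < Q1_EPS:
        val = float(np.exp(-0.5 * np.sum(d.values / Q * pp * np.log(pp))))
    else:
        total = float(np.sum(d.values / Q * pp**q))
        val = total ** (1.0 / (2.0 * (1.0 - q)))
    if not np.isfinite(val):
        raise FloatingPointError(f"non-finite qPD at q = {q}")
    return val


def pd_profile(
    d: OverlapDistanceMatrix,
    w: IntensityWeights,
    q_min: float = 0.0,
    q_max: float = 2.0,
    steps: int = 41,
) -> PDProfile:
    """Evaluate qPD on an evenly spaced grid of orders.

    The default grid, q in [0, 2] with 41 points, covers the range
    ecologists usually inspect.
    """
    if not q_min < q_max:
        raise ValueError(f"need q_min < q_max, got [{q_min}, {q_max}]")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    orders = np.linspace(q_min, q_max, int(steps))
    values = np.array([pd(d, w, float(q)) for q in orders])
    return PDProfile(orders, values, S=d.S, Q=rao_factor(d, w))
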