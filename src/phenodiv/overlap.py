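"""Pairwise curve-overlap distances (modified Morisita-Horn index).

For two nonnegative phenological curves z_i(t), z_j(t) on a shared grid,

    O_ij = 1 - 2 * int(z_i z_j) / (int(z_i^2) + int(z_j^2))

with all integrals taken over the studied time interval by the composite
trapezoidal rule. O_ij = 0 iff the curves are pointwise identical and
O_ij = 1 iff their supports are disjoint; it always lies in [0, 1] for
nonnegative curves and is invariant to a joint rescaling of both curves.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import CommunityPhenology, OverlapDistanceMatrix, PhenologyCurve

__all__ = [
    "curve_integral",
    "overlap_distance",
    "distance_matrix",
    "UndefinedDistanceError",
]

logger = logging.getLogger("phenodiv")


class UndefinedDistanceError(ValueError):
    """Both curves identically zero: the overlap distance is undefined."""


def curve_integral(curve: PhenologyCurve, grid) -> float:
    """Trapezoidal integral of a curve over its time grid."""
    return float(np.trapezoid(curve.values, grid.times))


def _pair_distance(vi: np.ndarray, vj: np.ndarray, times: np.ndarray) -> float:
    cross = np.trapezoid(vi * vj, times)
    denom = np.trapezoid(vi * vi, times) + np.trapezoid(vj * vj, times)
    if denom == 0.0:
        raise UndefinedDistanceError("overlap distance undefined for two all-zero curves")
    d = 1.0 - 2.0 * cross / denom
    # guard float fuzz at the boundaries; the identity 0 <= O <= 1 is exact
    # in real arithmetic for nonnegative curves
    if -1e-12 < d < 0.0:
        d = 0.0
    return d


def overlap_distance(zi: PhenologyCurve, zj: PhenologyCurve, grid) -> float:
    """Overlap distance between two curves on the same grid.

    Raises if the grids disagree in length or if both curves are
    identically zero. A single all-zero curve against a nonzero partner
    yields 1 with a warning (such species should normally have been
    dropped during smoothing).
    """
    if zi.values.size != zj.values.size or zi.values.size != len(grid):
        raise ValueError(
            f"curves {zi.species_id!r} and {zj.species_id!r} are not on the same grid"
        )
    if not np.any(zi.values) or not np.any(zj.values):
        if not np.any(zi.values) and not np.any(zj.values):
            raise UndefinedDistanceError(
                f"overlap distance undefined: {zi.species_id!r} and {zj.species_id!r} are both all-zero"
            )
        logger.warning(
            "all-zero curve in pair (%s, %s); distance is 1 by convention",
            zi.species_id,
            zj.species_id,
        )
    return _pair_distance(zi.values, zj.values, grid.times)


def distance_matrix(comm: CommunityPhenology) -> OverlapDistanceMatrix:
    """Symmetric matrix of overlap distances over all species pairs.

    Each unordered pair is computed once; the diagonal is exactly zero.
    """
    if comm.S < 2:
        raise ValueError("need at least 2 species for a distance matrix")
    times = comm.grid.times
    vals = comm.matrix()
    S = comm.S
    out = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            try:
                d = _pair_distance(vals[i], vals[j], times)
            except UndefinedDistanceError as exc:
                raise UndefinedDistanceError(
                    f"pair ({comm.species[i]!r}, {comm.species[j]!r}): {exc}"
                ) from None
            out[i, j] = out[j, i] = d
    return OverlapDistanceMatrix(out, tuple(comm.species))
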