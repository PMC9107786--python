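"""Synthetic community phenologies for benchmarking qPD.

Nine named scenarios cover the crossing of three community traits:
how species spread their activity over time (staggered pulses vs
year-round presence), whether intensities are equal or unequal, and
community size (S = 40 vs S = 2):

==== ====================================================================
case definition
==== ====================================================================
a    S = 40, pulses evenly staggered over the period, equal intensities
b    as a, but intensities form a geometric series (ratio 0.9)
c    S = 40, identical constant curves
d    S = 40, identical time-modulated curves (1 + 0.5 sin)
e    S = 40, constant curves with geometric intensities
f    S = 2, two temporally disjoint pulses, equal intensities
g    S = 2, overlapping (displaced) pulses, equal intensities
h    as f with unequal intensities
i    as g with unequal intensities
==== ====================================================================

Pulses are Gaussian bumps truncated at 4 sigma, so pulses whose supports
do not meet are exactly disjoint on the grid; each curve is rescaled so
its trapezoidal area equals its prescribed intensity, which makes the
"equal intensities" cases exactly equal-weight. ``simulate_random``
draws randomized communities of such pulses for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CommunityPhenology, PhenologyCurve, TimeGrid

__all__ = ["SimulationSpec", "simulate_case", "simulate_random", "CASE_IDS"]

CASE_IDS = ("a", "b", "c", "d", "e", "f", "g", "h", "i")

#: amplitude ratio of the geometric series used for "unequal intensities"
UNEQUAL_RATIO = 0.9
#: pulse support as a fraction of the period, 40-species staggered cases
PULSE_WIDTH_S40 = 0.02
#: pulse support as a fraction of the period, 2-species cases
PULSE_WIDTH_S2 = 0.25
#: peak displacement (fraction of the period) for "not equally distributed"
DISPLACED_PEAKS = (0.40, 0.60)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameterized random community of truncated-Gaussian pulses.

    pulse_width is the full support of a pulse as a fraction of the
    period; peak positions are uniform over the period, widths are
    jittered within a factor of 2 of pulse_width, and unequal amplitudes
    are drawn log-uniformly over one decade.
    """

    S: int = 40
    grid_length: int = 360
    pattern: str = "staggered_pulse"
    pulse_width: float = 0.05
    amplitudes: str = "equal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError(f"S must be >= 2, got {self.S}")
        if self.grid_length < 16:
            raise ValueError(f"grid_length must be >= 16, got {self.grid_length}")
        if not 0.0 < self.pulse_width <= 1.0:
            raise ValueError(f"pulse_width must lie in (0, 1], got {self.pulse_width}")
        if self.pattern not in ("staggered_pulse", "constant", "constant_modulated"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.amplitudes not in ("equal", "unequal"):
            raise ValueError(f"amplitudes must be 'equal' or 'unequal', got {self.amplitudes!r}")


def _grid(grid_length: int) -> TimeGrid:
    return TimeGrid(np.arange(grid_length, dtype=float))


def _truncated_gaussian(times: np.ndarray, peak: float, support: float) -> np.ndarray:
    """Gaussian bump with support `support` (truncated at 4 sigma)."""
    sigma = support / 8.0
    v = np.exp(-0.5 * ((times - peak) / sigma) ** 2)
    v[np.abs(times - peak) > 4.0 * sigma] = 0.0
    return v


def _normalize_area(values: np.ndarray, times: np.ndarray, area: float) -> np.ndarray:
    cur = np.trapezoid(values, times)
    return values * (area / cur)


def _pulse_community(
    peaks: np.ndarray, areas: np.ndarray, grid_length: int, pulse_width: float,
    supports: np.ndarray | None = None,
) -> CommunityPhenology:
    grid = _grid(grid_length)
    period = grid_length - 1
    if supports is None:
        supports = np.full(peaks.size, pulse_width * period)
    curves = []
    for k, (peak, area, sup) in enumerate(zip(peaks, areas, supports)):
        v = _truncated_gaussian(grid.times, peak, sup)
        curves.append(
            PhenologyCurve(f"sp{k + 1:02d}", _normalize_area(v, grid.times, area), stage="smoothed")
        )
    return CommunityPhenology(grid, tuple(curves))


def _areas(S: int, amplitudes: str) -> np.ndarray:
    if amplitudes == "equal":
        return np.ones(S)
    return UNEQUAL_RATIO ** np.arange(S)


def simulate_case(case_id: str, grid_length: int = 360, seed: int = 0) -> CommunityPhenology:
    """Generate one of the nine named benchmark scenarios.

    All cases are deterministic given (case_id, grid_length); seed is
    accepted for interface uniformity. Curves are generated already
    smooth (stage = "smoothed"); pass them through the wavelet stage
    explicitly for end-to-end tests.
    """
    if case_id not in CASE_IDS:
        raise ValueError(f"unknown case {case_id!r}; valid cases: {', '.join(CASE_IDS)}")
    if grid_length < 16:
        raise ValueError(f"grid_length must be >= 16, got {grid_length}")
    grid = _grid(grid_length)
    period = grid_length - 1

    if case_id in ("a", "b"):
        S = 40
        peaks = (np.arange(S) + 0.5) / S * period
        return _pulse_community(peaks, _areas(S, "equal" if case_id == "a" else "unequal"),
                                grid_length, PULSE_WIDTH_S40)
    if case_id == "c":
        curves = tuple(
            PhenologyCurve(f"sp{k + 1:02d}", np.ones(grid_length), stage="smoothed")
            for k in range(40)
        )
        return CommunityPhenology(grid, curves)
    if case_id == "d":
        shape = 1.0 + 0.5 * np.sin(2.0 * np.pi * grid.times / period)
        curves = tuple(
            PhenologyCurve(f"sp{k + 1:02d}", shape.copy(), stage="smoothed") for k in range(40)
        )
        return CommunityPhenology(grid, curves)
    if case_id == "e":
        areas = _areas(40, "unequal")
        curves = tuple(
            PhenologyCurve(f"sp{k + 1:02d}", np.full(grid_length, a), stage="smoothed")
            for k, a in enumerate(areas)
        )
        return CommunityPhenology(grid, curves)

    # two-species cases f-i
    amplitudes = "equal" if case_id in ("f", "g") else "unequal"
    if case_id in ("f", "h"):
        peaks = np.array([0.25, 0.75]) * period
    else:
        peaks = np.array(DISPLACED_PEAKS) * period
    return _pulse_community(peaks, _areas(2, amplitudes), grid_length, PULSE_WIDTH_S2)


def simulate_random(spec: SimulationSpec) -> CommunityPhenology:
    """Reproducible randomized community under the spec's rules.

    Randomized quantities (staggered_pulse pattern): peak positions
    uniform over the period; pulse supports uniform in
    [pulse_width/2, pulse_width] of the period; unequal amplitudes
    log-uniform in [0.1, 1]. Constant patterns randomize only the
    amplitudes. Identical seeds give identical communities.
    """
    rng = np.random.default_rng(spec.seed)
    grid = _grid(spec.grid_length)
    period = spec.grid_length - 1

    if spec.amplitudes == "equal":
        areas = np.ones(spec.S)
    else:
        areas = 10.0 ** rng.uniform(-1.0, 0.0, size=spec.S)

    if spec.pattern == "constant":
        curves = tuple(
            PhenologyCurve(f"sp{k + 1:02d}",
                           _normalize_area(np.ones(spec.grid_length), grid.times, a),
                           stage="smoothed")
            for k, a in enumerate(areas)
        )
        return CommunityPhenology(grid, curves)
    if spec.pattern == "constant_modulated":
        shape = 1.0 + 0.5 * np.sin(2.0 * np.pi * grid.times / period + rng.uniform(0, 2 * np.pi))
        curves = tuple(
            PhenologyCurve(f"sp{k + 1:02d}",
                           _normalize_area(shape.copy(), grid.times, a), stage="smoothed")
            for k, a in enumerate(areas)
        )
        return CommunityPhenology(grid, curves)

    peaks = rng.uniform(0.0, period, size=spec.S)
    supports = rng.uniform(0.5, 1.0, size=spec.S) * spec.pulse_width * period
    # keep every pulse's support inside the observation window
    peaks = np.clip(peaks, supports / 2.0, period - supports / 2.0)
    return _pulse_community(peaks, areas, spec.grid_length, spec.pulse_width, supports=supports)
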