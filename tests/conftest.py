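import numpy as np
import pytest

from phenodiv import CommunityPhenology, PhenologyCurve, TimeGrid


def make_community(curve_values, times=None, stage="smoothed", labels=None):
    """Build a community from a list of value sequences."""
    curve_values = [np.asarray(v, dtype=float) for v in curve_values]
    if times is None:
        times = np.arange(len(curve_values[0]), dtype=float)
    grid = TimeGrid(np.asarray(times, dtype=float))
    labels = labels or [f"sp{k + 1}" for k in range(len(curve_values))]
    curves = tuple(
        PhenologyCurve(lab, v, stage=stage) for lab, v in zip(labels, curve_values)
    )
    return CommunityPhenology(grid, curves)


@pytest.fixture
def step_communities():
    """Hand-constructed step-curve communities (S <= 4) with a shared grid.

    Step curves have closed-form trapezoidal integrals, so they double as
    oracle fixtures for both the overlap distance and the diversity chain.
    """
    n = 48
    t = np.arange(n, dtype=float)

    def block(lo, hi, height=1.0):
        v = np.zeros(n)
        v[lo:hi] = height
        return v

    comms = {
        "two_disjoint": make_community([block(0, 12), block(24, 36)], t),
        "two_constant": make_community([np.ones(n), 3 * np.ones(n)], t),
        "three_mixed": make_community(
            [block(0, 20, 2.0), block(10, 30, 1.0), block(28, 48, 0.5)], t
        ),
        "four_overlapping": make_community(
            [block(0, 16), block(8, 24, 1.5), block(16, 32, 0.75), block(24, 48, 2.0)], t
        ),
    }
    return comms


@pytest.fixture
def pulse_series():
    """A raw Madagascar-style series: seasonal activity pulses plus count noise."""
    rng = np.random.default_rng(7)
    n = 120
    t = np.arange(n, dtype=float)
    raw = np.zeros(n)
    for peak, width, amp in ((20, 6, 10.0), (60, 9, 6.0), (100, 5, 8.0)):
        raw += amp * np.exp(-0.5 * ((t - peak) / width) ** 2)
    raw += rng.poisson(1.0, n) * 0.5
    return PhenologyCurve("pulse", raw, stage="raw")
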