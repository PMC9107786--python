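import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenodiv import (
    IntensityWeights,
    OverlapDistanceMatrix,
    SimulationSpec,
    distance_matrix,
    pd,
    pd_profile,
    rao_factor,
    relative_intensities,
    simulate_random,
)

from conftest import make_community
from oracle import qpd_bf


def uniform_weights(S):
    return IntensityWeights(np.full(S, 1.0 / S))


def disjoint_matrix(S):
    return OverlapDistanceMatrix(1.0 - np.eye(S), tuple(f"s{i}" for i in range(S)))


def zero_matrix(S):
    return OverlapDistanceMatrix(np.zeros((S, S)), tuple(f"s{i}" for i in range(S)))


# ---------------------------------------------------------------------------
# relative intensities
# ---------------------------------------------------------------------------

def test_relative_intensities_examples():
    n = 41
    t = np.arange(n, dtype=float)
    equal = make_community([np.ones(n), np.full(n, 1.0)], t)
    np.testing.assert_allclose(relative_intensities(equal).p, [0.5, 0.5], atol=1e-15)

    scaled = make_community([np.full(n, 0.25), np.full(n, 0.75)], t)  # areas 10, 30
    np.testing.assert_allclose(relative_intensities(scaled).p, [0.25, 0.75], atol=1e-12)

    forty = make_community([np.ones(n)] * 40, t, labels=[f"s{k}" for k in range(40)])
    np.testing.assert_allclose(relative_intensities(forty).p, np.full(40, 0.025), atol=1e-12)


def test_zero_integral_species_rejected():
    comm = make_community([np.ones(20), np.zeros(20)])
    with pytest.raises(ValueError, match="dropped upstream"):
        relative_intensities(comm)


def test_weights_validation():
    with pytest.raises(ValueError):
        IntensityWeights(np.array([0.5, 0.0, 0.5]))
    with pytest.raises(ValueError):
        IntensityWeights(np.array([0.5, 0.6]))


# ---------------------------------------------------------------------------
# Rao factor Q
# ---------------------------------------------------------------------------

def test_rao_factor_closed_forms():
    assert rao_factor(disjoint_matrix(2), uniform_weights(2)) == pytest.approx(0.5, abs=1e-15)
    assert rao_factor(zero_matrix(5), uniform_weights(5)) == 0.0
    # S disjoint equal-weight species: Q = (S-1)/S
    assert rao_factor(disjoint_matrix(40), uniform_weights(40)) == pytest.approx(
        39 / 40, abs=1e-12
    )


def test_rao_factor_dimension_mismatch():
    with pytest.raises(ValueError, match="species"):
        rao_factor(disjoint_matrix(3), uniform_weights(4))


# ---------------------------------------------------------------------------
# qPD
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 1.5, 2.0])
@pytest.mark.parametrize("S", [2, 3, 40])
def test_disjoint_equal_weight_gives_S_at_every_order(S, q):
    assert pd(disjoint_matrix(S), uniform_weights(S), q) == pytest.approx(S, abs=1e-9)


@pytest.mark.parametrize("q", [0.0, 1.0, 2.0])
def test_identical_curves_give_zero(q):
    assert pd(zero_matrix(40), uniform_weights(40), q) == 0.0


def test_negative_order_rejected():
    with pytest.raises(ValueError, match="nonnegative"):
        pd(disjoint_matrix(2), uniform_weights(2), -0.5)


def test_matches_brute_force_oracle(step_communities):
    """Full-chain agreement with the explicit-loop reference on every
    hand-constructed step community, across orders."""
    for name, comm in step_communities.items():
        d = distance_matrix(comm)
        w = relative_intensities(comm)
        t = list(comm.grid.times)
        curves = [list(v) for v in comm.matrix()]
        for q in (0.0, 0.5, 1.0, 1.7, 2.0, 3.0):
            assert pd(d, w, q) == pytest.approx(qpd_bf(curves, t, q), rel=1e-9), (name, q)


def test_continuity_at_q_one(step_communities):
    for comm in step_communities.values():
        d = distance_matrix(comm)
        w = relative_intensities(comm)
        center = pd(d, w, 1.0)
        for q in (1.0 - 1e-4, 1.0 + 1e-4):
            assert abs(pd(d, w, q) - center) / center <= 1e-3


def test_common_rescaling_changes_nothing(step_communities):
    comm = step_communities["four_overlapping"]
    scaled = make_community([7.3 * v for v in comm.matrix()], comm.grid.times)
    stretched = make_community(comm.matrix(), comm.grid.times * 4.0)
    for variant in (scaled, stretched):
        for q in (0.0, 1.0, 2.0):
            ref = pd(distance_matrix(comm), relative_intensities(comm), q)
            got = pd(distance_matrix(variant), relative_intensities(variant), q)
            assert got == pytest.approx(ref, rel=1e-9)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def test_profile_flat_for_disjoint_equal_case():
    prof = pd_profile(disjoint_matrix(2), uniform_weights(2), 0.0, 2.0, 5)
    np.testing.assert_allclose(prof.pd_values, np.full(5, 2.0), atol=1e-9)
    assert prof.S == 2
    assert prof.Q == pytest.approx(0.5)


def test_profile_decreases_with_unequal_intensities():
    spec = SimulationSpec(S=12, grid_length=180, pulse_width=0.1, amplitudes="unequal", seed=4)
    comm = simulate_random(spec)
    d, w = distance_matrix(comm), relative_intensities(comm)
    prof = pd_profile(d, w, 0.0, 2.0, 21)
    assert prof.pd_values[-1] < prof.pd_values[0]
    diffs = np.diff(prof.pd_values)
    assert np.all(diffs <= 1e-9)


def test_profile_rejects_bad_range():
    with pytest.raises(ValueError):
        pd_profile(disjoint_matrix(2), uniform_weights(2), 1.0, 1.0, 5)


@given(seed=st.integers(0, 10_000), s=st.integers(2, 8), unequal=st.booleans())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_profile_monotone_on_random_communities(seed, s, unequal):
    """qPD is non-increasing in q on arbitrary pulse communities."""
    spec = SimulationSpec(
        S=s, grid_length=120, pulse_width=0.2,
        amplitudes="unequal" if unequal else "equal", seed=seed,
    )
    comm = simulate_random(spec)
    d, w = distance_matrix(comm), relative_intensities(comm)
    prof = pd_profile(d, w, 0.0, 2.0, 11)
    assert np.all(prof.pd_values >= 0)
    diffs = np.diff(prof.pd_values)
    assert np.all(diffs <= 1e-9 * max(1.0, prof.pd_values[0]))
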