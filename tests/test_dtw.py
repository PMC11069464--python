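"""Distance primitives: worked examples, oracle equality, bound sandwich."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as stv
from hypothesis.extra.numpy import arrays

from oracles import dtw_enumerate, dtw_full_dp
from somtimes import (
    compute_envelope,
    dtw_distance,
    euclidean_distance,
    lb_keogh,
    window_size,
)
from somtimes.exceptions import LengthMismatchError, ParameterError

series = arrays(
    float, stv.integers(2, 12),
    elements=stv.floats(-10, 10, allow_nan=False, allow_infinity=False),
)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2, 3], [1, 1, 2], math.sqrt(2)),
        ([0], [3], 3.0),
    ],
)
def test_euclidean_examples(a, b, expected):
    assert euclidean_distance(a, b) == pytest.approx(expected, abs=1e-12)


def test_euclidean_length_mismatch():
    with pytest.raises(LengthMismatchError):
        euclidean_distance([1, 2], [1, 2, 3])


@pytest.mark.parametrize(
    "m, fraction, expected",
    [(100, 0.05, 5), (10, 0.10, 1), (3, 0.05, 1), (60, 0.05, 3)],
)
def test_window_size(m, fraction, expected):
    assert window_size(m, fraction) == expected


@pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
def test_window_size_rejects_bad_fraction(fraction):
    with pytest.raises(ParameterError):
        window_size(10, fraction)


def test_envelope_windowed_extremes():
    env = compute_envelope([0, 2, 1, 3], 1)
    assert env.upper.tolist() == [2, 2, 3, 3]
    assert env.lower.tolist() == [0, 0, 1, 1]


def test_envelope_constant_series_zero_bandwidth():
    env = compute_envelope([5.0, 5.0, 5.0], 2)
    assert env.upper.tolist() == env.lower.tolist() == [5, 5, 5]


def test_envelope_full_window_is_global_extremes(rng):
    q = rng.normal(size=30)
    env = compute_envelope(q, 30)
    assert np.allclose(env.upper, q.max())
    assert np.allclose(env.lower, q.min())


def test_envelope_contains_source(rng):
    q = rng.normal(size=50)
    env = compute_envelope(q, 3)
    assert np.all(env.lower <= q) and np.all(q <= env.upper)


def test_envelope_rejects_zero_window():
    with pytest.raises(ParameterError):
        compute_envelope([1.0, 2.0], 0)


def test_lb_keogh_inside_band_is_zero(rng):
    q = rng.normal(size=40)
    env = compute_envelope(q, 4)
    inside = (env.upper + env.lower) / 2
    assert lb_keogh(inside, env) == 0.0


def test_lb_keogh_hand_example():
    env = compute_envelope([0, 2, 1, 3], 1)   # U=[2,2,3,3], L=[0,0,1,1]
    assert lb_keogh([0, 0, 0, 0], env) == pytest.approx(math.sqrt(2), abs=1e-12)


def test_lb_keogh_of_constant_envelope_equals_euclidean(rng):
    q = np.full(20, 2.5)
    t = rng.normal(size=20)
    env = compute_envelope(q, 2)
    assert lb_keogh(t, env) == pytest.approx(euclidean_distance(q, t), abs=1e-12)


@pytest.mark.parametrize(
    "q, c, w, expected",
    [
        ([4, 7, 1], [4, 7, 1], 1, 0.0),
        ([1, 2, 3], [1, 1, 2], 3, 1.0),
    ],
)
def test_dtw_examples(q, c, w, expected):
    assert dtw_distance(q, c, w) == pytest.approx(expected, abs=1e-12)


def test_dtw_beats_euclidean_on_shifted_ramp():
    # warping absorbs the one-step shift that Euclidean pays for
    assert dtw_distance([1, 2, 3], [1, 1, 2], 3) < euclidean_distance([1, 2, 3], [1, 1, 2])


def test_dtw_length_mismatch():
    with pytest.raises(LengthMismatchError):
        dtw_distance([1, 2], [1, 2, 3], 1)


def test_sandwich_property(rng):
    """LB_Keogh <= DTW <= Euclidean on random pairs sharing a window."""
    for _ in range(300):
        q, c = rng.normal(size=50), rng.normal(size=50)
        env = compute_envelope(q, 3)
        lb, d, ed = lb_keogh(c, env), dtw_distance(q, c, 3), euclidean_distance(q, c)
        assert lb <= d + 1e-12
        assert d <= ed + 1e-12


def test_dtw_monotone_in_window(rng):
    q, c = rng.normal(size=40), rng.normal(size=40)
    dists = [dtw_distance(q, c, w) for w in (1, 2, 5, 10, 40)]
    assert all(a >= b - 1e-12 for a, b in zip(dists, dists[1:]))


def test_dtw_full_window_equals_unconstrained(rng):
    q, c = rng.normal(size=20), rng.normal(size=20)
    assert dtw_distance(q, c, 20) == pytest.approx(dtw_full_dp(q, c, 20), abs=1e-12)


def test_dtw_matches_dp_and_enumeration_oracles(rng):
    for _ in range(100):
        m = int(rng.integers(2, 6))
        w = int(rng.integers(1, m + 1))
        q, c = rng.normal(size=m), rng.normal(size=m)
        d = dtw_distance(q, c, w)
        assert d == pytest.approx(dtw_full_dp(q, c, w), abs=1e-9)
        assert d == pytest.approx(dtw_enumerate(q, c, w), abs=1e-9)
    for m in (30, 100):
        q, c = rng.normal(size=m), rng.normal(size=m)
        w = max(1, m // 20)
        assert dtw_distance(q, c, w) == pytest.approx(dtw_full_dp(q, c, w), abs=1e-9)


@given(series)
def test_dtw_identity_is_zero(q):
    assert dtw_distance(q, q, max(1, q.size // 2)) == 0.0


@given(series, stv.integers(1, 12))
def test_dtw_symmetric(q, w):
    c = q[::-1].copy()
    assert dtw_distance(q, c, w) == pytest.approx(dtw_distance(c, q, w), abs=1e-9)
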