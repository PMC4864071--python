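"""Banded DTW against an exhaustive warp-path enumeration oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtwspec import DTWConfig, dtw_distance, dtw_path

# ---------------------------------------------------------------------------
# oracle: enumerate every monotone path from (0,0) to (n-1,m-1) inside the band


def _local(a, b, cost):
    d = a - b
    return d * d if cost == "squared" else abs(d)


def brute_force_dtw(x, y, window, cost="abs"):
    """Minimum summed local cost over all monotone banded paths (recursion)."""
    n, m = len(x), len(y)

    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], acc)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m and abs(ni - nj) <= window:
                walk(ni, nj, acc + _local(x[ni], y[nj], cost))

    if abs(0) > window:  # pragma: no cover - (0,0) always in band
        return np.inf
    walk(0, 0, _local(x[0], y[0], cost))
    return best[0]


def random_pair(rng, max_len=8):
    n = int(rng.integers(1, max_len + 1))
    m = int(rng.integers(1, max_len + 1))
    return rng.standard_normal(n), rng.standard_normal(m)


@pytest.mark.parametrize("cost", ["abs", "squared"])
def test_matches_exhaustive_enumeration(cost):
    """200 random short pairs: DP equals brute-force path minimum."""
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 200:
        x, y = random_pair(rng)
        window = int(rng.choice([0, 1, 2, 8]))
        if abs(len(x) - len(y)) > window:
            continue
        cfg = DTWConfig(window=window, local_cost=cost)
        expected = brute_force_dtw(x, y, window, cost)
        assert dtw_distance(x, y, cfg) == pytest.approx(expected, abs=1e-10)
        checked += 1


def test_path_cost_consistency():
    """Sum of local costs along the returned path equals the distance."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        x, y = random_pair(rng)
        window = int(rng.choice([1, 2, 8]))
        if abs(len(x) - len(y)) > window:
            continue
        cfg = DTWConfig(window=window)
        wp = dtw_path(x, y, cfg)
        path_cost = sum(abs(x[i] - y[j]) for i, j in wp.pairs)
        assert path_cost == pytest.approx(dtw_distance(x, y, cfg), abs=1e-10)
        # path structure: endpoints, monotone steps, band
        assert wp.pairs[0] == (0, 0) and wp.pairs[-1] == (len(x) - 1, len(y) - 1)
        for (i0, j0), (i1, j1) in itertools.pairwise(wp.pairs):
            assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}
            assert abs(i1 - j1) <= cfg.window


def test_identical_sequences_give_zero_and_diagonal():
    x = [1.0, 2.0, 3.0, 2.0]
    assert dtw_distance(x, x, DTWConfig(window=2)) == 0.0
    wp = dtw_path(x, x, DTWConfig(window=2))
    assert wp.pairs == [(0, 0), (1, 1), (2, 2), (3, 3)]


def test_two_point_band_one_example():
    # all three feasible paths of x=[0,0], y=[1,1] cost 2 with |x-y|=1 locals
    assert dtw_distance([0, 0], [1, 1], DTWConfig(window=1)) == pytest.approx(2.0)


@given(st.lists(st.floats(-50, 50), min_size=1, max_size=12))
@settings(max_examples=60, deadline=None)
def test_self_distance_zero(xs):
    assert dtw_distance(xs, xs, DTWConfig(window=3)) == 0.0


@given(
    st.lists(st.floats(-10, 10), min_size=4, max_size=10),
    st.lists(st.floats(-10, 10), min_size=4, max_size=10),
)
@settings(max_examples=60, deadline=None)
def test_symmetry_and_band_monotonicity(xs, ys):
    """d(x,y)=d(y,x); widening the band never increases the distance."""
    if abs(len(xs) - len(ys)) > 3:
        ys = ys[: len(xs)] if len(ys) > len(xs) else ys
        if abs(len(xs) - len(ys)) > 3:
            xs = xs[: len(ys) + 3]
    prev = np.inf
    for w in (3, 5, 20):
        cfg = DTWConfig(window=w)
        d = dtw_distance(xs, ys, cfg)
        assert d == pytest.approx(dtw_distance(ys, xs, cfg), abs=1e-9)
        assert d <= prev + 1e-9
        prev = d
    # window >= max(n, m) equals the unconstrained optimum
    big = dtw_distance(xs, ys, DTWConfig(window=max(len(xs), len(ys))))
    assert big == pytest.approx(dtw_distance(xs, ys, DTWConfig(window=1000)), abs=1e-9)


def test_window_zero_equal_length_is_pointwise_cost():
    rng = np.random.default_rng(3)
    x, y = rng.standard_normal(6), rng.standard_normal(6)
    assert dtw_distance(x, y, DTWConfig(window=0)) == pytest.approx(np.abs(x - y).sum())


def test_dtw_never_exceeds_diagonal_cost():
    rng = np.random.default_rng(4)
    for _ in range(20):
        x, y = rng.standard_normal(7), rng.standard_normal(7)
        assert dtw_distance(x, y, DTWConfig(window=4)) <= np.abs(x - y).sum() + 1e-12


def test_input_validation():
    with pytest.raises(ValueError, match="infeasible"):
        dtw_distance(np.zeros(5), np.zeros(1), DTWConfig(window=2))
    with pytest.raises(ValueError, match="empty"):
        dtw_distance([], [1.0], DTWConfig())
    with pytest.raises(ValueError, match="finite"):
        dtw_distance([np.nan, 1.0], [1.0, 2.0], DTWConfig())
    with pytest.raises(ValueError):
        DTWConfig(window=-1)
    with pytest.raises(ValueError):
        DTWConfig(local_cost="euclid")


def test_python_fallback_matches_jit():
    """The pure-python DP and the jitted DP are the same algorithm."""
    from dtwspec.dtw import _accumulate_py, accumulated_cost_matrix

    rng = np.random.default_rng(9)
    x, y = rng.standard_normal(9), rng.standard_normal(8)
    D_py = _accumulate_py(x, y, 3, False)
    D = accumulated_cost_matrix(x, y, DTWConfig(window=3))
    assert np.allclose(D_py, D, equal_nan=True)
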