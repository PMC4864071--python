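"""Exact dynamic-time-warping with a Sakoe-Chiba band.

The alignment cost between sequences ``x`` (length n) and ``y`` (length m) is
the minimum, over all monotone warp paths from (0, 0) to (n-1, m-1) whose
steps increment i, j or both by one, of the summed local costs
``d(x[i], y[j])``.  The Sakoe-Chiba band restricts paths to cells with
``|i - j| <= window``; cells outside the band are unreachable (+inf).  The
band both speeds up the dynamic program and bounds temporal distortion.

No slope weighting and no path-length normalization is applied by default:
within a fixed-length template bank the raw cumulative cost is directly
comparable across templates.  A normalized variant (cost / path length) is
available via ``normalize=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DTWConfig", "WarpPath", "dtw_distance", "dtw_path", "accumulated_cost_matrix"]

LOCAL_COSTS = ("abs", "squared")


@dataclass
class DTWConfig:
    """Banded-DTW parameters: band half-width (samples) and local cost."""

    window: int = 20
    local_cost: str = "abs"

    def __post_init__(self) -> None:
        self.window = int(self.window)
        if self.window < 0:
            raise ValueError("window must be nonnegative")
        if self.local_cost not in LOCAL_COSTS:
            raise ValueError(f"local_cost must be one of {LOCAL_COSTS}")


@dataclass
class WarpPath:
    """A monotone alignment path and its total cost."""

    pairs: list[tuple[int, int]]
    total_cost: float


def _check_inputs(x: np.ndarray, y: np.ndarray, cfg: DTWConfig) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sequence")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if abs(x.size - y.size) > cfg.window:
        raise ValueError(
            f"band infeasible: |len(x) - len(y)| = {abs(x.size - y.size)} "
            f"exceeds window {cfg.window}"
        )
    return x, y


def _accumulate_py(x: np.ndarray, y: np.ndarray, window: int, squared: bool) -> np.ndarray:
    n, m = x.size, y.size
    D = np.full((n, m), np.inf)
    for i in range(n):
        lo = max(0, i - window)
        hi = min(m - 1, i + window)
        xi = x[i]
        for j in range(lo, hi + 1):
            d = xi - y[j]
            c = d * d if squared else abs(d)
            if i == 0 and j == 0:
                best = 0.0
            else:
                best = np.inf
                if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                    best = D[i - 1, j - 1]
                if i > 0 and D[i - 1, j] < best:
                    best = D[i - 1, j]
                if j > 0 and D[i, j - 1] < best:
                    best = D[i, j - 1]
            D[i, j] = c + best
    return D

try:  # optional jit of the inner loop; semantics identical to the python path
    from numba import njit

    _accumulate_jit = njit(cache=True)(_accumulate_py)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _accumulate_jit = None

_warmed = False


def accumulated_cost_matrix(x, y, cfg: DTWConfig | None = None) -> np.ndarray:
    """Full banded accumulated-cost matrix; +inf outside the band."""
    cfg = cfg or DTWConfig()
    x, y = _check_inputs(x, y, cfg)
    squared = cfg.local_cost == "squared"
    global _warmed
    if _accumulate_jit is not None:
        _warmed = True
        return _accumulate_jit(x, y, cfg.window, squared)
    return _accumulate_py(x, y, cfg.window, squared)


def dtw_distance(x, y, cfg: DTWConfig | None = None, normalize: bool = False) -> float:
    """Minimum cumulative local cost over band-restricted monotone warp paths."""
    cfg = cfg or DTWConfig()
    D = accumulated_cost_matrix(x, y, cfg)
    dist = float(D[-1, -1])
    if normalize:
        dist /= len(dtw_path(x, y, cfg).pairs)
    return dist


def dtw_path(x, y, cfg: DTWConfig | None = None) -> WarpPath:
    """Optimal warp path by backtracking.

    Ties during backtracking are broken deterministically: diagonal first,
    then the i-decrement, then the j-decrement.
    """
    cfg = cfg or DTWConfig()
    D = accumulated_cost_matrix(x, y, cfg)
    n, m = D.shape
    i, j = n - 1, m - 1
    pairs = [(i, j)]
    while i > 0 or j > 0:
        cands: list[tuple[float, int, int]] = []
        if i > 0 and j > 0:
            cands.append((D[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            cands.append((D[i - 1, j], i - 1, j))
        if j > 0:
            cands.append((D[i, j - 1], i, j - 1))
        best = min(c[0] for c in cands)
        # first candidate attaining the minimum, in preference order
        _, i, j = next(c for c in cands if c[0] == best)
        pairs.append((i, j))
    pairs.reverse()
    return WarpPath(pairs=pairs, total_cost=float(D[-1, -1]))
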