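"""Distance primitives: Euclidean, windowed DTW, and the LB_Keogh bound.

Dynamic time warping (DTW) aligns two equal-length series under three
rules — every point matched at least once, endpoints matched to each
other, and no crossing (indices monotone) — and minimises the accumulated
pointwise cost over all such alignments.  A Sakoe–Chiba band restricts
matches to ``|i - j| <= W``.

The local cost is the *squared* difference and the returned distance is
the square root of the accumulated cost.  With that convention the three
quantities used for pruning nest cleanly for any pair sharing a window:

    LB_Keogh(t, env(q, W))  <=  DTW(q, t, W)  <=  Euclidean(q, t)

The upper bound holds because the diagonal alignment is always legal; the
lower bound is the classical envelope argument: any warped match of
``t_i`` lands inside ``[L_i, U_i]``, so each per-point penalty
under-counts the true cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .exceptions import LengthMismatchError, ParameterError
from .series import as_values

__all__ = [
    "Envelope",
    "euclidean_distance",
    "window_size",
    "compute_envelope",
    "lb_keogh",
    "dtw_distance",
]


@dataclass
class Envelope:
    """Running max/min band around a query series.

    ``upper[i] = max(q[i-W] .. q[i+W])`` and ``lower[i]`` the analogous
    min, window endpoints clipped at the series edges.  The source value
    always lies inside the band.
    """

    upper: np.ndarray
    lower: np.ndarray
    window: int

    def __len__(self) -> int:
        return self.upper.size


def euclidean_distance(a, b) -> float:
    """Pointwise (one-to-one alignment) distance — the DTW upper bound."""
    av, bv = as_values(a), as_values(b)
    if av.size != bv.size:
        raise LengthMismatchError(
            f"series lengths differ: {av.size} vs {bv.size}"
        )
    return float(np.sqrt(np.sum((av - bv) ** 2)))


def window_size(m: int, fraction: float) -> int:
    """Sakoe–Chiba half-width from a fraction of the series length.

    ``W = max(1, floor(fraction * m))``.  The default study setting is a
    5% window; the narrative stage uses 10% (one decile of ten).
    """
    if m < 1:
        raise ParameterError("series length must be >= 1")
    if not (0.0 < fraction <= 1.0):
        raise ParameterError("window fraction must lie in (0, 1]")
    return max(1, int(math.floor(fraction * m)))


def compute_envelope(q, window: int) -> Envelope:
    """LB_Keogh envelope of a query: running max/min over ``[i-W, i+W]``."""
    if window < 1:
        raise ParameterError("window must be >= 1")
    qv = as_values(q)
    size = 2 * window + 1
    # mode="nearest" pads with the edge value, which equals clipping the
    # window to valid indices (the edge value is already in the window).
    upper = maximum_filter1d(qv, size=size, mode="nearest")
    lower = minimum_filter1d(qv, size=size, mode="nearest")
    return Envelope(upper=upper, lower=lower, window=window)


def lb_keogh(t, env: Envelope) -> float:
    """Lower bound on windowed DTW between the envelope's query and ``t``.

    Sums squared excursions of the candidate outside the band (zero where
    it lies inside) and takes the square root.
    """
    tv = as_values(t)
    if tv.size != len(env):
        raise LengthMismatchError(
            f"candidate length {tv.size} does not match envelope length {len(env)}"
        )
    above = np.clip(tv - env.upper, 0.0, None)
    below = np.clip(env.lower - tv, 0.0, None)
    return float(np.sqrt(np.sum(above * above + below * below)))


@njit(cache=True)
def _dtw_band_sq(q: np.ndarray, c: np.ndarray, w: int) -> float:  # pragma: no cover
    """Banded DP over the accumulated squared cost; returns the final cell."""
    m = q.size
    inf = np.inf
    prev = np.full(m, inf)
    curr = np.full(m, inf)
    for i in range(m):
        lo = i - w
        if lo < 0:
            lo = 0
        hi = i + w
        if hi > m - 1:
            hi = m - 1
        for j in range(lo, hi + 1):
            d = q[i] - c[j]
            d = d * d
            if i == 0 and j == 0:
                best = 0.0
            else:
                best = inf
                if i > 0 and prev[j] < best:
                    best = prev[j]
                if j > 0 and curr[j - 1] < best:
                    best = curr[j - 1]
                if i > 0 and j > 0 and prev[j - 1] < best:
                    best = prev[j - 1]
            curr[j] = d + best
        for j in range(m):
            prev[j] = curr[j]
            curr[j] = inf
    return prev[m - 1]


def dtw_distance(q, c, window: int) -> float:
    """Windowed DTW distance (sqrt of minimal accumulated squared cost)."""
    qv, cv = as_values(q), as_values(c)
    if qv.size != cv.size:
        raise LengthMismatchError(
            f"series lengths differ: {qv.size} vs {cv.size}"
        )
    if window < 1:
        raise ParameterError("window must be >= 1")
    return float(np.sqrt(_dtw_band_sq(qv, cv, int(window))))
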