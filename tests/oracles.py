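"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: a full-matrix dynamic
program, a brute-force warping-path enumeration, and a least-squares
derivation of Savitzky-Golay convolution weights.
"""

from __future__ import annotations

import math

import numpy as np


def dtw_full_dp(q, c, w) -> float:
    """Full (m+1)x(m+1) dynamic program over squared costs, banded."""
    q = np.asarray(q, float)
    c = np.asarray(c, float)
    m = q.size
    acc = np.full((m + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(max(1, i - w), min(m, i + w) + 1):
            d = (q[i - 1] - c[j - 1]) ** 2
            acc[i, j] = d + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    return math.sqrt(acc[m, m])


def dtw_enumerate(q, c, w) -> float:
    """Exhaustive minimum over every legal warping path (tiny m only)."""
    q = np.asarray(q, float)
    c = np.asarray(c, float)
    m = q.size
    best = [np.inf]

    def walk(i, j, cost):
        cost += (q[i] - c[j]) ** 2
        if cost >= best[0]:
            return
        if i == m - 1 and j == m - 1:
            best[0] = cost
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < m and nj < m and abs(ni - nj) <= w:
                walk(ni, nj, cost)

    walk(0, 0, 0.0)
    return math.sqrt(best[0])


def savgol_weights(order: int, window: int) -> np.ndarray:
    """Central-point convolution weights from the design matrix.

    Fitting a degree-``order`` polynomial over positions -h..h by least
    squares and evaluating it at 0 is a linear map of the samples; its
    coefficients are the first row of (A^T A)^{-1} A^T.
    """
    h = window // 2
    x = np.arange(-h, h + 1, dtype=float)
    a = np.vander(x, order + 1, increasing=True)
    return np.linalg.pinv(a)[0]


def brute_best_match(query, candidates, w, dtw_fn=None):
    """Arg-min of DTW over all candidates, ties to the lowest index."""
    dtw_fn = dtw_fn or dtw_full_dp
    dists = [dtw_fn(query, c, w) for c in candidates]
    idx = int(np.argmin(dists))
    return idx, dists[idx]
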