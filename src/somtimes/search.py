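"""Bound-pruned best-match search.

The two-step pruning that both clustering engines share:

1. the Euclidean distance from the query to every candidate is an upper
   bound on its DTW distance; the minimum of these upper bounds is the
   *pruning threshold*;
2. any candidate whose LB_Keogh lower bound exceeds the threshold cannot
   be the nearest candidate and is excluded; full DTW runs only inside
   the surviving *qualification region*.

Pruning is exact: the candidate with the minimal Euclidean distance is
never pruned (its bound cannot exceed its own upper bound), every pruned
candidate has DTW strictly above the threshold, and the threshold is at
least the DTW of that surviving candidate — so the arg-min over survivors
equals the arg-min over all candidates, value and index alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dtw import compute_envelope, dtw_distance
from .exceptions import EmptyInputError, LengthMismatchError
from .series import as_values

__all__ = ["PruneStats", "BestMatch", "prune_threshold", "find_best_match"]


@dataclass
class PruneStats:
    """Bookkeeping of bound evaluations versus full DTW calls."""

    n_candidates: int = 0
    n_upper_bound_evals: int = 0
    n_lower_bound_evals: int = 0
    n_dtw_calls: int = 0
    n_pruned: int = 0

    @property
    def pruning_fraction(self) -> float:
        """Fraction of candidate comparisons whose DTW was avoided."""
        if self.n_candidates == 0:
            return 0.0
        return self.n_pruned / self.n_candidates

    def __iadd__(self, other: "PruneStats") -> "PruneStats":
        self.n_candidates += other.n_candidates
        self.n_upper_bound_evals += other.n_upper_bound_evals
        self.n_lower_bound_evals += other.n_lower_bound_evals
        self.n_dtw_calls += other.n_dtw_calls
        self.n_pruned += other.n_pruned
        return self

    def as_dict(self) -> dict:
        return {
            "n_candidates": self.n_candidates,
            "n_upper_bound_evals": self.n_upper_bound_evals,
            "n_lower_bound_evals": self.n_lower_bound_evals,
            "n_dtw_calls": self.n_dtw_calls,
            "n_pruned": self.n_pruned,
        }


@dataclass
class BestMatch:
    """Winning candidate of a search: minimal DTW, ties to the lowest index."""

    index: int
    distance: float
    stats: PruneStats = field(default_factory=PruneStats)


def _candidate_matrix(candidates) -> np.ndarray:
    if isinstance(candidates, np.ndarray) and candidates.ndim == 2:
        return candidates.astype(float, copy=False)
    rows = [as_values(c) for c in candidates]
    if not rows:
        raise EmptyInputError("candidate list is empty")
    m = rows[0].size
    if any(r.size != m for r in rows):
        raise LengthMismatchError("candidates must share one length")
    return np.stack(rows)


def prune_threshold(query, candidates) -> float:
    """Minimum Euclidean (upper-bound) distance from query to the candidates."""
    qv = as_values(query)
    cand = _candidate_matrix(candidates)
    if cand.shape[0] == 0:
        raise EmptyInputError("candidate list is empty")
    if cand.shape[1] != qv.size:
        raise LengthMismatchError("query and candidates must share one length")
    return float(np.min(np.sqrt(np.sum((cand - qv) ** 2, axis=1))))


def find_best_match(query, candidates, window: int, pruning: bool = True) -> BestMatch:
    """DTW nearest candidate to ``query``, with or without bound pruning.

    Both modes return the identical index and distance; they differ only
    in how many full DTW evaluations the search performs.  Candidates
    whose lower bound *equals* the threshold are kept (strictly-greater
    pruning test).
    """
    qv = as_values(query)
    cand = _candidate_matrix(candidates)
    k = cand.shape[0]
    if k == 0:
        raise EmptyInputError("candidate list is empty")
    if cand.shape[1] != qv.size:
        raise LengthMismatchError("query and candidates must share one length")
    if not np.all(np.isfinite(qv)) or not np.all(np.isfinite(cand)):
        raise ValueError("series contain non-finite values")

    stats = PruneStats(n_candidates=k)
    if pruning:
        diffs = cand - qv
        upper = np.sqrt(np.sum(diffs * diffs, axis=1))
        stats.n_upper_bound_evals = k
        threshold = float(upper.min())

        env = compute_envelope(qv, window)
        above = np.clip(cand - env.upper, 0.0, None)
        below = np.clip(env.lower - cand, 0.0, None)
        lower = np.sqrt(np.sum(above * above + below * below, axis=1))
        stats.n_lower_bound_evals = k

        survivors = np.flatnonzero(lower <= threshold)
    else:
        survivors = np.arange(k)

    best_index = -1
    best_distance = np.inf
    for idx in survivors:
        d = dtw_distance(qv, cand[idx], window)
        stats.n_dtw_calls += 1
        if d < best_distance:
            best_distance = d
            best_index = int(idx)
    stats.n_pruned = k - stats.n_dtw_calls
    return BestMatch(index=best_index, distance=best_distance, stats=stats)
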