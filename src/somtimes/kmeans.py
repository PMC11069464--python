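"""K-TimeS: K-means over time series with DTW assignment and bound pruning.

Assignment uses the same qualification-region search as the SOM: a
centroid is skipped when its LB_Keogh lower bound to the query exceeds
the minimum Euclidean upper bound over all centroids — such a centroid
cannot be the nearest.  Centroid update is the pointwise arithmetic mean
(valid since all series share one length); empty clusters are repaired
by re-seeding with the observation farthest from its own centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dtw import dtw_distance, window_size
from .exceptions import EmptyInputError, ParameterError
from .search import PruneStats, find_best_match
from .som import _dataset_matrix

__all__ = [
    "KMeansConfig",
    "KMeansResult",
    "init_centroids",
    "assign_step",
    "update_centroids",
    "cluster",
]


@dataclass
class KMeansConfig:
    k: int
    iterations: int = 10
    window_fraction: float = 0.05
    seed: int = 0
    pruning: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray          # shape (k, m)
    stats: list[PruneStats] = field(default_factory=list)
    n_iterations: int = 0


def init_centroids(dataset, k: int, seed: int) -> np.ndarray:
    """k distinct seeded dataset members as the starting centroids."""
    data = _dataset_matrix(dataset)
    n = data.shape[0]
    if k > n:
        raise ParameterError(f"k={k} exceeds dataset size n={n}")
    rng = np.random.default_rng(seed)
    picks = rng.choice(n, size=k, replace=False)
    return data[picks].copy()


def assign_step(dataset, centroids, window: int, pruning: bool = True):
    """Label each observation with its DTW-nearest centroid.

    Returns ``(labels, stats)``; labels are identical with pruning on or
    off, only the DTW call count differs.
    """
    data = _dataset_matrix(dataset)
    if data.shape[0] == 0:
        raise EmptyInputError("dataset is empty")
    centroids = np.asarray(centroids, dtype=float)
    stats = PruneStats()
    labels = np.empty(data.shape[0], dtype=int)
    for i, row in enumerate(data):
        best = find_best_match(row, centroids, window, pruning=pruning)
        labels[i] = best.index
        stats += best.stats
    return labels, stats


def update_centroids(dataset, labels, k: int, *, centroids=None, window: int | None = None):
    """Pointwise mean per cluster; re-seed empty clusters.

    An empty cluster takes the observation farthest from its currently
    assigned centroid (DTW when ``centroids`` and ``window`` are given,
    Euclidean otherwise), so exactly ``k`` centroids always come back.
    """
    data = _dataset_matrix(dataset)
    labels = np.asarray(labels, dtype=int)
    new = np.empty((k, data.shape[1]))
    empty = []
    for j in range(k):
        members = data[labels == j]
        if members.shape[0] == 0:
            empty.append(j)
        else:
            new[j] = members.mean(axis=0)
    if empty:
        if centroids is not None and window is not None:
            dists = np.array(
                [dtw_distance(data[i], centroids[labels[i]], window) for i in range(data.shape[0])]
            )
        else:
            ref = new[labels.clip(max=k - 1)]
            dists = np.sqrt(np.sum((data - ref) ** 2, axis=1))
        order = np.argsort(-dists)
        for rank, j in enumerate(empty):
            new[j] = data[order[rank]]
    return new


def cluster(dataset, config: KMeansConfig) -> KMeansResult:
    """Alternate assignment and update until labels stabilise or the
    iteration budget is spent."""
    data = _dataset_matrix(dataset)
    n, m = data.shape
    if config.k > n:
        raise ParameterError(f"k={config.k} exceeds dataset size n={n}")
    window = window_size(m, config.window_fraction)
    centroids = init_centroids(data, config.k, config.seed)
    stats_log: list[PruneStats] = []
    labels = None
    for it in range(config.iterations):
        new_labels, stats = assign_step(data, centroids, window, pruning=config.pruning)
        stats_log.append(stats)
        if labels is not None and np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        centroids = update_centroids(
            data, labels, config.k, centroids=centroids, window=window
        )
    return KMeansResult(
        labels=labels, centroids=centroids, stats=stats_log, n_iterations=len(stats_log)
    )
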