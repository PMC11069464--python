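"""High-level clustering runs with evaluation and pruning instrumentation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kmeans as km
from . import som
from .dtw import window_size
from .exceptions import ParameterError
from .metrics import MetricsReport, compute_indices
from .search import PruneStats
from .series import Dataset

__all__ = ["RunReport", "run_cluster"]


@dataclass
class RunReport:
    """Everything one clustering run produced.

    ``pruning_fraction`` is exactly ``1 - dtw_calls / candidate
    comparisons`` accumulated over all epochs/iterations of training.
    """

    algorithm: str
    config: dict
    labels: np.ndarray
    metrics: MetricsReport | None
    per_epoch_stats: list[PruneStats] = field(default_factory=list)

    @property
    def total_stats(self) -> PruneStats:
        total = PruneStats()
        for s in self.per_epoch_stats:
            total += s
        return total

    @property
    def total_dtw_calls(self) -> int:
        return self.total_stats.n_dtw_calls

    @property
    def pruning_fraction(self) -> float:
        return self.total_stats.pruning_fraction

    def as_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "config": self.config,
            "labels": [int(x) for x in self.labels],
            "metrics": self.metrics.as_dict() if self.metrics else None,
            "per_epoch_stats": [s.as_dict() for s in self.per_epoch_stats],
            "total_dtw_calls": self.total_dtw_calls,
            "pruning_fraction": self.pruning_fraction,
        }


def run_cluster(dataset: Dataset, algorithm: str, params: dict | None = None,
                seed: int = 0):
    """Dispatch a clustering run and evaluate it against file labels.

    ``algorithm`` is ``"som"`` or ``"kmeans"``.  ``params`` may carry
    ``k``, ``rows``/``cols``, ``epochs``, ``iterations``,
    ``window_fraction``, ``toroidal`` and ``pruning``.  Engines only ever
    see the value matrix; labels are used for the final evaluation.

    Returns ``(report, model)`` where ``model`` is the trained
    :class:`~somtimes.som.SOMGrid` or :class:`~somtimes.kmeans.KMeansResult`.
    """
    params = dict(params or {})
    try:
        if algorithm == "som":
            k = params.pop("k", None)
            if k is not None:
                params.setdefault("rows", 1)
                params.setdefault("cols", int(k))
            config = som.SOMConfig(seed=seed, **params)
            grid = som.train(dataset.values, config)
            w = window_size(dataset.length, config.window_fraction)
            labels = som.classify(grid, dataset.values, w, pruning=config.pruning)
            stats = [e.stats for e in grid.epoch_log]
            config_echo = {**config.__dict__}
            model = grid
        elif algorithm == "kmeans":
            config = km.KMeansConfig(seed=seed, **params)
            result = km.cluster(dataset.values, config)
            labels = result.labels
            stats = result.stats
            config_echo = {**config.__dict__}
            model = result
        else:
            raise ParameterError(f"unknown algorithm {algorithm!r}")
    except Exception as exc:
        raise type(exc)(f"[dataset {dataset.name or 'unnamed'}] {exc}") from exc

    metrics = None
    if dataset.labels is not None:
        metrics = compute_indices(dataset.labels, labels)
    report = RunReport(
        algorithm=algorithm,
        config=config_echo,
        labels=labels,
        metrics=metrics,
        per_epoch_stats=stats,
    )
    return report, model
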