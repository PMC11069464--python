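"""Containers for univariate, equal-length time series.

A :class:`TimeSeries` is one observation (the query ``Q`` of a similarity
search, or a candidate such as a SOM node weight vector).  A
:class:`Dataset` bundles ``n`` equal-length series with optional integer
class labels; labels are carried for *evaluation only* — the clustering
engines receive bare value matrices and never see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import EmptyInputError, LengthMismatchError


@dataclass
class TimeSeries:
    """One univariate observation.

    Parameters
    ----------
    values
        Ordered real values ``q_1 .. q_m`` (unitless), ``m >= 1``, all finite.
    id
        Opaque identifier.
    label
        Optional integer class, kept for evaluation.
    """

    values: np.ndarray
    id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("a time series must be a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series values must be finite")

    def __len__(self) -> int:
        return self.values.size


def as_values(series) -> np.ndarray:
    """Return the 1-D float array behind a TimeSeries or array-like."""
    if isinstance(series, TimeSeries):
        return series.values
    return np.asarray(series, dtype=float)


@dataclass
class Dataset:
    """``n`` equal-length series with optional labels.

    ``problem_size`` is the scaling covariate sum(|Q|_i) = n * m used when
    reporting how much work a clustering run represents.
    """

    values: np.ndarray                     # shape (n, m)
    ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None       # ints, evaluation only
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise EmptyInputError("dataset has no series")
        if not self.ids:
            self.ids = [str(i) for i in range(self.values.shape[0])]
        if len(self.ids) != self.values.shape[0]:
            raise LengthMismatchError("ids do not match number of series")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.size != self.values.shape[0]:
                raise LengthMismatchError("labels do not match number of series")

    @classmethod
    def from_series(cls, series: Iterable[TimeSeries], name: str = "") -> "Dataset":
        series = list(series)
        if not series:
            raise EmptyInputError("dataset has no series")
        m = len(series[0])
        if any(len(s) != m for s in series):
            raise LengthMismatchError("all series in a dataset must share one length")
        labels = None
        if all(s.label is not None for s in series):
            labels = np.array([s.label for s in series], dtype=int)
        return cls(
            values=np.stack([s.values for s in series]),
            ids=[s.id or str(i) for i, s in enumerate(series)],
            labels=labels,
            name=name,
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]

    @property
    def problem_size(self) -> int:
        return self.values.shape[0] * self.values.shape[1]

    def to_series(self) -> list[TimeSeries]:
        labels: Sequence = self.labels if self.labels is not None else [None] * self.n
        return [
            TimeSeries(self.values[i].copy(), id=self.ids[i], label=labels[i])
            for i in range(self.n)
        ]
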