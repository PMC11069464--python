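"""Seeded generators of labeled benchmark data.

Two kinds of inputs are emulated.  ``generate_dataset`` builds an
equal-length labeled time-series collection in the style of public
classification archives: each class is a smooth prototype shape, and
observations are monotonically time-warped, noised copies — exactly the
distortions dynamic time warping is meant to absorb.  ``make_token_corpus``
builds tagged-token conversation streams (future- versus past-oriented
speakers) for the narrative stage.

Defaults (3 classes x 20 series, length 60, warp 3 steps, noise sd 0.1)
give well-separated clusters: pairwise prototype DTW distance is large
against the noise scale, so a correct clusterer should recover the
labels nearly perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dtw import dtw_distance, window_size
from .exceptions import ParameterError
from .series import Dataset

__all__ = [
    "SynthSpec",
    "make_prototypes",
    "warp_series",
    "generate_dataset",
    "make_token_corpus",
]


@dataclass
class SynthSpec:
    """Generator settings; defaults are the package's reference conditions."""

    n_classes: int = 3
    per_class: int = 20
    length: int = 60
    warp_steps: int = 3
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.per_class < 1 or self.length < 1:
            raise ParameterError("n_classes, per_class and length must be >= 1")
        if not (0 <= self.warp_steps < self.length):
            raise ParameterError("warp_steps must lie in [0, length)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def n(self) -> int:
        return self.n_classes * self.per_class


def make_prototypes(n_classes: int, length: int) -> np.ndarray:
    """Distinct smooth class shapes, pairwise well separated under DTW.

    Class ``c`` is a unit-amplitude sinusoid with ``c + 1`` periods and a
    class-specific phase; differing frequencies keep shapes far apart
    even after windowed alignment.
    """
    if n_classes < 1:
        raise ParameterError("n_classes must be >= 1")
    t = np.arange(length) / length
    protos = np.empty((n_classes, length))
    for c in range(n_classes):
        protos[c] = np.sin(2.0 * np.pi * (c + 1) * t + c * np.pi / 4.0)
    return protos


def warp_series(series, warp_steps: int, seed: int) -> np.ndarray:
    """Random monotone re-indexing with displacement at most ``warp_steps``.

    Walks a pointer through the source series, randomly dwelling or
    skipping while never drifting more than ``warp_steps`` from the
    diagonal; endpoints map to endpoints.  Output length equals input
    length and source indices are non-decreasing.
    """
    values = np.asarray(series, dtype=float)
    m = values.size
    if not (0 <= warp_steps < m):
        raise ParameterError("warp_steps must lie in [0, length)")
    if warp_steps == 0:
        return values.copy()
    rng = np.random.default_rng(seed)
    idx = np.empty(m, dtype=int)
    p = 0
    for i in range(m):
        # candidate advances 0, 1 or 2 keeping |p - i| <= warp_steps
        step = rng.integers(0, 3)
        p = p + step
        p = min(max(p, i - warp_steps, 0), i + warp_steps, m - 1)
        idx[i] = p
    idx[-1] = m - 1
    return values[idx]


def generate_dataset(spec: SynthSpec) -> Dataset:
    """Labeled, shuffled dataset of warped + noised prototype copies."""
    rng = np.random.default_rng(spec.seed)
    protos = make_prototypes(spec.n_classes, spec.length)
    rows, labels, ids = [], [], []
    for c in range(spec.n_classes):
        for r in range(spec.per_class):
            warped = warp_series(protos[c], spec.warp_steps, seed=int(rng.integers(2**31)))
            rows.append(warped + rng.normal(0.0, spec.noise_sd, spec.length))
            labels.append(c)
            ids.append(f"c{c}_{r}")
    order = rng.permutation(spec.n)
    return Dataset(
        values=np.stack(rows)[order],
        ids=[ids[i] for i in order],
        labels=np.array(labels)[order],
        name=f"synthetic_{spec.n_classes}x{spec.per_class}_m{spec.length}",
    )


def prototype_separation(spec: SynthSpec) -> float:
    """Smallest pairwise windowed DTW distance between the prototypes."""
    protos = make_prototypes(spec.n_classes, spec.length)
    if spec.n_classes == 1:
        return 0.0
    w = window_size(spec.length, 0.05)
    return min(
        dtw_distance(protos[i], protos[j], w)
        for i in range(spec.n_classes)
        for j in range(i + 1, spec.n_classes)
    )


def make_token_corpus(
    n_per_group: int = 20,
    words: int = 600,
    p_future: tuple[float, float] = (0.8, 0.2),
    verb_rate: float = 0.15,
    seed: int = 0,
):
    """Synthetic tagged-token conversation streams in two temporal styles.

    Group 0 ("optimistic") tags its verbs future with probability
    ``p_future[0]``; group 1 with ``p_future[1]``.  Non-verb words carry
    the tag ``none``, and a sprinkle of ``present`` verbs is included so
    consumers must ignore them.  Returns ``(streams, labels)`` where each
    stream is a list of ``(position, tag)`` pairs.
    """
    rng = np.random.default_rng(seed)
    streams, labels = [], []
    for group, p in enumerate(p_future):
        for _ in range(n_per_group):
            tokens = []
            for pos in range(words):
                if rng.random() < verb_rate:
                    u = rng.random()
                    if u < 0.2:
                        tag = "present"
                    elif rng.random() < p:
                        tag = "future"
                    else:
                        tag = "past"
                else:
                    tag = "none"
                tokens.append((pos, tag))
            streams.append(tokens)
            labels.append(group)
    order = rng.permutation(len(streams))
    return [streams[i] for i in order], np.array(labels)[order]
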