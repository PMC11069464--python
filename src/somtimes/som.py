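"""SOMTimeS: a Kohonen self-organizing map over time series with DTW.

Each node of a 2-D mesh carries a weight vector that is itself a time
series of the data length.  Training repeats for a fixed number of
epochs: every observation (in a seeded, per-epoch shuffled order) finds
its best matching unit (BMU) by bound-pruned DTW search, then the BMU
and its mesh neighbourhood are pulled toward the observation.  Learning
rate and neighbourhood radius decay linearly over epochs.

Classification mode arranges exactly ``k`` nodes as a 1 x k mesh and
assigns each observation the flat index of its BMU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dtw import window_size
from .exceptions import EmptyInputError, ParameterError
from .search import PruneStats, find_best_match
from .series import Dataset, as_values

__all__ = [
    "SOMConfig",
    "SOMGrid",
    "EpochLog",
    "init_som",
    "decay_schedule",
    "update_weights",
    "train",
    "classify",
    "compute_umatrix",
    "save_grid",
    "load_grid",
    "classification_config",
]


@dataclass
class SOMConfig:
    """Mesh geometry and training schedule.

    ``radius`` defaults to ``max(rows, cols) / 2`` — half the mesh span —
    so early epochs order the whole map and late epochs fine-tune.
    """

    rows: int = 1
    cols: int = 1
    toroidal: bool = True
    epochs: int = 100
    learning_rate: float = 0.9
    radius: float | None = None
    window_fraction: float = 0.05
    seed: int = 0
    pruning: bool = True

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ParameterError("mesh must have at least one node")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ParameterError("initial learning rate must lie in (0, 1]")
        if self.radius is None:
            self.radius = max(self.rows, self.cols) / 2.0
        if self.radius <= 0:
            raise ParameterError("initial radius must be positive")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols


def classification_config(k: int, **kwargs) -> SOMConfig:
    """Config for classification mode: a mesh of exactly ``k`` nodes (1 x k)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    return SOMConfig(rows=1, cols=k, **kwargs)


@dataclass
class EpochLog:
    epoch: int
    learning_rate: float
    radius: float
    stats: PruneStats


@dataclass
class SOMGrid:
    """Trained (or initial) mesh state.

    ``weights`` has shape (rows, cols, m); ``epoch_log`` records the
    schedule and pruning counters of each completed epoch.
    """

    weights: np.ndarray
    toroidal: bool = True
    epoch_log: list[EpochLog] = field(default_factory=list)

    @property
    def rows(self) -> int:
        return self.weights.shape[0]

    @property
    def cols(self) -> int:
        return self.weights.shape[1]

    @property
    def length(self) -> int:
        return self.weights.shape[2]

    def flat_weights(self) -> np.ndarray:
        """(rows*cols, m) view; row-major flat node indexing."""
        return self.weights.reshape(-1, self.weights.shape[2])


def _dataset_matrix(dataset) -> np.ndarray:
    if isinstance(dataset, Dataset):
        return dataset.values
    if isinstance(dataset, np.ndarray) and dataset.ndim == 2:
        return dataset.astype(float, copy=False)
    rows = [as_values(s) for s in dataset]
    if not rows:
        raise EmptyInputError("dataset is empty")
    return np.stack(rows)


def init_som(config: SOMConfig, dataset) -> SOMGrid:
    """Seeded initialisation: every node weight is a copy of a dataset member.

    Nodes are drawn without replacement while the mesh is no larger than
    the dataset, keeping initial weights distinct.
    """
    data = _dataset_matrix(dataset)
    n = data.shape[0]
    if n == 0:
        raise EmptyInputError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    replace_draw = config.n_nodes > n
    picks = rng.choice(n, size=config.n_nodes, replace=replace_draw)
    weights = data[picks].reshape(config.rows, config.cols, data.shape[1]).copy()
    return SOMGrid(weights=weights, toroidal=config.toroidal)


def decay_schedule(epoch: int, config: SOMConfig) -> tuple[float, float]:
    """Linear decay of learning rate and radius over the epoch budget.

    ``alpha_t = alpha0 * (1 - t/E)`` and ``r_t = max(1, r0 * (1 - t/E))``.
    """
    if not (0 <= epoch < config.epochs):
        raise ParameterError(f"epoch {epoch} outside [0, {config.epochs})")
    frac = 1.0 - epoch / config.epochs
    return config.learning_rate * frac, max(1.0, config.radius * frac)


def _grid_distances(rows: int, cols: int, bmu: tuple[int, int], toroidal: bool) -> np.ndarray:
    br, bc = bmu
    dr = np.abs(np.arange(rows) - br)
    dc = np.abs(np.arange(cols) - bc)
    if toroidal:
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    return np.sqrt(dr[:, None] ** 2 + dc[None, :] ** 2)


def update_weights(
    grid: SOMGrid,
    bmu: tuple[int, int],
    query,
    learning_rate: float,
    radius: float,
) -> SOMGrid:
    """Pull nodes toward the query with a Gaussian neighbourhood kernel.

    Each weight point moves by ``lr * h(d) * (x_i - w_i)`` where
    ``h(d) = exp(-d^2 / (2 r^2))`` and ``d`` is the (toroidal) mesh
    distance to the BMU.  Updates the grid in place and returns it.
    """
    if not (0.0 <= learning_rate <= 1.0):
        raise ParameterError("learning rate must lie in [0, 1]")
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    if learning_rate == 0.0:
        return grid
    qv = as_values(query)
    d = _grid_distances(grid.rows, grid.cols, bmu, grid.toroidal)
    if radius == 0.0:
        h = (d == 0).astype(float)
    else:
        h = np.exp(-(d ** 2) / (2.0 * radius ** 2))
    grid.weights += learning_rate * h[:, :, None] * (qv[None, None, :] - grid.weights)
    return grid


def train(dataset, config: SOMConfig) -> SOMGrid:
    """Run the full training loop; reproducible for a fixed seed.

    The pruning flag changes only the amount of DTW work, never the BMU
    trajectory or the trained weights.
    """
    data = _dataset_matrix(dataset)
    n, m = data.shape
    grid = init_som(config, data)
    window = window_size(m, config.window_fraction)
    rng = np.random.default_rng([config.seed, 1])
    for epoch in range(config.epochs):
        lr, radius = decay_schedule(epoch, config)
        stats = PruneStats()
        for i in rng.permutation(n):
            best = find_best_match(data[i], grid.flat_weights(), window, pruning=config.pruning)
            stats += best.stats
            bmu = divmod(best.index, grid.cols)
            update_weights(grid, bmu, data[i], lr, radius)
        grid.epoch_log.append(EpochLog(epoch=epoch, learning_rate=lr, radius=radius, stats=stats))
    return grid


def classify(grid: SOMGrid, dataset, window: int, pruning: bool = True) -> np.ndarray:
    """Assign each observation the flat index of its BMU on a trained mesh."""
    data = _dataset_matrix(dataset)
    if data.shape[0] == 0:
        raise EmptyInputError("dataset is empty")
    flat = grid.flat_weights()
    return np.array(
        [find_best_match(row, flat, window, pruning=pruning).index for row in data],
        dtype=int,
    )


def compute_umatrix(grid: SOMGrid, window: int) -> np.ndarray:
    """Unified distance matrix: per node, mean DTW distance to mesh neighbours.

    Four-connected neighbours, wrapping on a toroidal mesh; a wrap that
    lands back on the node itself (degenerate 1-wide dimension) is skipped.
    """
    from .dtw import dtw_distance

    rows, cols = grid.rows, grid.cols
    out = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            dists = []
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nr, nc = r + dr, c + dc
                if grid.toroidal:
                    nr %= rows
                    nc %= cols
                elif not (0 <= nr < rows and 0 <= nc < cols):
                    continue
                if (nr, nc) == (r, c):
                    continue
                dists.append(dtw_distance(grid.weights[r, c], grid.weights[nr, nc], window))
            out[r, c] = float(np.mean(dists)) if dists else 0.0
    return out


def save_grid(grid: SOMGrid, path) -> None:
    """Write a trained model as a structured JSON text document."""
    doc = {
        "rows": grid.rows,
        "cols": grid.cols,
        "length": grid.length,
        "toroidal": grid.toroidal,
        "weights": grid.flat_weights().tolist(),
        "epoch_log": [
            {
                "epoch": e.epoch,
                "learning_rate": e.learning_rate,
                "radius": e.radius,
                **e.stats.as_dict(),
            }
            for e in grid.epoch_log
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_grid(path) -> SOMGrid:
    with open(path) as fh:
        doc = json.load(fh)
    weights = np.asarray(doc["weights"], dtype=float).reshape(
        doc["rows"], doc["cols"], doc["length"]
    )
    log = [
        EpochLog(
            epoch=e["epoch"],
            learning_rate=e["learning_rate"],
            radius=e["radius"],
            stats=PruneStats(
                n_candidates=e["n_candidates"],
                n_upper_bound_evals=e["n_upper_bound_evals"],
                n_lower_bound_evals=e["n_lower_bound_evals"],
                n_dtw_calls=e["n_dtw_calls"],
                n_pruned=e["n_pruned"],
            ),
        )
        for e in doc.get("epoch_log", [])
    ]
    return SOMGrid(weights=weights, toroidal=doc["toroidal"], epoch_log=log)
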