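"""SOM engine: initialisation, schedules, updates, training, U-matrix."""

import math

import numpy as np
import pytest

from somtimes import (
    SOMConfig,
    classification_config,
    classify,
    compute_indices,
    compute_umatrix,
    dtw_distance,
    train,
    window_size,
)
from somtimes.exceptions import EmptyInputError, ParameterError
from somtimes.som import decay_schedule, init_som, load_grid, save_grid, update_weights


def test_init_deterministic(rng):
    data = rng.normal(size=(10, 20))
    cfg = SOMConfig(rows=2, cols=3, seed=42)
    g1, g2 = init_som(cfg, data), init_som(cfg, data)
    assert np.array_equal(g1.weights, g2.weights)


def test_init_weights_are_dataset_members(rng):
    data = rng.normal(size=(10, 20))
    grid = init_som(SOMConfig(rows=2, cols=2, seed=1), data)
    for w in grid.flat_weights():
        assert any(np.array_equal(w, row) for row in data)


def test_classification_mode_mesh_is_1_by_k():
    cfg = classification_config(3)
    assert (cfg.rows, cfg.cols) == (1, 3)
    assert cfg.n_nodes == 3


def test_init_empty_dataset():
    with pytest.raises(EmptyInputError):
        init_som(SOMConfig(), np.empty((0, 5)))


def test_decay_schedule_endpoints():
    cfg = SOMConfig(rows=4, cols=4, epochs=100, learning_rate=0.9)
    assert decay_schedule(0, cfg) == (0.9, 2.0)
    lr, r = decay_schedule(99, cfg)
    assert lr == pytest.approx(0.9 / 100)
    assert r == 1.0     # clamped at the minimum radius


def test_decay_monotone():
    cfg = SOMConfig(rows=5, cols=5, epochs=50)
    pairs = [decay_schedule(t, cfg) for t in range(50)]
    assert all(a[0] >= b[0] and a[1] >= b[1] for a, b in zip(pairs, pairs[1:]))


def test_decay_epoch_out_of_range():
    cfg = SOMConfig(epochs=10)
    with pytest.raises(ParameterError):
        decay_schedule(10, cfg)


def test_update_zero_lr_is_noop(rng):
    data = rng.normal(size=(5, 8))
    grid = init_som(SOMConfig(rows=2, cols=2, seed=0), data)
    before = grid.weights.copy()
    update_weights(grid, (0, 0), rng.normal(size=8), 0.0, 1.0)
    assert np.array_equal(grid.weights, before)


def test_update_full_overwrite_at_bmu(rng):
    data = rng.normal(size=(5, 8))
    grid = init_som(SOMConfig(rows=2, cols=2, seed=0), data)
    query = rng.normal(size=8)
    update_weights(grid, (1, 0), query, 1.0, 0.0)
    assert np.allclose(grid.weights[1, 0], query)


def test_update_gaussian_kernel_at_distance_one(rng):
    data = rng.normal(size=(4, 6))
    grid = init_som(SOMConfig(rows=1, cols=4, toroidal=False, seed=0), data)
    query = rng.normal(size=6)
    w_before = grid.weights[0, 1].copy()
    update_weights(grid, (0, 0), query, 0.5, 1.0)
    expected = w_before + 0.5 * math.exp(-0.5) * (query - w_before)
    assert np.allclose(grid.weights[0, 1], expected)


def test_train_single_series_fixed_point(rng):
    s = rng.normal(size=20)
    grid = train(s[None, :], SOMConfig(rows=1, cols=1, epochs=100, seed=0))
    assert np.allclose(grid.weights[0, 0], s, atol=1e-6)


def test_train_two_separated_levels_recovers_labels():
    data = np.vstack([np.zeros((10, 20)), np.full((10, 20), 10.0)])
    truth = np.repeat([0, 1], 10)
    cfg = SOMConfig(rows=1, cols=2, epochs=50, seed=3)
    grid = train(data, cfg)
    w = window_size(20, cfg.window_fraction)
    # with the radius floored at 1 the two nodes remain coupled (kernel
    # e^{-1/2}), so weights settle at mixtures on either side of the
    # midpoint rather than at the class means themselves
    levels = np.sort(grid.flat_weights()[:, 0])
    assert levels[0] < 5.0 < levels[1]
    labels = classify(grid, data, w)
    assert compute_indices(truth, labels).ari == pytest.approx(1.0)


def test_train_pruning_invariance(default_dataset):
    """The headline property: pruning never changes the trained map."""
    base = dict(rows=1, cols=3, epochs=10, seed=11)
    g_on = train(default_dataset.values, SOMConfig(pruning=True, **base))
    g_off = train(default_dataset.values, SOMConfig(pruning=False, **base))
    assert np.array_equal(g_on.weights, g_off.weights)
    w = window_size(default_dataset.length, 0.05)
    assert np.array_equal(
        classify(g_on, default_dataset.values, w),
        classify(g_off, default_dataset.values, w),
    )
    calls_on = sum(e.stats.n_dtw_calls for e in g_on.epoch_log)
    calls_off = sum(e.stats.n_dtw_calls for e in g_off.epoch_log)
    assert calls_on <= calls_off


def test_train_weights_stay_in_data_range(default_dataset):
    data = default_dataset.values
    grid = train(data, SOMConfig(rows=2, cols=2, epochs=10, seed=5))
    lo, hi = data.min(), data.max()
    assert grid.weights.min() >= lo - 1e-9
    assert grid.weights.max() <= hi + 1e-9


def test_epoch_log_conservation(default_dataset):
    grid = train(default_dataset.values, SOMConfig(rows=1, cols=3, epochs=5, seed=2))
    n, nodes = default_dataset.n, 3
    assert len(grid.epoch_log) == 5
    for e in grid.epoch_log:
        s = e.stats
        assert s.n_candidates == n * nodes
        assert s.n_pruned + s.n_dtw_calls == s.n_candidates


def test_umatrix_identical_weights_all_zero():
    grid = train(np.ones((4, 10)), SOMConfig(rows=2, cols=2, epochs=2, seed=0))
    grid.weights[:] = 1.0
    assert np.all(compute_umatrix(grid, 1) == 0.0)


def test_umatrix_two_nodes_equal_their_distance(rng):
    data = rng.normal(size=(6, 15))
    grid = init_som(SOMConfig(rows=1, cols=2, seed=4), data)
    um = compute_umatrix(grid, 2)
    d = dtw_distance(grid.weights[0, 0], grid.weights[0, 1], 2)
    assert np.allclose(um, d)


def test_umatrix_2x2_matches_direct_average(rng):
    data = rng.normal(size=(8, 12))
    grid = init_som(SOMConfig(rows=2, cols=2, toroidal=False, seed=9), data)
    um = compute_umatrix(grid, 2)
    w = grid.weights
    expected00 = np.mean([dtw_distance(w[0, 0], w[1, 0], 2),
                          dtw_distance(w[0, 0], w[0, 1], 2)])
    assert um[0, 0] == pytest.approx(expected00, abs=1e-12)


def test_classify_node_weights_map_to_themselves(rng):
    data = rng.normal(size=(5, 12))
    grid = init_som(SOMConfig(rows=1, cols=5, seed=0), data)
    labels = classify(grid, grid.flat_weights(), 1)
    assert labels.tolist() == [0, 1, 2, 3, 4]


def test_classify_invariant_to_pruning(default_dataset):
    grid = train(default_dataset.values, SOMConfig(rows=1, cols=3, epochs=5, seed=8))
    w = window_size(default_dataset.length, 0.05)
    assert np.array_equal(
        classify(grid, default_dataset.values, w, pruning=True),
        classify(grid, default_dataset.values, w, pruning=False),
    )


def test_grid_save_load_roundtrip(tmp_path, default_dataset):
    grid = train(default_dataset.values, SOMConfig(rows=1, cols=3, epochs=3, seed=1))
    path = tmp_path / "model.json"
    save_grid(grid, path)
    loaded = load_grid(path)
    assert np.array_equal(loaded.weights, grid.weights)
    assert loaded.toroidal == grid.toroidal
    assert len(loaded.epoch_log) == 3
    assert loaded.epoch_log[2].stats.n_dtw_calls == grid.epoch_log[2].stats.n_dtw_calls
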