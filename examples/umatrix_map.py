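"""Train a 4 x 4 visualization mesh and print its unified distance matrix.

High U-matrix values mark boundaries between clusters of nodes; the
per-epoch DTW call counts show the workload falling as the map organizes.
"""

import numpy as np

from somtimes import SOMConfig, SynthSpec, compute_umatrix, generate_dataset, train, window_size

dataset = generate_dataset(SynthSpec(seed=0))
config = SOMConfig(rows=4, cols=4, epochs=100, seed=0)
grid = train(dataset.values, config)

w = window_size(dataset.length, config.window_fraction)
um = compute_umatrix(grid, w)
print("U-matrix (mean DTW distance to mesh neighbours):")
for row in um:
    print("  " + "  ".join(f"{v:5.2f}" for v in row))

calls = np.array([e.stats.n_dtw_calls for e in grid.epoch_log], float)
print(f"DTW calls/epoch: first quartile {calls[:25].mean():.0f}, "
      f"last quartile {calls[75:].mean():.0f}")
# Large entries separate node neighbourhoods that encode different shape
# classes; the falling call count is the organizing map entering the
# fine-tuning phase where bounds prune most candidates.
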