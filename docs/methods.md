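# Methods

## Distance model

All series are equal-length, univariate and taken as-is (archive-style
inputs ship z-normalized; no normalization is applied internally).
Windowed DTW uses the three classical alignment rules (every point
matched at least once, endpoints anchored, monotone non-crossing
indices) and a Sakoe–Chiba band `|i − j| ≤ W`. The local cost is the
*squared* difference and the reported distance is the square root of the
minimal accumulated cost. That convention is not cosmetic: it is what
makes the three pruning quantities commensurate, since the upper bound
is root-sum-square Euclidean and LB_Keogh takes a square root of summed
squared excursions. With absolute-value local costs the sandwich
`LB_Keogh ≤ DTW ≤ ED` would not hold as stated.

`W` is derived from a fraction of the series length as
`max(1, floor(fraction·m))`; the default fraction is 0.05 (the
well-established setting for archive benchmarks), and the narrative
stage uses 0.10 — one decile of warping freedom on a ten-point arc.
Envelope windows are clipped at the series edges; the envelope is built
with running max/min filters (`scipy.ndimage`, edge-replicating mode,
which equals clipping because the edge value is inside every clipped
window). The banded dynamic program is numba-compiled; an independent
pure-Python full-matrix DP and an exhaustive path enumeration live in
the test suite as oracles.

## Pruned search

For a query against `M` candidates: compute all `M` Euclidean upper
bounds, set the threshold to their minimum, compute all `M` LB_Keogh
lower bounds from the query's envelope, and run DTW only where
`LB ≤ threshold` (candidates *equal* to the threshold are kept, so the
minimum-ED candidate always survives). Ties in the final arg-min go to
the lowest candidate index. The search is provably exact: every pruned
candidate has `DTW ≥ LB > threshold ≥ ED(best) ≥ DTW(best)`, strictly
above the returned distance, so neither winner nor tie-break can differ
from brute force. `PruneStats` counters satisfy
`n_pruned + n_dtw_calls = n_candidates` at every level of aggregation,
and the reported pruning fraction is exactly
`1 − DTW calls / candidate comparisons`.

DTW is always computed for survivors, even a sole survivor (its ED would
not generally equal its DTW).

## SOM engine

Node weights are initialised as copies of seeded dataset members —
without replacement while the mesh is no larger than the dataset, so
classification-mode nodes start distinct; this also keeps weights in the
data range and makes envelope windows meaningful from epoch 0. Each
epoch visits the observations in a seeded shuffled order, finds the BMU
by pruned search, and updates every node by
`w ← w + α_t · h(d) · (x − w)` with `h(d) = exp(−d²/2r_t²)`, `d` the
(optionally toroidal) mesh Euclidean distance to the BMU. Schedules are
linear: `α_t = α₀(1 − t/E)`, `r_t = max(1, r₀(1 − t/E))`, defaults
`α₀ = 0.9`, `r₀ = max(rows, cols)/2`, `E = 100` epochs, no early
stopping. Toroidal topology is the default. Every update is a convex
combination, so weights remain inside the data/initial-weight range per
time step.

Two consequences of the radius floor at 1 are worth knowing. On a
two-node mesh the nodes remain coupled with kernel `e^{−1/2}` forever,
so their weights settle at mixtures on either side of the between-class
midpoint rather than at the class means; classification is nevertheless
exact for separated classes because the ordering survives. And on a
`k`-node classification mesh the per-epoch DTW workload stays roughly
flat — the organizing-driven decline in DTW calls (more candidates
pruned as nodes specialise) appears on meshes larger than `k`, which is
where it is measured (4×4 in the acceptance checks).

Classification mode lays `k` nodes as a `1 × k` mesh and labels each
observation with its BMU's flat index. The U-matrix assigns each node
the mean DTW distance to its 4-connected mesh neighbours (wrapping when
toroidal; a wrap landing on the node itself is skipped). Trained models
round-trip through a JSON text document.

## K-means engine

Assignment is the identical pruned search over the `k` centroids.
Centroids initialise as `k` distinct seeded members and update as the
pointwise arithmetic mean of their cluster (valid since lengths agree;
DBA-style barycentres were deliberately not used — the mean keeps
iterations cheap and deterministic). An emptied cluster is re-seeded
with the observation farthest (DTW) from its currently assigned
centroid. Iteration stops at the budget (default 10) or as soon as two
consecutive labelings coincide. As a local-search method without
restarts, K-means occasionally converges to a merged-cluster optimum on
an unlucky seed; the SOM, whose neighbourhood kernel orders the map
before specialising it, is empirically more stable on the reference
conditions.

## Agreement indices

All six indices are computed from the contingency table: Rand index and
Fowlkes–Mallows from pair counts, ARI in the Hubert–Arabie adjusted
form, homogeneity/completeness as `MI/H(truth)` and `MI/H(pred)`
(defined as 1 when the corresponding entropy is zero), and AMI with the
`max(H(U), H(V))` normalizer using the exact hypergeometric expected
mutual information (log-gamma arithmetic). ARI/AMI return 1 when the
adjustment denominator vanishes. A single observation raises a
degenerate-input error. The test suite checks all six against
scikit-learn to 1e-9 on random labelings.

## Synthetic generator

The generator defines the package's reference study conditions: 3
classes × 20 series, length 60, warp 3 steps, noise SD 0.1 (seeded).
Prototypes are unit sinusoids with class-specific frequency and phase,
so pairwise windowed DTW separation far exceeds the noise scale
(checked: minimum prototype DTW > 5·noise_sd·√m). Observations are
monotone random re-indexings of the prototype — a pointer walk whose
displacement from the diagonal never exceeds `warp_steps`, directly
exercising the alignment rules — plus i.i.d. Gaussian noise. The token
corpus generator emulates two discourse styles by the probability that
a verb is future- versus past-tagged (0.8 vs 0.2), with present and
non-verb tokens mixed in.

What the generator does *not* emulate: real archives' heterogeneous
lengths, class imbalance, autocorrelated noise, and amplitude drift.
Passing the recovery checks therefore demonstrates correctness of the
machinery on separable, idealised data, not expected accuracy on real
archives.

## Narrative stage

Decile `d` of a conversation with `T` words covers positions
`[floor(dT/10), floor((d+1)T/10))`; its value is
`future / (future + past)` among the tagged verbs it contains. Present
and non-verb tokens never affect the arc. A decile with no past or
future verb takes the neutral value 0.5 — the decision threshold between
future- and past-dominated talk — so every surviving conversation yields
a complete arc; conversations below a configurable word minimum are
dropped (duration is expressed in words because transcripts carry no
timestamps). Smoothing is 2nd-order, 9-point Savitzky–Golay; boundary
points are evaluated from the polynomial fitted on the nearest full
window (no invented padding), which is `scipy.signal.savgol_filter`'s
interpolation mode. The smoother is linear; values are clamped to
[0, 1] only at the corpus-build step, after smoothing.

## Problem sizes and determinism

Default runs in the tests and acceptance script use the reference
conditions (60 series of length 60; 100-epoch SOMs; 5 seeds), sizes at
which every end-to-end property — pruning exactness, recovery,
epoch-wise workload decline — is measured in seconds. All randomness
flows through `numpy.random.default_rng` seeded from the run seed;
identical seeds give bitwise-identical datasets, training trajectories
and label files, with or without pruning.
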