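# Methods

## The model

`becseg` treats binary segmentation as pixel classification with a
precomputed-kernel support-vector machine. The similarity function is the
Bose–Einstein occupation number applied to a shifted distance between
feature vectors,

    G(x1, x2) = 1 / (exp(a / (kb · T)) − 1),

with `kb = 1.38` (the mantissa of the Boltzmann constant
`k_B = 1.3806488e−23 J/K`; only the product `kb · T` matters, which the test
suite asserts as a scale law). The argument `a` has two readings:

* **literal** (default): `a = ‖x1 − x2 − μ·1‖` — the formula at face value.
  Asymmetric in its inputs whenever `μ ≠ 0`, since `|d − μ| ≠ |−d − μ|`.
* **symmetric_distance**: `a = | ‖x1 − x2‖ − μ |` — symmetric by
  construction.

For `T > 0`, `μ = 0` the kernel is positive and strictly decreasing in the
distance — a heavy-tailed analogue of a radial basis function. For `T < 0`
the denominator lies in `(−1, 0)` and every off-singularity value is `≤ −1`.
A Gaussian baseline `exp(−a²/(2σ²))`, default `σ = 0.125`, runs through the
identical pipeline for comparisons. (The Gaussian is implemented with the
standard negative exponent and the shift outside the square; variants that
move `μ` inside the norm or drop the sign are not supported.)

## Handling the kernel's pathologies

**Singularity.** At `a = 0` the denominator `exp(0) − 1` vanishes. Any
denominator with `|d| < denom_floor` (default `1e−8`) is replaced by
`±denom_floor` with its sign preserved (`+` for an exact zero), and the
kernel value is clamped to `[−kernel_cap, +kernel_cap]` (default `1e6`).
This keeps "most similar at smallest argument" ordering without infinities.
Note that with `μ ≠ 0` the Gram *diagonal* is not singular (its argument is
`μ`); the capped entries instead appear wherever two features differ by
almost exactly `μ`.

**Asymmetry.** The default pathway symmetrizes the training Gram,
`(K + Kᵀ)/2`. For the rectangular train-vs-all cross-Gram the equivalent
pairwise form `(k(x, y) + k(y, x))/2` is used, so train and test
similarities come from one and the same symmetric kernel.

**Indefiniteness.** The symmetrized Gram is generally indefinite. Before
training, its eigenvalues are clipped at zero (`psd_project`, the nearest
PSD matrix in Frobenius norm). Prediction then filters the cross-Gram
through the projector `V₊V₊ᵀ` onto the training Gram's positive eigenspace —
the Nyström-consistent way to place test points in the same repaired
geometry the classifier was fit in. This filter matters: with the clipped
training Gram but *raw* cross similarities, predictions on the noisy phantom
collapse (F ≈ 0.14 at `(T, μ) = (6, 3)` versus 0.95 with the filter),
because the capped similarity spikes that the projection removes from the
training geometry reappear at test time. Skipping the projection entirely
(for indefinite-tolerant solvers) is available via
`SegmenterConfig(psd_project=False)` but performs worse on noisy images
(F ≈ 0.31 on the same fixture). Eigenvalue *flipping* (taking absolute
values) behaves similarly to clipping here and is not exposed.

## The segmentation pipeline

1. **Rescale** intensities affinely to `(0, 10)`. This makes pixel-intensity
   differences commensurate with chemical potentials of a few units and
   renders the pipeline invariant (up to float round-off) to affine
   intensity changes of the raw image. Constant images map to the low end.
2. **Flatten** row-major into an `(m·n, 1)` table of scalar intensity
   features. Coordinates are deliberately not included: the kernel is meant
   to act on intensity differences alone.
3. **Seed labels.** The classifier needs training labels that no external
   annotation provides, so weak labels are bootstrapped from the intensity
   histogram: Otsu's between-class-variance threshold over 256 bins
   (default) or 2-means on intensities; label 1 is the brighter side.
4. **Fit and predict.** A class-stratified subsample of at most
   `max_train_pixels` (default 2000) pixels is drawn with a seeded
   generator; the O(n²) Gram and its eigendecomposition stay cheap at that
   size while the subsample preserves class balance. `sklearn.svm.SVC` with
   `kernel="precomputed"` and cost `C = 1` is trained on the repaired Gram;
   all pixels are classified through the filtered cross-Gram. SMO iterations
   are capped at `svm_max_iter = 100 000`: healthy cells converge in tens to
   a few thousand iterations, while a few ill-posed `(T, μ)` combinations
   (negative `T` with small positive `μ`) otherwise stall the solver for
   minutes without improving the fit.
5. **Reshape** predictions to a 0/1 mask, 1 = target region.

Everything downstream of the seed is deterministic given `rng_seed`
(default 42): reruns produce bit-identical masks.

## Evaluation and the hyperparameter sweep

Precision `tp/(tp+fp)`, recall `tp/(tp+fn)` and `F = 2PR/(P+R)` are computed
from pixel-wise confusion counts; zero denominators yield 0 by convention
(synthetic fixtures never hit them). Values stay at full precision
internally; table display rounds to 4 decimals half-up.

The sweep evaluates every cell of a `T × μ` grid (default integers −10..10,
`T ≠ 0`; `μ = 6.7` can be appended as the upper end of the suggested
chemical-potential range) with the same RNG seed per cell, so cells differ
only through the kernel parameters. Failed cells are recorded with their
error and excluded from selection. "Best" is the max-F cell; ties break by
higher precision, then smaller `|T|`, then smaller `|μ|`, then canonical
(T-major) grid order — a deliberately explicit cascade, since max-F alone is
ambiguous and selection must be invariant to row order. The empirical
near-symmetry of results under `μ → −μ` is reported as a diagnostic
(`mu_symmetry_gap`), never asserted.

## Synthetic data

`make_phantom` renders a bright core (intensity 9) inside an enhancing
annulus (6) on a dark background (1), with Euclidean-distance region
membership at half-integer pixel centers, optional Gaussian pixel noise
added after region assignment and clipped to `(0, 10)`. Ground truth is
core ∪ ring (a flag restricts it to the core). Default geometry: 128×128,
radii 12/18/26. The test-suite presets are `noisy` (sd 0.3, seed 42) and
`small-noisy` (64×64, radii 6/9/13, sd 0.3, seed 42); the small phantom with
a 600-pixel training cap is used wherever dozens of segmentations run (the
84-cell sweep), keeping each cell well under a second without changing the
qualitative picture. `make_node_cloud` and `make_iris_like` draw labeled
Gaussian point clouds (the iris-like class means/spreads are fixed synthetic
constants, not the measured Fisher data).

What the phantoms do not emulate: MRI bias fields, partial-volume effects,
texture, multi-modality, anatomical background structure. Passing the
phantom suite shows the kernel pipeline is implemented correctly and is
robust to additive Gaussian noise at the stated level — not that the method
reaches any particular accuracy on clinical images.

## Known limitations and choices left open

* Scalar intensity features mean the classifier is (up to subsampling) a
  function of pixel intensity alone; spatial regularity comes only from the
  image's own structure.
* With `μ = 0` on the default pathway the Gram diagonal is entirely capped
  at `kernel_cap`; such cells behave poorly (low recall) and simply score
  badly in the sweep rather than being excluded.
* `T` is tested over both signs. Negative-temperature Grams are negative
  matrices whose repaired spectrum discards most structure; they are kept
  for completeness of the sweep protocol.
* How training labels would arise on real annotated images (per-image
  manual seeds vs. the unsupervised bootstrap used here) is an open design
  point; the config accepts any externally supplied seed labels through
  `fit_predict`.
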