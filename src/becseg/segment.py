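"""The five-step segmentation pipeline.

1. take a grayscale image and rescale its intensities to a working range,
2. flatten the pixels into a one-dimensional feature table,
3. bootstrap weak foreground/background labels (Otsu threshold or 2-means),
4. train a precomputed-kernel SVM on a stratified pixel subsample using the
   BEC (or Gaussian) kernel and predict every pixel,
5. reshape the 0/1 predictions back into a mask (1 = target region).

The kernel pathway follows the kernel module's defaults: literal argument,
matrix symmetrization of the training Gram, eigenvalue clipping to PSD.  The
train-vs-all cross-Gram uses the same pairwise-symmetrized kernel, filtered
through the training Gram's positive-eigenspace projector so that test
similarities live in the same repaired geometry the classifier was fit in
(without this, the clipped spectrum and the raw cross similarities disagree
and predictions degrade sharply on noisy images).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from becseg.kernel import (
    FeatureTable,
    GaussianParams,
    KernelParams,
    as_feature_table,
    pairwise_kernel,
)

__all__ = [
    "SegmenterConfig",
    "SegmentationResult",
    "rescale",
    "flatten",
    "seed_labels",
    "fit_predict",
    "segment",
]


@dataclass(frozen=True)
class SegmenterConfig:
    """Pipeline knobs the kernel itself does not define.

    ``intensity_target_range`` (default (0, 10)) puts pixel differences on the
    scale where chemical potentials of a few units are informative.
    ``max_train_pixels`` caps the training Gram at a size whose O(n^2)
    construction and eigendecomposition stay cheap; the stratified subsample
    preserves the seed-label class balance.
    """

    intensity_target_range: tuple[float, float] = (0.0, 10.0)
    seed_method: str = "otsu"
    max_train_pixels: int = 2000
    svm_c: float = 1.0
    svm_max_iter: int = 100_000
    rng_seed: int = 42
    symmetrize: bool = True
    psd_project: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.intensity_target_range
        if not lo < hi:
            raise ValueError("intensity range must satisfy low < high")
        if self.seed_method not in ("otsu", "kmeans2"):
            raise ValueError("seed_method must be 'otsu' or 'kmeans2'")
        if self.max_train_pixels < 2:
            raise ValueError("max_train_pixels must be >= 2")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")
        if self.svm_max_iter < 1:
            raise ValueError("svm_max_iter must be >= 1")
        if self.psd_project and not self.symmetrize:
            raise ValueError("psd_project requires symmetrize")


@dataclass
class SegmentationResult:
    mask: np.ndarray
    params: KernelParams | GaussianParams
    config: SegmenterConfig
    train_indices: np.ndarray


def _as_image(image) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ValueError(f"expected a 2-D image of size >= 2x2, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def rescale(image, target_range: tuple[float, float] = (0.0, 10.0)) -> np.ndarray:
    """Affinely map intensities onto ``target_range`` (min->low, max->high).

    A constant image maps entirely to the low end.  Idempotent on images
    already spanning the target range.
    """
    img = _as_image(image)
    lo, hi = target_range
    if not lo < hi:
        raise ValueError("target range must satisfy low < high")
    vmin, vmax = img.min(), img.max()
    if vmin == vmax:
        return np.full_like(img, lo)
    return lo + (img - vmin) * (hi - lo) / (vmax - vmin)


def flatten(image) -> FeatureTable:
    """Row-major flattening into an (m*n, 1) scalar-intensity feature table."""
    img = _as_image(image)
    return as_feature_table(img.ravel(order="C"))


def seed_labels(features, method: str = "otsu", rng_seed: int = 42) -> np.ndarray:
    """Bootstrap weak 0/1 labels from the intensity distribution.

    ``otsu``: threshold maximizing between-class variance over a 256-bin
    histogram; label 1 above the threshold.  ``kmeans2``: 2-means on the
    intensities; label 1 is the higher-mean cluster.  Deterministic given
    ``rng_seed``.
    """
    X = as_feature_table(features)
    values = X[:, 0]
    if np.unique(values).size < 2:
        raise ValueError("degenerate input: all feature values are equal; "
                         "cannot seed two classes")
    if method == "otsu":
        thresh = threshold_otsu(values, nbins=256)
        return (values > thresh).astype(int)
    if method == "kmeans2":
        km = KMeans(n_clusters=2, n_init=10, random_state=rng_seed)
        assign = km.fit_predict(values[:, None])
        high = int(np.argmax(km.cluster_centers_.ravel()))
        return (assign == high).astype(int)
    raise ValueError(f"unknown seed method {method!r}")


def _stratified_subsample(labels: np.ndarray, cap: int,
                          rng: np.random.Generator) -> np.ndarray:
    n = labels.size
    if n <= cap:
        return np.arange(n)
    take = []
    classes, counts = np.unique(labels, return_counts=True)
    # proportional allocation, at least one per class
    alloc = np.maximum(1, np.floor(cap * counts / n).astype(int))
    while alloc.sum() > cap:
        alloc[np.argmax(alloc)] -= 1
    for cls, k in zip(classes, alloc):
        idx = np.flatnonzero(labels == cls)
        take.append(rng.choice(idx, size=min(k, idx.size), replace=False))
    return np.sort(np.concatenate(take))


def fit_predict(
    features,
    seeds,
    params: KernelParams | GaussianParams,
    config: SegmenterConfig = SegmenterConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Train the precomputed-kernel SVM on seeded pixels, predict all pixels.

    Returns ``(labels, train_indices)`` where ``labels`` has one 0/1 entry per
    feature row.  Raises if the seed labels contain a single class.
    """
    X = as_feature_table(features)
    y = np.asarray(seeds, dtype=int)
    if y.shape != (X.shape[0],):
        raise ValueError("one seed label per feature row is required")
    if np.unique(y).size < 2:
        raise ValueError("seed labels contain a single class; adjust seeding "
                         "(e.g. a different seed_method) before training")

    rng = np.random.default_rng(config.rng_seed)
    train_idx = _stratified_subsample(y, config.max_train_pixels, rng)
    Xtr, ytr = X[train_idx], y[train_idx]

    K = pairwise_kernel(Xtr, Xtr, params, symmetric_pair=config.symmetrize)
    pos_basis = None
    if config.psd_project:
        # Clip the training spectrum to PSD; remember the positive eigenspace
        # so test similarities can be filtered through the same repair.
        w, V = eigh(K)
        K = (V * np.maximum(w, 0.0)) @ V.T
        K = 0.5 * (K + K.T)
        pos_basis = V[:, w > 0]

    # Ill-posed (T, mu) cells can stall SMO indefinitely on the repaired Gram;
    # the iteration cap keeps such cells cheap and deterministic (healthy fits
    # converge orders of magnitude below it).
    clf = SVC(C=config.svm_c, kernel="precomputed", max_iter=config.svm_max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(K, ytr)

    # Fold dual coefficients (and, when the training Gram was clipped, the
    # spectral projector V+ V+^T onto its positive eigenspace) into a single
    # weight vector: f(z) = k_sym(z, X_train) @ weights + b, exactly the SVC
    # decision function on the filtered cross-Gram.
    alpha = np.zeros(Xtr.shape[0])
    alpha[clf.support_] = clf.dual_coef_[0]
    if pos_basis is not None:
        alpha = pos_basis @ (pos_basis.T @ alpha)
    intercept = clf.intercept_[0]

    labels = np.empty(X.shape[0], dtype=int)
    chunk = 4096
    for start in range(0, X.shape[0], chunk):
        block = X[start:start + chunk]
        Kx = pairwise_kernel(block, Xtr, params, symmetric_pair=config.symmetrize)
        decision = Kx @ alpha + intercept
        labels[start:start + chunk] = clf.classes_[(decision > 0).astype(int)]
    return labels, train_idx


def segment(
    image,
    params: KernelParams | GaussianParams,
    config: SegmenterConfig = SegmenterConfig(),
) -> SegmentationResult:
    """Run the full pipeline on a 2-D grayscale image; 1 = target region."""
    img = _as_image(image)
    scaled = rescale(img, config.intensity_target_range)
    X = flatten(scaled)
    y0 = seed_labels(X, method=config.seed_method, rng_seed=config.rng_seed)
    labels, train_idx = fit_predict(X, y0, params, config)
    mask = labels.reshape(img.shape).astype(np.uint8)
    return SegmentationResult(mask=mask, params=params, config=config,
                              train_indices=train_idx)
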