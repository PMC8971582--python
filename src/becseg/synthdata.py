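"""Synthetic fixtures: glioma-like phantoms, two-class node clouds, iris-like data.

The phantom emulates the appearance the tool targets: a bright central disk
(tumor core) surrounded by an annular enhancing ring on a darker noisy
background.  Ground truth is the core plus the ring by default (a flag
restricts it to the core).  All generators are pure functions of their spec,
seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from becseg.kernel import FeatureTable, as_feature_table

__all__ = [
    "PhantomSpec",
    "NodeCloudSpec",
    "make_phantom",
    "make_node_cloud",
    "make_iris_like",
    "PHANTOM_PRESETS",
    "IRIS_LIKE_CLASSES",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of the core+annulus phantom.

    Intensities live on the segmenter's working scale (0, 10): background 1,
    core 9, ring 6 by default.  Gaussian pixel noise of standard deviation
    ``noise_sd`` is added after region assignment and the result is clipped to
    ``intensity_range``.  Pixel centers sit at integer coordinates + 0.5 and
    region membership is by Euclidean distance from ``center`` (defaults to
    the image center, so masks are 90-degree-rotation symmetric).
    """

    size: tuple[int, int] = (128, 128)
    center: tuple[float, float] | None = None
    core_radius: float = 12.0
    ring_inner: float = 18.0
    ring_outer: float = 26.0
    background: float = 1.0
    core: float = 9.0
    ring: float = 6.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    tumor_core_only: bool = False
    intensity_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        m, n = self.size
        if m < 2 or n < 2:
            raise ValueError("phantom must be at least 2x2")
        if not (0 < self.core_radius < self.ring_inner < self.ring_outer):
            raise ValueError(
                "radii must satisfy 0 < core_radius < ring_inner < ring_outer"
            )
        if self.ring_outer >= min(m, n) / 2:
            raise ValueError("ring_outer must fit inside the image")
        if len({self.background, self.core, self.ring}) != 3:
            raise ValueError("background, core and ring intensities must be distinct")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the phantom; returns ``(image, truth_mask)``.

    ``image`` is float64 of shape ``spec.size``; ``truth_mask`` is uint8 with
    1 on the tumor (core plus ring, or core only if ``tumor_core_only``).
    """
    m, n = spec.size
    cy, cx = spec.center if spec.center is not None else (m / 2.0, n / 2.0)
    yy = np.arange(m)[:, None] + 0.5
    xx = np.arange(n)[None, :] + 0.5
    dist = np.hypot(yy - cy, xx - cx)

    core = dist <= spec.core_radius
    ring = (dist >= spec.ring_inner) & (dist <= spec.ring_outer)
    image = np.full((m, n), spec.background, dtype=float)
    image[core] = spec.core
    image[ring] = spec.ring

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=(m, n))
        image = np.clip(image, *spec.intensity_range)

    truth = core if spec.tumor_core_only else (core | ring)
    return image, truth.astype(np.uint8)


@dataclass(frozen=True)
class NodeCloudSpec:
    """Two-class Gaussian point cloud (the random-node clustering fixture)."""

    n_per_class: int = 100
    means: tuple[tuple[float, ...], ...] = ((0.0, 0.0), (6.0, 6.0))
    spreads: tuple[tuple[float, ...], ...] = ((1.0, 1.0), (1.0, 1.0))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("need at least 2 nodes per class")
        dims = {len(mu) for mu in self.means} | {len(sd) for sd in self.spreads}
        if len(dims) != 1:
            raise ValueError("means and spreads must share one dimension")
        if len(self.means) != len(self.spreads):
            raise ValueError("one spread vector per class mean is required")
        if any(s < 0 for sd in self.spreads for s in sd):
            raise ValueError("spreads must be >= 0")


def make_node_cloud(spec: NodeCloudSpec) -> tuple[FeatureTable, np.ndarray]:
    """Draw the cloud; returns ``(features, labels)`` with labels 0..k-1."""
    rng = np.random.default_rng(spec.rng_seed)
    blocks, labels = [], []
    for k, (mu, sd) in enumerate(zip(spec.means, spec.spreads)):
        pts = rng.normal(np.asarray(mu, dtype=float),
                         np.asarray(sd, dtype=float),
                         size=(spec.n_per_class, len(mu)))
        blocks.append(pts)
        labels.append(np.full(spec.n_per_class, k, dtype=int))
    return as_feature_table(np.vstack(blocks)), np.concatenate(labels)


# Two well-separated 4-D classes with sepal/petal-like scales; a synthetic
# statistical stand-in, not the measured Fisher iris data.
IRIS_LIKE_CLASSES = {
    0: {"mean": (5.0, 3.4, 1.5, 0.2), "sd": (0.35, 0.38, 0.17, 0.10)},
    1: {"mean": (5.9, 2.8, 4.3, 1.3), "sd": (0.52, 0.31, 0.47, 0.20)},
}


def make_iris_like(n_per_class: int = 50, rng_seed: int = 0):
    """Synthetic iris-like fixture: two fixed 4-D Gaussian classes."""
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    spec = NodeCloudSpec(
        n_per_class=n_per_class,
        means=tuple(tuple(c["mean"]) for c in IRIS_LIKE_CLASSES.values()),
        spreads=tuple(tuple(c["sd"]) for c in IRIS_LIKE_CLASSES.values()),
        rng_seed=rng_seed,
    )
    return make_node_cloud(spec)


#: Named phantom presets used throughout the test suite and examples.
PHANTOM_PRESETS: dict[str, PhantomSpec] = {
    "default": PhantomSpec(),
    "noisy": PhantomSpec(noise_sd=0.3, rng_seed=42),
    "small-noisy": PhantomSpec(
        size=(64, 64), core_radius=6.0, ring_inner=9.0, ring_outer=13.0,
        noise_sd=0.3, rng_seed=42,
    ),
}
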