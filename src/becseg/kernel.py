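"""The BEC kernel, a Gaussian baseline, and Gram-matrix construction/repair.

The BEC kernel transplants the Bose-Einstein occupation number

    n(a) = 1 / (exp(a / (k_B * T)) - 1)

into a pixel-similarity function by feeding it the (shifted) distance between
two feature vectors.  The Boltzmann constant is replaced by its mantissa 1.38,
leaving two dimensionless hyperparameters: a "temperature" T (T != 0) and a
"chemical potential" mu that shifts the kernel argument.

Two readings of the argument are supported:

* ``literal``            -- a = ||x1 - x2 - mu * 1||, the formula taken at
                            face value.  Asymmetric in (x1, x2) when mu != 0.
* ``symmetric_distance`` -- a = | ||x1 - x2|| - mu |, symmetric by
                            construction.

The kernel is singular at a = 0 (the occupation number diverges) and is not
positive semidefinite, so this module also provides the repairs a standard
maximum-margin classifier needs: a denominator floor plus value cap for the
singularity, matrix symmetrization, and eigenvalue clipping (``psd_project``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

__all__ = [
    "KernelParams",
    "GaussianParams",
    "FeatureTable",
    "GramMatrix",
    "as_feature_table",
    "bec_kernel_value",
    "gaussian_kernel_value",
    "gram",
    "pairwise_kernel",
    "symmetrize",
    "psd_project",
]

MODES = ("literal", "symmetric_distance")


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the BEC kernel.

    Parameters
    ----------
    T
        Dimensionless temperature; any nonzero real.  Negative T flips the
        kernel's sign regime (all off-singularity values <= -1).
    mu
        Dimensionless chemical potential shifting the kernel argument.
    kb_scale
        Stand-in for the Boltzmann constant; 1.38, the mantissa of
        k_B = 1.3806488e-23 J/K (only the product ``kb_scale * T`` matters).
    denom_floor
        Smallest |denominator| allowed before it is replaced by
        ``+/- denom_floor`` (sign preserved, ``+`` for an exact zero).
    kernel_cap
        Kernel values are clamped to ``[-kernel_cap, +kernel_cap]``.
    mode
        ``"literal"`` or ``"symmetric_distance"`` (see module docstring).
    """

    T: float
    mu: float = 0.0
    kb_scale: float = 1.38
    denom_floor: float = 1e-8
    kernel_cap: float = 1e6
    mode: str = "literal"

    def __post_init__(self) -> None:
        if not np.isfinite(self.T) or self.T == 0:
            raise ValueError(f"temperature T must be finite and nonzero, got {self.T}")
        if not np.isfinite(self.mu):
            raise ValueError("chemical potential mu must be finite")
        if self.kb_scale <= 0:
            raise ValueError("kb_scale must be positive")
        if self.denom_floor <= 0:
            raise ValueError("denom_floor must be positive")
        if self.kernel_cap <= 0:
            raise ValueError("kernel_cap must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class GaussianParams:
    """Hyperparameters of the Gaussian (RBF) baseline kernel.

    ``sigma`` is the bandwidth (default 0.125); ``mu`` shifts the argument the
    same way the BEC kernel's chemical potential does (default 0, the plain
    radial basis function).
    """

    sigma: float = 0.125
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be finite and positive, got {self.sigma}")
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")


#: A feature table is an (n, p) float array: n samples, p finite features each.
FeatureTable = np.ndarray


def as_feature_table(rows) -> FeatureTable:
    """Validate and coerce ``rows`` into an (n, p) float feature table.

    Accepts 1-D input (interpreted as n scalar features) or 2-D input.
    Raises ``ValueError`` on empty, ragged, or non-finite input.
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError(f"feature table must be 1-D or 2-D, got ndim={X.ndim}")
    if X.size == 0:
        raise ValueError("feature table is empty")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature table contains non-finite entries")
    return X


@dataclass
class GramMatrix:
    """A dense matrix of pairwise kernel evaluations plus repair-state flags."""

    values: np.ndarray
    params: KernelParams | GaussianParams
    symmetrized: bool = False
    psd_corrected: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",")


def _bec_from_arg(a: np.ndarray, params: KernelParams) -> np.ndarray:
    """Occupation-number kernel of the nonnegative argument ``a``.

    Applies the denominator floor (sign-preserving, ``+`` for exact zero) and
    the value cap.
    """
    z = np.asarray(a, dtype=float) / (params.kb_scale * params.T)
    with np.errstate(over="ignore"):
        denom = np.expm1(z)
    small = np.abs(denom) < params.denom_floor
    if np.any(small):
        sign = np.where(denom < 0, -1.0, 1.0)  # exact zero gets +
        denom = np.where(small, sign * params.denom_floor, denom)
    with np.errstate(divide="ignore"):
        value = 1.0 / denom
    value = np.where(np.isfinite(value), value, 0.0)  # 1/inf overflow tail
    return np.clip(value, -params.kernel_cap, params.kernel_cap)


def _argument(delta: np.ndarray, mu: float, mode: str) -> float:
    delta = np.atleast_1d(np.asarray(delta, dtype=float))
    if not np.all(np.isfinite(delta)):
        raise ValueError("delta contains non-finite entries")
    if mode == "literal":
        return float(np.linalg.norm(delta - mu))
    return float(abs(np.linalg.norm(delta) - mu))


def bec_kernel_value(delta, params: KernelParams) -> float:
    """Evaluate the BEC kernel for one difference vector ``delta = x1 - x2``.

    Examples
    --------
    >>> bec_kernel_value(1.38, KernelParams(T=1.0))  # 1 / (e - 1)
    0.5819767068693265
    """
    a = _argument(delta, params.mu, params.mode)
    return float(_bec_from_arg(np.array(a), params))


def gaussian_kernel_value(delta, params: GaussianParams) -> float:
    """Evaluate the Gaussian kernel ``exp(-a^2 / (2 sigma^2))``, a = ||delta - mu||."""
    a = _argument(delta, params.mu, "literal")
    return float(np.exp(-(a**2) / (2.0 * params.sigma**2)))


def _pairwise_argument(
    X: FeatureTable, Y: FeatureTable, mu: float, mode: str
) -> np.ndarray:
    """(n, m) matrix of kernel arguments a_ij for rows of X against rows of Y."""
    if mode == "literal":
        # ||x_i - y_j - mu*1|| == ||x_i - (y_j + mu*1)||
        return cdist(X, Y + mu)
    return np.abs(cdist(X, Y) - mu)


def pairwise_kernel(
    X,
    Y,
    params: KernelParams | GaussianParams,
    *,
    symmetric_pair: bool = False,
) -> np.ndarray:
    """Raw (n, m) array of kernel values k(x_i, y_j).

    With ``symmetric_pair=True`` the pairwise-symmetrized kernel
    ``(k(x_i, y_j) + k(y_j, x_i)) / 2`` is returned instead; unlike matrix
    symmetrization this is defined for rectangular X-vs-Y evaluations, and on
    a square X-vs-X block it coincides with ``(K + K.T) / 2`` exactly.
    """
    X = as_feature_table(X)
    Y = as_feature_table(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {X.shape[1]} vs {Y.shape[1]}"
        )
    if isinstance(params, GaussianParams):

        def evaluate(A, B):
            a = _pairwise_argument(A, B, params.mu, "literal")
            return np.exp(-(a**2) / (2.0 * params.sigma**2))

    else:

        def evaluate(A, B):
            a = _pairwise_argument(A, B, params.mu, params.mode)
            return _bec_from_arg(a, params)

    K = evaluate(X, Y)
    if symmetric_pair:
        K = 0.5 * (K + evaluate(Y, X).T)
    return K


def gram(X, Y, params: KernelParams | GaussianParams) -> GramMatrix:
    """Materialize the kernel over all row pairs of X and Y (no repairs applied)."""
    return GramMatrix(values=pairwise_kernel(X, Y, params), params=params)


def symmetrize(K: GramMatrix) -> GramMatrix:
    """Replace a square Gram matrix by ``(K + K.T) / 2``.  Idempotent."""
    n, m = K.values.shape
    if n != m:
        raise ValueError(f"symmetrize needs a square matrix, got {n}x{m}")
    values = 0.5 * (K.values + K.values.T)
    return GramMatrix(values=values, params=K.params, symmetrized=True,
                      psd_corrected=K.psd_corrected)


def psd_project(K: GramMatrix, tol: float = 0.0) -> GramMatrix:
    """Clip the eigenvalues of a symmetrized Gram matrix at ``tol``.

    The BEC kernel is not a Mercer kernel, so its (symmetrized) Gram matrices
    generally have negative eigenvalues; clipping them yields the nearest PSD
    surrogate in Frobenius norm (for tol = 0).
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    n, m = K.values.shape
    if n != m:
        raise ValueError(f"psd_project needs a square matrix, got {n}x{m}")
    if not K.symmetrized:
        raise ValueError("psd_project requires a symmetrized Gram matrix; "
                         "call symmetrize() first")
    w, V = eigh(K.values)
    w = np.maximum(w, tol)
    values = (V * w) @ V.T
    values = 0.5 * (values + values.T)  # restore exact symmetry
    return GramMatrix(values=values, params=K.params, symmetrized=True,
                      psd_corrected=True)


def with_params(params: KernelParams, **changes) -> KernelParams:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **changes)
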