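"""Conditional covariance estimation for expression given genetic covariates.

Stage 1 of the two-stage conditional graphical-model fit: before any
precision matrix is estimated, the covariate (marker) effects on the
expression matrix are conditioned out.  The estimator is the empirical
conditional variance operator between reproducing-kernel Hilbert spaces of
``X`` and ``Y``; with a linear kernel it reduces to the familiar
moment-based formula ``S_YY - S_YX S_XX^{-1} S_XY``.

All moment matrices are computed from mean-centered data with divisor ``n``.
Centering makes the general kernel formula (which centers through the
projection ``Q = I - J/n``) and the linear-kernel moment formula agree
exactly, and expression data are never mean zero in practice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger(__name__)

#: singular values below this fraction of the largest are treated as zero
#: in every pseudoinverse taken by this module.
PINV_RTOL = 1e-10

KERNELS = ("linear", "rbf", "polynomial")


@dataclass
class CondCovEstimate:
    """A per-condition conditional covariance matrix ``Sigma_t = Var(Y | X)``.

    Attributes
    ----------
    sigma : (p, p) ndarray
        Symmetric, numerically PSD conditional covariance estimate.
    kernel : str
        Kernel used for the covariates: ``linear``, ``rbf``, ``polynomial``
        or ``none`` (no covariates; plain sample covariance).
    n : int
        Number of samples the estimate was computed from.
    """

    sigma: np.ndarray
    kernel: str = "linear"
    n: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be a square matrix")
        asym = np.max(np.abs(s - s.T)) if s.size else 0.0
        if asym > 1e-8 * (1.0 + np.max(np.abs(s))):
            raise ValueError(f"sigma is not symmetric (max asymmetry {asym:.3g})")
        self.sigma = (s + s.T) / 2.0

    @property
    def p(self) -> int:
        return self.sigma.shape[0]


def _center(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    return A - A.mean(axis=0, keepdims=True)


def make_kernel(X: np.ndarray, kind: str = "linear", *, bandwidth: float | None = None,
                degree: int = 2) -> np.ndarray:
    """Gram matrix of the covariates under the requested kernel.

    Parameters
    ----------
    X : (n, q) array
        Covariate matrix (rows are samples).
    kind : {'linear', 'rbf', 'polynomial'}
        ``linear`` gives ``X X^T``; ``rbf`` gives
        ``exp(-||x_i - x_j||^2 / (2 sigma^2))`` with ``sigma`` the bandwidth;
        ``polynomial`` gives ``(x_i^T x_j + 1)^d``.
    bandwidth : float, optional
        RBF bandwidth ``sigma``.  Defaults to the median pairwise Euclidean
        distance (median heuristic); must be positive when given.
    degree : int
        Polynomial degree ``d >= 1``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (samples x covariates)")
    if kind == "linear":
        K = X @ X.T
    elif kind == "rbf":
        if bandwidth is None:
            d = pdist(X)
            med = np.median(d[d > 0]) if np.any(d > 0) else 1.0
            bandwidth = float(med) if med > 0 else 1.0
        if bandwidth <= 0:
            raise ValueError(f"rbf bandwidth must be positive, got {bandwidth}")
        sq = squareform(pdist(X, "sqeuclidean"))
        K = np.exp(-sq / (2.0 * bandwidth**2))
    elif kind == "polynomial":
        if degree < 1:
            raise ValueError(f"polynomial degree must be >= 1, got {degree}")
        K = (X @ X.T + 1.0) ** degree
    else:
        raise ValueError(f"unknown kernel kind {kind!r}; expected one of {KERNELS}")
    return (K + K.T) / 2.0


def kernel_cond_cov(Y: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Kernel conditional covariance of ``Y`` given covariates with Gram ``K``.

    Computes ``(1/n) (Y' Q Y - Y' Q (QKQ)(QKQ)^+ Q Y)`` where
    ``Q = I - J/n`` is the centering projection and ``+`` the Moore-Penrose
    pseudoinverse.  ``(QKQ)(QKQ)^+`` is the orthogonal projector onto the
    column space of the centered kernel, so the second term removes the part
    of (centered) ``Y`` explained by the covariate feature space.

    A zero kernel therefore returns the plain centered sample covariance
    (divisor ``n``).
    """
    Y = np.asarray(Y, dtype=float)
    K = np.asarray(K, dtype=float)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if K.shape != (n, n):
        raise ValueError(f"kernel must be {n}x{n}, got {K.shape}")
    scale = max(np.max(np.abs(K)), 1.0)
    if np.max(np.abs(K - K.T)) > 1e-8 * scale:
        raise ValueError("kernel matrix is not symmetric")
    w = np.linalg.eigvalsh((K + K.T) / 2.0)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(f"kernel matrix is not PSD (min eigenvalue {w.min():.3g})")

    Yc = _center(Y)  # Q Y
    A = _center(_center(K).T)  # Q K Q
    # projector onto col(QKQ) applied to Q Y
    proj = A @ np.linalg.pinv(A, rcond=PINV_RTOL) @ Yc
    sigma = (Yc.T @ Yc - Yc.T @ proj) / n
    return (sigma + sigma.T) / 2.0


def linear_cond_cov(Y: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    """Linear-kernel conditional covariance ``S_YY - S_YX S_XX^+ S_XY``.

    Moment matrices use mean-centered ``Y`` and ``X`` and divisor ``n``.
    ``X`` with zero columns (or ``None``) returns the plain sample
    covariance, i.e. the unconditional model.  A rank-deficient ``S_XX`` is
    handled through the pseudoinverse.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    Yc = _center(Y)
    S_YY = Yc.T @ Yc / n
    if X is None or np.size(X) == 0 or np.asarray(X).shape[-1] == 0:
        return (S_YY + S_YY.T) / 2.0
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError(f"X has {X.shape[0]} rows but Y has {n}")
    q = X.shape[1]
    if n <= q:
        warnings.warn(
            f"n = {n} <= q = {q}: conditional covariance estimate may be degenerate",
            stacklevel=2,
        )
    Xc = _center(X)
    S_XX = Xc.T @ Xc / n
    S_XY = Xc.T @ Yc / n
    sigma = S_YY - S_XY.T @ np.linalg.pinv(S_XX, rcond=PINV_RTOL) @ S_XY
    return (sigma + sigma.T) / 2.0


def conditional_covariance(Y: np.ndarray, X: np.ndarray | None = None, *,
                           kernel: str = "linear", **kernel_params) -> CondCovEstimate:
    """Convenience front end selecting the estimator by kernel name.

    ``kernel='none'`` or empty ``X`` gives the unconditional sample
    covariance; ``'linear'`` uses the moment formula; other kernels go
    through :func:`kernel_cond_cov`.
    """
    Y = np.asarray(Y, dtype=float)
    if kernel == "none" or X is None or np.size(X) == 0:
        return CondCovEstimate(linear_cond_cov(Y, None), kernel="none", n=Y.shape[0])
    if kernel == "linear":
        return CondCovEstimate(linear_cond_cov(Y, X), kernel="linear", n=Y.shape[0])
    K = make_kernel(np.asarray(X, dtype=float), kernel, **kernel_params)
    return CondCovEstimate(kernel_cond_cov(Y, K), kernel=kernel, n=Y.shape[0])
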