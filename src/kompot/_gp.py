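"""Shared Gaussian-process primitives: kernels, jittered factorizations, heuristics."""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, cho_solve, solve_triangular
from scipy.spatial.distance import cdist

__all__ = [
    "matern52",
    "jittered_cholesky",
    "median_pairwise_distance",
    "FactorizationError",
]

_SQRT5 = np.sqrt(5.0)


class FactorizationError(np.linalg.LinAlgError):
    """Cholesky factorization failed even after jitter escalation."""


def matern52(X: np.ndarray, Y: np.ndarray, lengthscale: float) -> np.ndarray:
    """Matern-5/2 covariance between row sets X and Y (unit variance)."""
    if lengthscale <= 0:
        raise ValueError(f"lengthscale must be positive, got {lengthscale}")
    r = cdist(np.atleast_2d(X), np.atleast_2d(Y)) * (_SQRT5 / lengthscale)
    return (1.0 + r + r * r / 3.0) * np.exp(-r)


def jittered_cholesky(
    A: np.ndarray,
    jitter: float = 1e-10,
    max_jitter: float = 1e-4,
) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of a symmetric PSD matrix, escalating the
    diagonal jitter geometrically until the factorization succeeds.

    Returns (L, jitter_used). Raises FactorizationError past max_jitter.
    """
    A = np.asarray(A, dtype=float)
    eps = jitter
    eye = np.eye(A.shape[0])
    while eps <= max_jitter:
        try:
            L = cholesky(A + eps * eye, lower=True)
            return L, eps
        except np.linalg.LinAlgError:
            eps *= 10.0
    raise FactorizationError(
        f"Cholesky failed for {A.shape[0]}x{A.shape[0]} matrix even with "
        f"jitter {max_jitter:g}"
    )


def chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve A x = b given the lower Cholesky factor L of A."""
    return cho_solve((L, True), b)


def tri_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve L x = b for lower-triangular L."""
    return solve_triangular(L, b, lower=True)


def median_pairwise_distance(
    X: np.ndarray, max_points: int = 1000, seed: int = 0
) -> float:
    """Median Euclidean pairwise distance, subsampled for large inputs."""
    X = np.atleast_2d(X)
    n = X.shape[0]
    if n > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(n, size=max_points, replace=False)]
    d = cdist(X, X)
    iu = np.triu_indices_from(d, k=1)
    vals = d[iu]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("all pairwise distances are zero")
    return float(np.median(vals))
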