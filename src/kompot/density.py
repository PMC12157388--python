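"""Condition-specific log-density estimation over the cell-state space.

The model places a Gaussian-process prior (Matern-5/2, learned constant mean)
on the log-density function g and ties it to the data through the
nearest-neighbor distance of each cell: under a locally homogeneous Poisson
process of intensity exp(g(x)) in dimension d, the first-neighbor distance r
has log-likelihood

    log p(r | g) = g + log d + log V_d + (d - 1) log r - exp(g) V_d r^d,

with V_d the volume of the unit d-ball. The MAP of g is found in whitened
coordinates; pointwise predictive uncertainty comes from a Laplace
approximation at the MAP, propagated through the standard GP predictive
equations. For large n an inducing-point (landmark) parameterization keeps
the fit tractable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize
from sklearn.neighbors import NearestNeighbors

from ._gp import jittered_cholesky, matern52, median_pairwise_distance

logger = logging.getLogger(__name__)

__all__ = [
    "DensityEstimate",
    "DensityFitError",
    "estimate_intrinsic_dimension",
    "fit_density",
    "predict_log_density",
]

_EULER_GAMMA = 0.5772156649015329
# variance of log W for W ~ Exponential is pi^2/6; scale the Laplace
# curvature so the implied Gaussian pseudo-observation matches that moment
_H_CAL = 6.0 / math.pi**2


class DensityFitError(RuntimeError):
    """MAP optimization did not converge."""

    def __init__(self, message: str, grad_norm: float):
        self.grad_norm = grad_norm
        super().__init__(f"{message} (final gradient norm {grad_norm:.3e})")


def unit_ball_volume(d: float) -> float:
    """Volume of the unit ball in (possibly fractional) dimension d."""
    return math.pi ** (d / 2.0) / math.gamma(d / 2.0 + 1.0)


def nn_distance_log_likelihood(r, g, d: float):
    """Per-cell log-likelihood of nearest-neighbor distances r given log-density g."""
    vd = unit_ball_volume(d)
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    return (
        g
        + math.log(d)
        + math.log(vd)
        + (d - 1.0) * np.log(r)
        - np.exp(g) * vd * r**d
    )


def _dedupe(coords: np.ndarray, what: str) -> np.ndarray:
    """Drop exact duplicate rows with a logged warning."""
    _, first_idx = np.unique(coords, axis=0, return_index=True)
    if len(first_idx) < coords.shape[0]:
        n_dup = coords.shape[0] - len(first_idx)
        logger.warning("%s: dropping %d duplicate point(s)", what, n_dup)
        coords = coords[np.sort(first_idx)]
    return coords


def estimate_intrinsic_dimension(coords: np.ndarray) -> float:
    """Global intrinsic dimension by the two-NN maximum-likelihood estimator.

    d = 1 / mean(log(r2 / r1)) over cells, where r1, r2 are the first and
    second nearest-neighbor distances. Clipped to [1, ambient dimension].
    """
    coords = np.asarray(coords, dtype=float)
    coords = _dedupe(coords, "estimate_intrinsic_dimension")
    n, ambient = coords.shape
    if n < 50:
        raise ValueError(f"need >= 50 cells for a stable estimate, got {n}")
    nn = NearestNeighbors(n_neighbors=3).fit(coords)
    dist, _ = nn.kneighbors(coords)
    r1, r2 = dist[:, 1], dist[:, 2]
    ratios = r2 / r1
    mean_log = float(np.mean(np.log(ratios)))
    if mean_log <= 1e-9:
        raise ValueError("degenerate input: all neighbor-distance ratios equal 1")
    d = 1.0 / mean_log
    return float(np.clip(d, 1.0, ambient))


@dataclass
class DensityEstimate:
    """Fitted per-condition log-density posterior."""

    condition: str | None
    n_cells: int
    intrinsic_dim: float
    predictive_mean: np.ndarray  # mu at the training states, log cells/volume
    predictive_sd: np.ndarray  # sigma at the training states
    model_state: "_DensityModelState"

    def predict(self, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return predict_log_density(self, query)


@dataclass
class _DensityModelState:
    """Opaque, serializable fitted-model internals."""

    mode: str  # "exact" | "sparse"
    X: np.ndarray  # training coords (exact) or inducing points (sparse)
    lengthscale: float
    intrinsic_dim: float
    n_cells: int
    mean_const: float
    pred_weights: np.ndarray  # K^{-1}(g_hat - m) at X
    # variance pieces (Laplace): exact mode stores sqrt(W) and chol(I + W^.5 K W^.5);
    # sparse mode stores chol(Kzz) and chol(Kzz + Kzx H Kxz)
    var_chol: np.ndarray
    var_aux: np.ndarray
    extras: dict[str, Any] = field(default_factory=dict)


def _nearest_neighbor_distances(X: np.ndarray) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    dist, _ = nn.kneighbors(X)
    return dist[:, 1]


def fit_density(
    coords: np.ndarray,
    intrinsic_dim: float | None = None,
    *,
    condition: str | None = None,
    lengthscale: float | None = None,
    lengthscale_factor: float = 1.0,
    optimize_lengthscale: bool = False,
    sparse_threshold: int = 5000,
    n_inducing: int = 1000,
    max_iter: int = 2000,
    gtol: float = 1e-5,
    seed: int = 0,
) -> DensityEstimate:
    """MAP fit of the GP log-density model from nearest-neighbor distances.

    Falls back to an inducing-point parameterization (k-means landmarks)
    above ``sparse_threshold`` cells. Deterministic given seed and config.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2:
        raise ValueError("coords must be 2-D (cells x state dims)")
    n = X.shape[0]
    if n < 50:
        raise ValueError(f"need >= 50 cells to fit a density, got {n}")

    # exact duplicates break the likelihood (r1 = 0): jitter them
    _, first_idx = np.unique(X, axis=0, return_index=True)
    if len(first_idx) < n:
        warnings.warn(
            f"{n - len(first_idx)} duplicate point(s) perturbed by 1e-10 jitter",
            stacklevel=2,
        )
        dup_mask = np.ones(n, dtype=bool)
        dup_mask[np.sort(first_idx)] = False
        rng = np.random.default_rng(seed)
        X = X.copy()
        X[dup_mask] += rng.normal(scale=1e-10, size=(dup_mask.sum(), X.shape[1]))

    if intrinsic_dim is None:
        intrinsic_dim = estimate_intrinsic_dimension(X)
    d = float(intrinsic_dim)
    if d <= 0:
        raise ValueError(f"intrinsic_dim must be positive, got {d}")

    if lengthscale is None:
        lengthscale = median_pairwise_distance(X, seed=seed) * lengthscale_factor
    ls = float(lengthscale)

    r = _nearest_neighbor_distances(X)
    vd = unit_ball_volume(d)
    w = vd * r**d  # exp(g) * w is the likelihood's rate term
    loglik_const = math.log(d) + math.log(vd) + (d - 1.0) * np.log(r)

    sparse = n > sparse_threshold
    if sparse:
        from .expression import select_landmarks

        k = min(n_inducing, n)
        Z = select_landmarks(X, k=k, t=10, seed=seed).points
        state = _fit_sparse(X, Z, w, loglik_const, d, ls, n, max_iter, gtol)
    else:
        if optimize_lengthscale:
            state = _fit_exact_opt_ls(X, w, loglik_const, d, ls, n, max_iter, gtol)
        else:
            state = _fit_exact(X, w, loglik_const, d, ls, n, max_iter, gtol)
    state.extras["train_coords"] = X

    mu, sd = _predict(state, X)
    return DensityEstimate(
        condition=condition,
        n_cells=n,
        intrinsic_dim=d,
        predictive_mean=mu,
        predictive_sd=sd,
        model_state=state,
    )


def _g_init(w: np.ndarray) -> float:
    # E[log W] = -g - gamma for W ~ Exp(e^g): crude unbiased start for the mean
    return float(np.mean(-np.log(w)) - _EULER_GAMMA)


def _check_converged(res, gtol: float, n_params: int):
    # L-BFGS-B reporting convergence on f-reduction or the projected gradient
    # both count as converged; only flag a genuine non-convergence (iteration
    # budget exhausted or an abnormal termination with a large gradient).
    gnorm = float(np.max(np.abs(res.jac)))
    if not res.success and gnorm > max(gtol, 1e-3) * np.sqrt(n_params):
        raise DensityFitError(
            f"density MAP optimization did not converge: {res.message}", gnorm
        )


def _fit_exact(X, w, loglik_const, d, ls, n, max_iter, gtol) -> _DensityModelState:
    K = matern52(X, X, ls)
    L, _ = jittered_cholesky(K, jitter=1e-8)

    m0 = _g_init(w)

    def negobj(theta):
        z, m = theta[:-1], theta[-1]
        g = m + L @ z
        rate = np.exp(np.clip(g, -700.0, 700.0)) * w
        f = -(np.sum(g + loglik_const - rate)) + 0.5 * z @ z
        dl = 1.0 - rate  # d loglik / d g
        grad = np.empty_like(theta)
        grad[:-1] = -(L.T @ dl) + z
        grad[-1] = -np.sum(dl)
        return f, grad

    theta0 = np.zeros(n + 1)
    theta0[-1] = m0
    res = minimize(
        negobj,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12, "maxfun": 10 * max_iter},
    )
    _check_converged(res, gtol, n + 1)

    z_hat, m_hat = res.x[:-1], res.x[-1]
    g_hat = m_hat + L @ z_hat
    # Gaussianized likelihood curvature: the raw Laplace Hessian exp(g) w is
    # ~1 per cell at the MAP, but the log-exponential observation
    # -log(V_d r^d) has true variance pi^2/6 about g; moment-match the
    # pseudo-noise so the posterior spread is not understated.
    h = np.exp(np.clip(g_hat, -700.0, 700.0)) * w * _H_CAL
    sqrt_h = np.sqrt(h)
    B = np.eye(n) + sqrt_h[:, None] * K * sqrt_h[None, :]
    LB = cholesky(B, lower=True)

    # predictive-mean weights K^{-1}(g_hat - m) = L^{-T} z
    alpha = solve_triangular(L, z_hat, lower=True, trans="T")

    # the constant mean is learned with a flat prior; propagate its
    # uncertainty into the predictive variance (universal-kriging term):
    # with Sigma = K + H^{-1}, add (1 - k*^T Sigma^{-1} 1)^2 / (1^T Sigma^{-1} 1).
    # Sigma^{-1} v = W^.5 B^{-1} W^.5 v via the stored factor of B.
    tmp = solve_triangular(LB, sqrt_h, lower=True)
    tmp = solve_triangular(LB, tmp, lower=True, trans="T")
    sigma_inv_one = sqrt_h * tmp
    one_sigma_one = float(np.sum(sqrt_h * tmp))

    return _DensityModelState(
        mode="exact",
        X=X,
        lengthscale=ls,
        intrinsic_dim=d,
        n_cells=n,
        mean_const=float(m_hat),
        pred_weights=alpha,
        var_chol=LB,
        var_aux=sqrt_h,
        extras={"sigma_inv_one": sigma_inv_one, "one_sigma_one": one_sigma_one},
    )


def _fit_exact_opt_ls(X, w, loglik_const, d, ls0, n, max_iter, gtol):
    """Whitened joint MAP over latent values and log length-scale."""
    m0 = _g_init(w)
    cache: dict[float, np.ndarray] = {}

    def chol_for(log_ls):
        key = round(float(log_ls), 12)
        if key not in cache:
            if len(cache) > 8:
                cache.clear()
            K = matern52(X, X, math.exp(log_ls))
            cache[key], _ = jittered_cholesky(K, jitter=1e-8)
        return cache[key]

    def negobj(theta):
        z, m, log_ls = theta[:-2], theta[-2], theta[-1]
        L = chol_for(log_ls)
        g = m + L @ z
        rate = np.exp(np.clip(g, -700.0, 700.0)) * w
        return -(np.sum(g + loglik_const - rate)) + 0.5 * z @ z

    theta0 = np.zeros(n + 2)
    theta0[-2] = m0
    theta0[-1] = math.log(ls0)
    res = minimize(
        negobj,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * n
        + [(None, None), (math.log(ls0) - 2.0, math.log(ls0) + 2.0)],
        options={"maxiter": max_iter, "maxfun": 4 * max_iter},
    )
    ls = math.exp(res.x[-1])
    # refit cleanly at the optimized length-scale for the Laplace pieces
    return _fit_exact(X, w, loglik_const, d, ls, n, max_iter, gtol)


def _fit_sparse(X, Z, w, loglik_const, d, ls, n, max_iter, gtol):
    k = Z.shape[0]
    Kzz = matern52(Z, Z, ls)
    Lz, _ = jittered_cholesky(Kzz, jitter=1e-8)
    Kxz = matern52(X, Z, ls)
    # g = A u with A = Kxz Kzz^{-1}; whitened u = m + Lz s -> g = A(m 1 + Lz s)
    A = solve_triangular(Lz, Kxz.T, lower=True)
    A = solve_triangular(Lz, A, lower=True, trans="T").T  # n x k
    B = A @ Lz  # n x k
    a1 = A.sum(axis=1)

    m0 = _g_init(w)

    def negobj(theta):
        s, m = theta[:-1], theta[-1]
        g = m * a1 + B @ s
        rate = np.exp(np.clip(g, -700.0, 700.0)) * w
        f = -(np.sum(g + loglik_const - rate)) + 0.5 * s @ s
        dl = 1.0 - rate
        grad = np.empty_like(theta)
        grad[:-1] = -(B.T @ dl) + s
        grad[-1] = -np.sum(dl * a1)
        return f, grad

    theta0 = np.zeros(k + 1)
    theta0[-1] = m0
    res = minimize(
        negobj,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12, "maxfun": 10 * max_iter},
    )
    _check_converged(res, gtol, k + 1)

    s_hat, m_hat = res.x[:-1], res.x[-1]
    u_hat = m_hat + Lz @ s_hat
    g_hat = A @ u_hat
    h = np.exp(np.clip(g_hat, -700.0, 700.0)) * w * _H_CAL

    # posterior cov of u: (Kzz^{-1} + A^T H A)^{-1}; predictive variance uses
    # Kzz^{-1} - (Kzz + Kzx H Kxz)^{-1}
    M = Kzz + Kxz.T @ (h[:, None] * Kxz)
    LM, _ = jittered_cholesky(M, jitter=1e-8)

    alpha = solve_triangular(Lz, s_hat, lower=True, trans="T")  # Kzz^{-1}(u - m)

    return _DensityModelState(
        mode="sparse",
        X=Z,
        lengthscale=ls,
        intrinsic_dim=d,
        n_cells=n,
        mean_const=float(m_hat),
        pred_weights=alpha,
        var_chol=LM,
        var_aux=Lz,
    )


def _predict(state: _DensityModelState, query: np.ndarray):
    query = np.asarray(query, dtype=float)
    if query.ndim != 2:
        raise ValueError("query must be 2-D (states x dims)")
    if query.shape[1] != state.X.shape[1]:
        raise ValueError(
            f"query dimension {query.shape[1]} != model dimension {state.X.shape[1]}"
        )
    if query.shape[0] == 0:
        return np.empty(0), np.empty(0)

    Ks = matern52(query, state.X, state.lengthscale)  # (m, n_basis)
    mu = state.mean_const + Ks @ state.pred_weights
    kss = 1.0  # unit-variance Matern at zero lag

    if state.mode == "exact":
        sqrt_h = state.var_aux
        V = solve_triangular(state.var_chol, (Ks * sqrt_h[None, :]).T, lower=True)
        var = kss - np.einsum("ij,ij->j", V, V)
        if "sigma_inv_one" in state.extras:
            resid = 1.0 - Ks @ state.extras["sigma_inv_one"]
            var = var + resid**2 / state.extras["one_sigma_one"]
    else:
        Lz, LM = state.var_aux, state.var_chol
        V1 = solve_triangular(Lz, Ks.T, lower=True)
        V2 = solve_triangular(LM, Ks.T, lower=True)
        var = (
            kss
            - np.einsum("ij,ij->j", V1, V1)
            + np.einsum("ij,ij->j", V2, V2)
        )
    var = np.maximum(var, 0.0)
    return mu, np.sqrt(var)


def predict_log_density(model, query: np.ndarray):
    """Predictive mean and sd of log density (log cells per volume) at query states."""
    state = model.model_state if isinstance(model, DensityEstimate) else model
    return _predict(state, query)
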