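"""Differential expression via counterfactual fold changes and the
landmark-covariance Mahalanobis distance.

Per gene g and state x the log fold change is the difference of the two
conditions' posterior expression functions, lfc(x, g) = mu_b(x, g) -
mu_a(x, g); the per-gene significance score is

    D = sqrt((mu_a - mu_b)^T (Sigma_a + Sigma_b)^{-1} (mu_a - mu_b))

evaluated at a fixed landmark set, i.e. the number of posterior standard
deviations separating the two expression functions, accounting for the
covariance between neighboring cell states. D is a ranking score; no null
distribution (and hence no multiple-testing correction) is claimed for it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from ._gp import FactorizationError, jittered_cholesky
from .abundance import posterior_tail_probability
from .expression import ExpressionPredictor, impute_expression, select_landmarks

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionComparison",
    "fold_change",
    "mahalanobis_distance",
    "compare_expression",
    "local_expression_ptp",
    "rank_genes",
]

DEFAULT_LFC_THRESHOLD = 0.15
DEFAULT_D_THRESHOLD = 3.0
DEFAULT_DIVERGENT_LFC_MAX = 0.07
DEFAULT_DIVERGENT_D_MIN = 6.0


@dataclass
class ExpressionComparison:
    """Per-gene DE result for one ordered condition pair on one cell group."""

    condition_from: str
    condition_to: str
    gene_ids: np.ndarray
    lfc: np.ndarray  # (n_states, G) natural-log fold change b - a
    mean_lfc: np.ndarray  # (G,) over the evaluated group
    mahalanobis: np.ndarray  # (G,) D >= 0
    significant: np.ndarray  # (G,) |mean_lfc| > thr and D > thr
    category: np.ndarray  # (G,) {"up", "down", "divergent", "ns"}
    group: str = "all"
    thresholds: dict = field(default_factory=dict)
    landmarks: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mean_lfc": self.mean_lfc,
                "mahalanobis": self.mahalanobis,
                "significant": self.significant,
                "category": self.category,
            }
        )


def _check_gene_lists(pred_a: ExpressionPredictor, pred_b: ExpressionPredictor):
    if not np.array_equal(pred_a.gene_ids, pred_b.gene_ids):
        sym = set(pred_a.gene_ids) ^ set(pred_b.gene_ids)
        raise ValueError(
            f"gene lists differ between predictors; symmetric difference: "
            f"{sorted(sym)[:20]}"
        )


def fold_change(
    pred_a: ExpressionPredictor,
    pred_b: ExpressionPredictor,
    states: np.ndarray,
) -> np.ndarray:
    """lfc(x, g) = mu_b(x, g) - mu_a(x, g) at every supplied state."""
    _check_gene_lists(pred_a, pred_b)
    return impute_expression(pred_b, states) - impute_expression(pred_a, states)


def mahalanobis_distance(
    mu_a: np.ndarray,
    mu_b: np.ndarray,
    cov_sum: np.ndarray,
    *,
    jitter: float = 1e-10,
    max_jitter: float = 1e-4,
) -> np.ndarray:
    """D = sqrt((mu_a - mu_b)^T cov_sum^{-1} (mu_a - mu_b)) per gene.

    ``mu_a``/``mu_b`` are (k,) or (k, G); ``cov_sum`` is the k x k sum of the
    two conditions' landmark covariances. Computed through one triangular
    factorization reused across genes; never forms an explicit inverse.
    """
    cov_sum = np.asarray(cov_sum, dtype=float)
    if cov_sum.ndim != 2 or cov_sum.shape[0] != cov_sum.shape[1]:
        raise ValueError("cov_sum must be square")
    if not np.allclose(cov_sum, cov_sum.T, atol=1e-8 * max(1.0, np.abs(cov_sum).max())):
        raise ValueError("cov_sum must be symmetric")
    cov_sum = 0.5 * (cov_sum + cov_sum.T)

    diff = np.asarray(mu_a, dtype=float) - np.asarray(mu_b, dtype=float)
    single = diff.ndim == 1
    if single:
        diff = diff[:, None]
    if diff.shape[0] != cov_sum.shape[0]:
        raise ValueError(
            f"mean vectors of length {diff.shape[0]} do not match "
            f"{cov_sum.shape[0]}-landmark covariance"
        )

    # jitter only when needed so well-conditioned inputs are solved exactly
    eigmin = float(np.linalg.eigvalsh(cov_sum).min())
    try:
        if eigmin >= 1e-10:
            from scipy.linalg import cholesky as _chol

            L = _chol(cov_sum, lower=True)
        else:
            L, _ = jittered_cholesky(cov_sum, jitter=jitter, max_jitter=max_jitter)
    except (np.linalg.LinAlgError, FactorizationError) as exc:
        raise FactorizationError(
            f"covariance factorization failed for {diff.shape[1]} gene(s): {exc}"
        ) from exc
    sol = solve_triangular(L, diff, lower=True)
    D = np.sqrt(np.einsum("ij,ij->j", sol, sol))
    return float(D[0]) if single else D


def local_expression_ptp(
    lfc: np.ndarray, sd_a: np.ndarray, sd_b: np.ndarray
) -> np.ndarray:
    """Per-state (per-gene) posterior tail probability of the expression
    fold change; same contract as the abundance PTP."""
    lfc = np.asarray(lfc, dtype=float)
    sd_a = np.asarray(sd_a, dtype=float)
    sd_b = np.asarray(sd_b, dtype=float)
    if lfc.ndim == 2 and sd_a.ndim == 1:
        sd_a = sd_a[:, None]
        sd_b = sd_b[:, None]
    return posterior_tail_probability(lfc, sd_a, sd_b)


def compare_expression(
    pred_a: ExpressionPredictor,
    pred_b: ExpressionPredictor,
    states: np.ndarray,
    cell_mask: np.ndarray | None = None,
    *,
    n_landmarks: int | None = None,
    kmeans_iters: int = 10,
    seed: int = 0,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    d_threshold: float = DEFAULT_D_THRESHOLD,
    divergent_lfc_max: float = DEFAULT_DIVERGENT_LFC_MAX,
    divergent_d_min: float = DEFAULT_DIVERGENT_D_MIN,
    group: str = "all",
) -> ExpressionComparison:
    """Full DE comparison over a cell group.

    Landmarks are (re-)selected by k-means from the evaluated group's states
    before computing landmark means and covariances, keeping the covariance
    well-conditioned and resolution proportional to the subset size.
    """
    _check_gene_lists(pred_a, pred_b)
    states = np.asarray(states, dtype=float)
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask)
        if cell_mask.dtype == bool and not cell_mask.any():
            raise ValueError("cell_mask selects an empty subset")
        states = states[cell_mask]
        if states.shape[0] == 0:
            raise ValueError("cell_mask selects an empty subset")

    n_states = states.shape[0]
    if n_landmarks is None:
        n_landmarks = min(pred_a.k, n_states)
    if n_landmarks > n_states:
        warnings.warn(
            f"subset of {n_states} states smaller than k={n_landmarks}; "
            "reducing k to the subset size",
            stacklevel=2,
        )
        n_landmarks = n_states
    lm = select_landmarks(states, k=n_landmarks, t=kmeans_iters, seed=seed)

    mu_a = impute_expression(pred_a, lm.points)  # (k, G)
    mu_b = impute_expression(pred_b, lm.points)
    cov_sum = pred_a.posterior_cov(lm.points) + pred_b.posterior_cov(lm.points)
    D = mahalanobis_distance(mu_a, mu_b, cov_sum)

    lfc = fold_change(pred_a, pred_b, states)
    mean_lfc = lfc.mean(axis=0)

    significant = (np.abs(mean_lfc) > lfc_threshold) & (D > d_threshold)
    category = np.full(len(D), "ns", dtype=object)
    category[(np.abs(mean_lfc) < divergent_lfc_max) & (D > divergent_d_min)] = (
        "divergent"
    )
    category[significant & (mean_lfc > 0)] = "up"
    category[significant & (mean_lfc < 0)] = "down"

    return ExpressionComparison(
        condition_from=pred_a.condition or "a",
        condition_to=pred_b.condition or "b",
        gene_ids=pred_a.gene_ids,
        lfc=lfc,
        mean_lfc=mean_lfc,
        mahalanobis=D,
        significant=significant,
        category=category,
        group=group,
        thresholds={
            "lfc_threshold": lfc_threshold,
            "d_threshold": d_threshold,
            "divergent_lfc_max": divergent_lfc_max,
            "divergent_d_min": divergent_d_min,
        },
        landmarks=lm.points,
    )


def rank_genes(comparison: ExpressionComparison, mode: str) -> pd.DataFrame:
    """Deterministic gene ranking by Mahalanobis distance within a category.

    ``up``/``down``: genes passing the sign, |mean_lfc| and D thresholds;
    ``divergent``: |mean_lfc| < divergent_lfc_max and D > divergent_d_min.
    Ties broken by gene id.
    """
    thr = comparison.thresholds
    lfc_thr = thr.get("lfc_threshold", DEFAULT_LFC_THRESHOLD)
    d_thr = thr.get("d_threshold", DEFAULT_D_THRESHOLD)
    div_lfc = thr.get("divergent_lfc_max", DEFAULT_DIVERGENT_LFC_MAX)
    div_d = thr.get("divergent_d_min", DEFAULT_DIVERGENT_D_MIN)

    m, D = comparison.mean_lfc, comparison.mahalanobis
    if mode == "up":
        mask = (m > lfc_thr) & (D > d_thr)
    elif mode == "down":
        mask = (m < -lfc_thr) & (D > d_thr)
    elif mode == "divergent":
        mask = (np.abs(m) < div_lfc) & (D > div_d)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected up, down or divergent")

    df = pd.DataFrame(
        {
            "gene_id": comparison.gene_ids[mask],
            "mean_lfc": m[mask],
            "mahalanobis": D[mask],
        }
    )
    df = df.sort_values(
        ["mahalanobis", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
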