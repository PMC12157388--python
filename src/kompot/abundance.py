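"""Differential-abundance statistics between two conditions.

All log quantities use the natural log. Per ordered condition pair (a -> b)
the per-state statistics are

    Delta(x) = mu_b(x) - mu_a(x) - log(N_a / N_b)
    PTP(x)   = Phi(-|Delta(x)| / sqrt(sigma_a^2(x) + sigma_b^2(x)))

where Phi is the standard-normal CDF. PTP is the posterior probability that
the true density change has the opposite sign of the point estimate — a
Bayesian tail probability, maximal at 0.5, reported without any
multiple-testing correction (it is not a frequentist p-value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceComparison",
    "normalize_log_density",
    "log_fold_change",
    "posterior_tail_probability",
    "classify_significance",
    "summarize_by_group",
    "compare_abundance",
]

DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_PTP_THRESHOLD = 1e-3


@dataclass
class AbundanceComparison:
    """Per-cell-state differential-abundance result for one ordered pair."""

    condition_from: str
    condition_to: str
    lfc: np.ndarray  # Delta per state, natural log
    ptp: np.ndarray
    combined_sd: np.ndarray  # sqrt(sigma_a^2 + sigma_b^2)
    significant: np.ndarray | None = None
    direction: np.ndarray | None = None  # {"increase", "decrease", "none"}
    thresholds: tuple[float, float] | None = None
    cell_ids: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.lfc)
        ids = (
            self.cell_ids
            if self.cell_ids is not None
            else np.array([str(i) for i in range(n)], dtype=object)
        )
        with np.errstate(divide="ignore"):
            neg_log10 = -np.log10(self.ptp)
        return pd.DataFrame(
            {
                "cell_id": ids,
                "condition_from": self.condition_from,
                "condition_to": self.condition_to,
                "lfc": self.lfc,
                "ptp": self.ptp,
                "neg_log10_ptp": neg_log10,
                "significant": self.significant
                if self.significant is not None
                else np.zeros(n, dtype=bool),
                "direction": self.direction
                if self.direction is not None
                else np.full(n, "none", dtype=object),
            }
        )


def normalize_log_density(mu: np.ndarray, n_cells: int) -> np.ndarray:
    """mu - log(N): converts log cells/volume to log fraction-of-cells/volume."""
    if n_cells <= 0:
        raise ValueError(f"n_cells must be positive, got {n_cells}")
    return np.asarray(mu, dtype=float) - np.log(n_cells)


def log_fold_change(
    mu_a: np.ndarray, mu_b: np.ndarray, n_a: int, n_b: int
) -> np.ndarray:
    """Delta = (mu_b - mu_a) - log(N_a / N_b); antisymmetric under swapping."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_b = np.asarray(mu_b, dtype=float)
    if mu_a.shape != mu_b.shape:
        raise ValueError(f"shape mismatch: {mu_a.shape} vs {mu_b.shape}")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("cell counts must be positive")
    return (mu_b - mu_a) - (np.log(n_a) - np.log(n_b))


def posterior_tail_probability(
    delta: np.ndarray, sd_a: np.ndarray, sd_b: np.ndarray
) -> np.ndarray:
    """PTP = Phi(-|Delta| / sqrt(sd_a^2 + sd_b^2)), in (0, 0.5].

    Degenerate zero-uncertainty states return 0 where Delta != 0 and 0.5
    where Delta == 0.
    """
    delta = np.asarray(delta, dtype=float)
    sd_a = np.asarray(sd_a, dtype=float)
    sd_b = np.asarray(sd_b, dtype=float)
    if np.any(sd_a < 0) or np.any(sd_b < 0):
        raise ValueError("predictive standard deviations must be non-negative")
    combined = np.sqrt(sd_a**2 + sd_b**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(delta) / combined
    zero_sd = combined == 0
    if np.ndim(z) == 0:
        z = np.asarray(z)
    z = np.where(zero_sd & (delta == 0), 0.0, z)  # -> PTP 0.5
    ptp = ndtr(-z)  # Phi(-|z|); Phi(-inf) = 0 handles sd=0, delta!=0
    return ptp


def classify_significance(
    comparison: AbundanceComparison,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    ptp_threshold: float = DEFAULT_PTP_THRESHOLD,
) -> AbundanceComparison:
    """Flag states with |Delta| > lfc_threshold and PTP < ptp_threshold."""
    if lfc_threshold <= 0 or ptp_threshold <= 0:
        raise ValueError("thresholds must be positive")
    sig = (np.abs(comparison.lfc) > lfc_threshold) & (
        comparison.ptp < ptp_threshold
    )
    direction = np.full(len(sig), "none", dtype=object)
    direction[sig & (comparison.lfc > 0)] = "increase"
    direction[sig & (comparison.lfc < 0)] = "decrease"
    comparison.significant = sig
    comparison.direction = direction
    comparison.thresholds = (lfc_threshold, ptp_threshold)
    return comparison


def summarize_by_group(
    comparison: AbundanceComparison, groups: np.ndarray
) -> pd.DataFrame:
    """Counts and fractions of significant increase/decrease per group."""
    if comparison.significant is None or comparison.direction is None:
        raise ValueError("run classify_significance first")
    groups = np.asarray(groups)
    if len(groups) != len(comparison.lfc):
        raise ValueError("groups must align with cells")
    rows = []
    for grp in pd.unique(groups):
        mask = groups == grp
        n = int(mask.sum())
        if n == 0:
            logger.warning("empty group %r", grp)
        d = comparison.direction[mask]
        n_inc = int(np.sum(d == "increase"))
        n_dec = int(np.sum(d == "decrease"))
        n_none = n - n_inc - n_dec
        rows.append(
            {
                "group": grp,
                "n_cells": n,
                "n_increase": n_inc,
                "n_decrease": n_dec,
                "n_nonsignificant": n_none,
                "frac_increase": n_inc / n if n else 0.0,
                "frac_decrease": n_dec / n if n else 0.0,
                "frac_nonsignificant": n_none / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def compare_abundance(
    density_a,
    density_b,
    states: np.ndarray,
    *,
    cell_ids: np.ndarray | None = None,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    ptp_threshold: float = DEFAULT_PTP_THRESHOLD,
) -> AbundanceComparison:
    """Full DA comparison of two fitted density estimates at given states."""
    mu_a, sd_a = density_a.predict(states)
    mu_b, sd_b = density_b.predict(states)
    delta = log_fold_change(mu_a, mu_b, density_a.n_cells, density_b.n_cells)
    ptp = posterior_tail_probability(delta, sd_a, sd_b)
    comparison = AbundanceComparison(
        condition_from=density_a.condition or "a",
        condition_to=density_b.condition or "b",
        lfc=delta,
        ptp=ptp,
        combined_sd=np.sqrt(sd_a**2 + sd_b**2),
        cell_ids=cell_ids,
    )
    return classify_significance(comparison, lfc_threshold, ptp_threshold)
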