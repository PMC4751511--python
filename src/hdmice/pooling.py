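"""Post-imputation analysis models and Rubin's-rule combination.

Each completed dataset is analysed with an ordinary regression model
(Gaussian OLS or logistic MLE); the M per-dataset estimates are then pooled
with the classic combining rules: pooled point estimate q_bar, within-
imputation variance W, between-imputation variance B, total variance
T = W + (1 + 1/M) B, and a t reference distribution with
nu = (M - 1) (1 + W / ((1 + 1/M) B))^2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data import IncompleteMatrix

__all__ = [
    "AnalysisEstimate",
    "PooledEstimate",
    "fit_analysis_model",
    "rubin_pool",
    "pool_coefficient",
    "complete_case_fit",
]


@dataclass
class AnalysisEstimate:
    """Point estimates and model-based standard errors from one dataset.

    ``coefficients`` and ``standard_errors`` are ordered intercept first,
    then the covariates in the order supplied.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    df_residual: int
    family: str = "gaussian"


@dataclass
class PooledEstimate:
    """Rubin's-rule combination for a single scalar parameter."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float


def fit_analysis_model(
    dataset: np.ndarray,
    outcome: int,
    covariates: Sequence[int],
    family: str = "gaussian",
) -> AnalysisEstimate:
    """Fit the analysis model on one completed dataset.

    Gaussian uses OLS with the unbiased (n - k) residual-variance
    denominator; binomial uses logistic maximum likelihood.
    """
    dataset = np.asarray(dataset, dtype=float)
    y = dataset[:, outcome]
    X = sm.add_constant(dataset[:, list(covariates)], has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear covariates in analysis model")
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
    elif family == "binomial":
        try:
            res = sm.Logit(y, X).fit(disp=0)
        except Exception as exc:
            raise RuntimeError(
                "logistic fit failed (possible separation); consider a "
                "complete-case style caveat for this dataset"
            ) from exc
    else:
        raise ValueError("family must be 'gaussian' or 'binomial'")
    return AnalysisEstimate(
        np.asarray(res.params, dtype=float),
        np.asarray(res.bse, dtype=float),
        int(res.df_resid),
        family,
    )


def rubin_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    confidence: float = 0.95,
) -> PooledEstimate:
    """Combine M (estimate, squared-SE) pairs by Rubin's rules.

    When the between-imputation variance is exactly zero the degrees of
    freedom are infinite and normal quantiles are used.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    M = q.size
    if M < 2:
        raise ValueError("pooling requires multiple imputations (M >= 2)")
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / M) * B
    if B > 0:
        df = (M - 1) * (1.0 + W / ((1.0 + 1.0 / M) * B)) ** 2
        quantile = stats.t.ppf(0.5 + confidence / 2.0, df)
        p = 2.0 * stats.t.sf(abs(qbar) / np.sqrt(T), df)
    else:
        df = np.inf
        quantile = stats.norm.ppf(0.5 + confidence / 2.0)
        p = 2.0 * stats.norm.sf(abs(qbar) / np.sqrt(T))
    half = quantile * np.sqrt(T)
    return PooledEstimate(qbar, W, B, T, df, qbar - half, qbar + half, float(p))


def pool_coefficient(
    fits: Sequence[AnalysisEstimate], index: int, confidence: float = 0.95
) -> PooledEstimate:
    """Pool one coefficient across the M per-dataset analysis fits."""
    return rubin_pool(
        [f.coefficients[index] for f in fits],
        [f.standard_errors[index] ** 2 for f in fits],
        confidence,
    )


def complete_case_fit(
    data: IncompleteMatrix,
    outcome: int,
    covariates: Sequence[int],
    family: str = "gaussian",
) -> AnalysisEstimate:
    """Drop every row with a missing outcome or covariate, then fit."""
    cols = [outcome] + list(covariates)
    complete = data.mask[:, cols].all(axis=1)
    n_complete = int(complete.sum())
    if n_complete < len(covariates) + 2:
        raise ValueError(
            f"too few complete rows for a complete-case fit: {n_complete}"
        )
    return fit_analysis_model(data.values[complete], outcome, covariates, family)
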