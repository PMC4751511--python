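"""Monte-Carlo evaluation harness: data generation, MAR masking, metrics.

The synthetic design emulates a high-dimensional regression study with a
general missing-data pattern.  Each replicate dataset has n rows and p
covariates plus a fully observed outcome y:

* ``z4 .. zp`` are multivariate normal with mean 0 and a first-order
  autoregressive covariance, ``cov(z_i, z_j) = rho^|i-j|``;
* a common true active set S of cardinality q (the first q columns of the
  AR(1) block, ``{z4, ..., z_{3+q}}``) drives the three partially observed
  variables: ``z_j ~ Normal(alpha * sum_{k in S} z_k, 1)`` independently
  for j = 1, 2, 3;
* the outcome is ``y = beta1 z1 + beta2 z2 + beta3 z3 + eps`` with
  ``eps ~ Normal(0, sigma_y^2)`` and beta = (1, 1, 1).

Missingness is imposed on z1..z3 only, through independent logistic models
on fully observed quantities (y and z4), hence missing at random; the
common intercept is calibrated by bisection so that about 40% of rows have
at least one missing cell.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data import IncompleteMatrix
from .engine import multiple_impute
from .imputers import IMPUTER_NAMES, make_imputer, mi_true_imputer
from .penalties import PenaltySpec
from .pooling import complete_case_fit, fit_analysis_model, pool_coefficient

__all__ = [
    "SimConfig",
    "ar1_covariance",
    "generate_complete_data",
    "impose_mar_missingness",
    "calibrate_missingness",
    "run_study",
]

_TRUE_BETA = 1.0  # beta1 = beta2 = beta3 = 1 in the generative model


@dataclass
class SimConfig:
    """All knobs of one simulation scenario.

    ``phi_slopes`` are the coefficients of (y, z4) in each missingness
    logit; ``phi_intercepts`` are the three intercepts (calibrated to the
    target incomplete-row rate when left ``None``).
    """

    n: int = 100
    p: int = 200
    q: int = 4
    rho: float = 0.1
    alpha: float = 1.0
    beta: tuple = (1.0, 1.0, 1.0)
    sigma_y: float = 6.25
    phi_slopes: tuple = (1.0, 1.0)
    phi_intercepts: Optional[tuple] = None
    target_missing_rate: float = 0.40
    n_mc: int = 200
    M: int = 10
    T: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.q > self.p - 3:
            raise ValueError("q must be <= p - 3")
        if not (0 < self.target_missing_rate < 1):
            raise ValueError("target_missing_rate must lie in (0, 1)")

    @property
    def true_active_set(self) -> np.ndarray:
        """Column indices of S = {z4, ..., z_{3+q}} (0-based: 3 .. q+2)."""
        return np.arange(3, 3 + self.q)

    @property
    def outcome_col(self) -> int:
        return self.p


def ar1_covariance(dim: int, rho: float) -> np.ndarray:
    """AR(1) covariance: entry (i, j) equals rho^|i-j|."""
    if dim < 1 or not abs(rho) < 1:
        raise ValueError("need dim >= 1 and |rho| < 1")
    idx = np.arange(dim)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def generate_complete_data(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One complete n x (p+1) dataset; columns z1..zp then y (last)."""
    chol = np.linalg.cholesky(ar1_covariance(cfg.p - 3, cfg.rho))
    Z_block = rng.standard_normal((cfg.n, cfg.p - 3)) @ chol.T
    S_sum = Z_block[:, : cfg.q].sum(axis=1)
    Z123 = cfg.alpha * S_sum[:, None] + rng.standard_normal((cfg.n, 3))
    y = Z123 @ np.asarray(cfg.beta) + cfg.sigma_y * rng.standard_normal(cfg.n)
    return np.column_stack([Z123, Z_block, y])


def _missing_probs(data: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """n x 3 matrix of missingness probabilities for z1..z3 (MAR)."""
    if cfg.phi_intercepts is None:
        raise ValueError("phi_intercepts not set; run calibrate_missingness first")
    y = data[:, cfg.outcome_col]
    z4 = data[:, 3]
    lin = cfg.phi_slopes[0] * y + cfg.phi_slopes[1] * z4
    return expit(np.add.outer(lin, np.asarray(cfg.phi_intercepts, dtype=float)))


def impose_mar_missingness(
    data: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> IncompleteMatrix:
    """Mask z1..z3 by independent logistic missingness models on (y, z4)."""
    probs = _missing_probs(data, cfg)
    mask = np.ones(data.shape, dtype=bool)
    mask[:, :3] = rng.random(probs.shape) >= probs
    names = [f"z{k + 1}" for k in range(cfg.p)] + ["y"]
    return IncompleteMatrix(np.where(mask, data, np.nan), mask, names)


def calibrate_missingness(
    cfg: SimConfig,
    target: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    n_datasets: int = 2000,
    tol: float = 0.01,
) -> SimConfig:
    """Bisect a common logit intercept to hit the target incomplete-row rate.

    The expected fraction of rows with at least one missing cell,
    ``E[1 - prod_j (1 - p_j)]``, is evaluated over ``n_datasets`` simulated
    replicates (it is monotone in the shared intercept, so bisection
    converges).  Returns a copy of ``cfg`` with ``phi_intercepts`` set.
    """
    target = cfg.target_missing_rate if target is None else target
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    # only (y, z4) enter the logits; simulate those marginals in bulk
    N = n_datasets * cfg.n
    chol = np.linalg.cholesky(ar1_covariance(cfg.q, cfg.rho))
    Z_S = rng.standard_normal((N, cfg.q)) @ chol.T
    S_sum = Z_S.sum(axis=1)
    Z123 = cfg.alpha * S_sum[:, None] + rng.standard_normal((N, 3))
    y = Z123 @ np.asarray(cfg.beta) + cfg.sigma_y * rng.standard_normal(N)
    lin = cfg.phi_slopes[0] * y + cfg.phi_slopes[1] * Z_S[:, 0]

    def incomplete_rate(c: float) -> float:
        return float(np.mean(1.0 - (1.0 - expit(c + lin)) ** 3))

    lo, hi = -30.0, 30.0
    if not (incomplete_rate(lo) <= target <= incomplete_rate(hi)):
        raise ValueError(
            f"target {target} unreachable with slopes {cfg.phi_slopes}: "
            f"rate range [{incomplete_rate(lo):.4f}, {incomplete_rate(hi):.4f}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = incomplete_rate(mid)
        if abs(rate - target) <= tol / 10:
            break
        if rate < target:
            lo = mid
        else:
            hi = mid
    return replace(cfg, phi_intercepts=(mid, mid, mid))


def _t_ci_covers(est: float, se: float, df: float, truth: float) -> bool:
    half = stats.t.ppf(0.975, df) * se
    return bool(est - half <= truth <= est + half)


def _run_method(name, cfg, complete, incomplete, rng):
    """One method on one replicate -> list of (coef, est, se, covers)."""
    cov = [0, 1, 2]
    out = cfg.outcome_col
    if name == "GS":
        fit = fit_analysis_model(complete, out, cov)
        return [
            (c, fit.coefficients[c + 1], fit.standard_errors[c + 1],
             _t_ci_covers(fit.coefficients[c + 1], fit.standard_errors[c + 1],
                          fit.df_residual, _TRUE_BETA))
            for c in range(3)
        ]
    if name == "CC":
        fit = complete_case_fit(incomplete, out, cov)
        return [
            (c, fit.coefficients[c + 1], fit.standard_errors[c + 1],
             _t_ci_covers(fit.coefficients[c + 1], fit.standard_errors[c + 1],
                          fit.df_residual, _TRUE_BETA))
            for c in range(3)
        ]
    if name == "mi-true":
        imputer = mi_true_imputer(cfg.true_active_set, out)
    else:
        imputer = make_imputer(name, PenaltySpec(penalty=name.split("-", 1)[1]))
    ensemble = multiple_impute(incomplete, imputer, M=cfg.M, T=cfg.T, rng=rng)
    fits = [fit_analysis_model(d, out, cov) for d in ensemble.datasets]
    rows = []
    for c in range(3):
        pooled = pool_coefficient(fits, c + 1)
        rows.append(
            (c, pooled.estimate, np.sqrt(pooled.total_var),
             pooled.ci_low <= _TRUE_BETA <= pooled.ci_high)
        )
    return rows


def run_study(
    cfg: SimConfig,
    methods: Sequence[str],
    max_failure_rate: float = 0.05,
) -> pd.DataFrame:
    """Run the full Monte-Carlo comparison and tabulate the five metrics.

    For each replicate: generate complete data, impose MAR missingness,
    run every method, and fit / pool the analysis model y ~ z1 + z2 + z3.
    Aggregates per (method, coefficient): bias, mean SE, Monte-Carlo SD,
    MSE and 95%-CI coverage.  Per-replicate method failures are logged and
    excluded; a method failing on more than ``max_failure_rate`` of the
    replicates aborts the run.
    """
    valid = {"GS", "CC"} | set(IMPUTER_NAMES)
    unknown = set(methods) - valid
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {sorted(valid)}")
    if cfg.phi_intercepts is None:
        cfg = calibrate_missingness(cfg)

    records: list[dict] = []
    failures = {m: 0 for m in methods}
    for rep in range(cfg.n_mc):
        seq = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(rep,))
        rng = np.random.default_rng(seq)
        complete = generate_complete_data(cfg, rng)
        incomplete = impose_mar_missingness(complete, cfg, rng)
        for name in methods:
            method_rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=cfg.seed, spawn_key=(rep, zlib.crc32(name.encode()))
                )
            )
            try:
                rows = _run_method(name, cfg, complete, incomplete, method_rng)
            except Exception as exc:
                failures[name] += 1
                warnings.warn(f"{name} failed on replicate {rep}: {exc}", stacklevel=2)
                continue
            for c, est, se, covers in rows:
                records.append(
                    {"method": name, "rep": rep, "coefficient": c + 1,
                     "estimate": est, "se": se, "covers": covers}
                )
    for name, count in failures.items():
        if count > max_failure_rate * cfg.n_mc:
            raise RuntimeError(f"{name} failed on {count}/{cfg.n_mc} replicates")

    per_rep = pd.DataFrame.from_records(records)
    rows = []
    for (name, c), g in per_rep.groupby(["method", "coefficient"], sort=False):
        est = g["estimate"].to_numpy()
        rows.append(
            {
                "method": name,
                "coefficient": int(c),
                "bias": float(est.mean() - _TRUE_BETA),
                "mean_se": float(g["se"].mean()),
                "mc_sd": float(est.std(ddof=1)),
                "mse": float(np.mean((est - _TRUE_BETA) ** 2)),
                "coverage": float(g["covers"].mean()),
                "n_reps": int(len(g)),
            }
        )
    order = {m: i for i, m in enumerate(methods)}
    rows.sort(key=lambda r: (order[r["method"]], r["coefficient"]))
    return pd.DataFrame(rows)
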