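"""Column-level imputation strategies for high-dimensional chained equations.

Two strategies built on penalized regression:

* **DURR** (direct use of regularized regression): bootstrap the current
  completed data, fit a CV-tuned penalized regression of the target column
  on all other columns, and draw imputations from the Gaussian predictive
  distribution at the bootstrap estimate.  The bootstrap step makes the
  coefficient estimate a random draw, so imputations are proper.
* **IURR** (indirect use): the penalized fit is used only to trim the
  predictor set (the active set); an OLS refit on the trimmed set provides
  the likelihood, and (sigma^2*, beta*) are drawn from the standard
  normal-inverse-chi-square posterior under a flat prior before drawing
  imputations.  A fresh parameter draw is taken at every iteration.

``mi_true`` is the simulation-only reference imputer that skips trimming
and conditions directly on a known active set plus the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import ChainState, IncompleteMatrix
from .penalties import PenaltySpec, active_set, fit_penalized

__all__ = [
    "durr_impute_column",
    "iurr_impute_column",
    "mi_true_impute_column",
    "norm_posterior_draw",
    "make_imputer",
    "mi_true_imputer",
    "IMPUTER_NAMES",
]


@dataclass
class DrawnParameters:
    """One posterior draw (beta including intercept first, and sigma^2)."""

    beta_star: np.ndarray
    sigma2_star: float


def _other_columns(p: int, j: int) -> np.ndarray:
    return np.array([k for k in range(p) if k != j])


def durr_impute_column(
    state: ChainState,
    data: IncompleteMatrix,
    j: int,
    spec: PenaltySpec,
    rng: np.random.Generator,
    fit_rows: str = "all",
    resample: bool = True,
    predictive_noise: bool = True,
) -> np.ndarray:
    """Impute the missing cells of column ``j`` by the bootstrap-penalized rule.

    A bootstrap sample of n rows is drawn from the current *completed*
    data and the penalized model of z_j on Z_{-j} is fitted on it
    (``fit_rows="observed"`` restricts the fit to bootstrap rows whose z_j
    was originally observed, for sensitivity checks; the default refits on
    every bootstrap row, so previous imputations feed back into the
    estimate).  Missing cells of the original data are then drawn from
    Normal(x'beta_hat, sigma_hat^2) with sigma_hat^2 the fit's mean
    squared residual.

    ``resample=False`` (identity bootstrap) and ``predictive_noise=False``
    turn off the two stochastic steps for diagnostics: together with a
    fixed lambda of 0 the imputations collapse to OLS fitted values.
    """
    missing = ~data.mask[:, j]
    if not missing.any():
        return np.empty(0)
    n = data.n
    others = _other_columns(data.p, j)
    W = state.completed
    min_rows = max(spec.cv_folds, 10)

    for attempt in range(2):
        boot = rng.integers(n, size=n) if resample else np.arange(n)
        if fit_rows == "all":
            train = boot
        else:
            train = boot[data.mask[boot, j]]
        if train.size >= min_rows:
            break
    else:
        raise ValueError(
            f"insufficient observed rows in bootstrap for column {j}: "
            f"{train.size} < {min_rows}"
        )

    model = fit_penalized(W[train, j], W[np.ix_(train, others)], spec, rng)
    mu = model.predict(W[np.ix_(np.flatnonzero(missing), others)])
    if not predictive_noise:
        return mu
    return mu + model.residual_scale * rng.standard_normal(mu.shape[0])


def norm_posterior_draw(
    y: np.ndarray, X: np.ndarray, rng: np.random.Generator
) -> DrawnParameters:
    """Flat-prior normal-inverse-chi-square draw for a Gaussian linear model.

    ``X`` excludes the intercept, which is prepended internally.  Draws
    sigma^2* = RSS / chi2(nu) with nu = n - k - 1, then
    beta* ~ Normal(beta_OLS, sigma^2* (X'X)^-1).
    """
    n = y.shape[0]
    Xi = np.column_stack([np.ones(n), X])
    k = Xi.shape[1] - 1
    nu = n - k - 1
    if nu <= 0:
        raise ValueError(f"active set too large for refit: n={n}, k={k}")
    beta_hat, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ beta_hat
    rss = float(resid @ resid)
    sigma2_star = rss / rng.chisquare(nu) if rss > 0 else 0.0
    XtX = Xi.T @ Xi
    # lower-triangular factor of (X'X)^-1 via the Cholesky of X'X
    L = np.linalg.cholesky(XtX)
    A = np.linalg.solve(L.T, np.eye(Xi.shape[1]))  # A A' = (X'X)^-1
    beta_star = beta_hat + np.sqrt(sigma2_star) * (A @ rng.standard_normal(Xi.shape[1]))
    return DrawnParameters(beta_star, sigma2_star)


def _draw_imputations(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    draw = norm_posterior_draw(y_obs, X_obs, rng)
    mu = draw.beta_star[0] + X_mis @ draw.beta_star[1:]
    return mu + np.sqrt(draw.sigma2_star) * rng.standard_normal(X_mis.shape[0])


def _drop_collinear(X: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Return kept column indices; drops smallest-|coefficient| columns first
    (the ordering supplied) until the design with intercept has full rank."""
    n = X.shape[0]
    keep = list(range(X.shape[1]))
    by_importance = list(order)  # ascending importance
    while keep:
        Xi = np.column_stack([np.ones(n), X[:, keep]])
        if np.linalg.matrix_rank(Xi) == Xi.shape[1]:
            return np.array(keep, dtype=int)
        drop = next(k for k in by_importance if k in keep)
        keep.remove(drop)
        warnings.warn("dropped a collinear predictor from the refit", stacklevel=3)
    return np.array([], dtype=int)


def iurr_impute_column(
    state: ChainState,
    data: IncompleteMatrix,
    j: int,
    spec: PenaltySpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Impute column ``j`` by penalized trimming plus a likelihood refit.

    The penalized regression of the observed z_j on the current Z_{-j}
    selects the active set; the set is capped at
    ``min(r_j - 3, r_j // 2)`` (least-important predictors dropped first)
    so the chi-square degrees of freedom stay positive; then the refit and
    posterior predictive draw are delegated to :func:`norm_posterior_draw`.
    """
    missing = ~data.mask[:, j]
    if not missing.any():
        return np.empty(0)
    obs = data.mask[:, j]
    others = _other_columns(data.p, j)
    W = state.completed
    y_obs = W[obs, j]
    X_obs_full = W[np.ix_(np.flatnonzero(obs), others)]

    model = fit_penalized(y_obs, X_obs_full, spec, rng)
    sel = np.array(active_set(model), dtype=int)

    r_j = int(obs.sum())
    cap = min(r_j - 3, r_j // 2)
    if cap < 0:
        raise ValueError(f"too few observed rows ({r_j}) in column {j}")
    if sel.size > cap:
        mag = np.abs(model.coefficients[sel])
        sel = sel[np.argsort(-mag, kind="stable")[:cap]]
        sel.sort()

    X_obs = X_obs_full[:, sel]
    X_mis = W[np.ix_(np.flatnonzero(missing), others)][:, sel]
    if sel.size:
        order = np.argsort(np.abs(model.coefficients[sel]), kind="stable")
        kept = _drop_collinear(X_obs, order)
        X_obs, X_mis = X_obs[:, kept], X_mis[:, kept]
    return _draw_imputations(y_obs, X_obs, X_mis, rng)


def mi_true_impute_column(
    state: ChainState,
    data: IncompleteMatrix,
    j: int,
    predictor_cols: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reference imputer conditioning on a known predictor set (no trimming).

    Identical to the IURR refit-and-draw steps with the active set replaced
    by ``predictor_cols`` (column indices into the full matrix, excluding
    ``j`` itself).
    """
    missing = ~data.mask[:, j]
    if not missing.any():
        return np.empty(0)
    obs = data.mask[:, j]
    cols = np.array([k for k in predictor_cols if k != j], dtype=int)
    W = state.completed
    y_obs = W[obs, j]
    X_obs = W[np.ix_(np.flatnonzero(obs), cols)]
    X_mis = W[np.ix_(np.flatnonzero(missing), cols)]
    if cols.size:
        kept = _drop_collinear(X_obs, np.arange(cols.size))
        X_obs, X_mis = X_obs[:, kept], X_mis[:, kept]
    return _draw_imputations(y_obs, X_obs, X_mis, rng)


_PENALTY_BY_SUFFIX = {"lasso": "lasso", "enet": "enet", "alasso": "alasso"}

IMPUTER_NAMES = tuple(
    f"{family}-{pen}" for family in ("durr", "iurr") for pen in _PENALTY_BY_SUFFIX
) + ("mi-true",)


def make_imputer(name: str, spec: PenaltySpec = None, **kwargs):
    """Build a column imputer callable from a registered name.

    Names: ``durr-lasso``, ``durr-enet``, ``durr-alasso``, ``iurr-lasso``,
    ``iurr-enet``, ``iurr-alasso``.  (``mi-true`` needs the true predictor
    set; use :func:`mi_true_imputer`.)
    """
    try:
        family, pen = name.split("-", 1)
        penalty = _PENALTY_BY_SUFFIX[pen]
    except (ValueError, KeyError):
        raise ValueError(f"unknown imputer {name!r}; choose from {IMPUTER_NAMES}") from None
    if spec is None:
        spec = PenaltySpec(penalty=penalty, **kwargs)
    if family == "durr":
        return lambda state, data, j, rng: durr_impute_column(state, data, j, spec, rng)
    if family == "iurr":
        return lambda state, data, j, rng: iurr_impute_column(state, data, j, spec, rng)
    raise ValueError(f"unknown imputer family {family!r}")


def mi_true_imputer(true_set: np.ndarray, outcome_col: int, include_other_incomplete: bool = True):
    """Imputer conditioning on the true active set plus the outcome.

    When ``include_other_incomplete`` (default), the other incomplete
    columns' current values are also conditioned on, mirroring the usual
    chained-equations practice of using all other variables.
    """
    base = list(true_set) + [outcome_col]

    def imputer(state, data, j, rng):
        cols = list(base)
        if include_other_incomplete:
            cols += [k for k in data.incomplete_columns if k != j and k not in cols]
        return mi_true_impute_column(state, data, j, np.array(sorted(set(cols))), rng)

    return imputer
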