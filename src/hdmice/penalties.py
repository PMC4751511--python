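"""Cross-validation-tuned lasso, elastic-net and adaptive-lasso fits.

This is the shared engine behind both regularized imputation strategies.
The penalized objective follows the standard coordinate-descent convention

    (1 / 2n) * ||y - b0 - X b||^2  +  lam * m * ||b||_1  +  lam * (1 - m) / 2 * ||b||^2

with mixing weight ``m`` (``m = 1`` is the pure lasso).  With a single
standardized predictor this reduces to the soft-threshold solution
``sign(b_ols) * max(|b_ols| - lam, 0)``, which the test suite uses as an
independent oracle.

Predictors are standardized internally (mean 0, unit population variance)
before penalization and coefficients are mapped back to the original scale,
because the penalties are scale-sensitive.  Tuning is K-fold CV minimizing
mean squared prediction error over a log-spaced grid of 100 lambdas from
``lam_max`` (the smallest fully-shrinking lambda) down to ``1e-3 * lam_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV, RidgeCV
from sklearn.model_selection import KFold

__all__ = [
    "PenaltySpec",
    "FittedPenalizedModel",
    "fit_penalized",
    "adaptive_weights",
    "active_set",
    "InsufficientRowsError",
]

#: Weight assigned to a predictor whose initial adaptive-lasso estimate is
#: exactly zero; large enough that the predictor is never selected.
ZERO_WEIGHT_CAP = 1e12

_PENALTIES = ("lasso", "enet", "alasso")


class InsufficientRowsError(ValueError):
    """Too few rows to run cross-validation (or to fit at all)."""


@dataclass
class PenaltySpec:
    """Penalty family and tuning contract for a penalized imputation model.

    Parameters
    ----------
    penalty
        One of ``"lasso"``, ``"enet"`` (elastic net) or ``"alasso"``
        (adaptive lasso).
    mixing
        Elastic-net mixing weight in (0, 1]; 1 means pure lasso.  Defaults
        to 0.5 for ``"enet"`` and 1.0 otherwise.
    gamma
        Adaptive-lasso weight exponent (> 0).
    lambda_grid
        ``"auto"`` for the data-driven 100-point grid, an explicit strictly
        decreasing sequence, or a single value for a fixed-lambda fit
        without cross-validation.
    cv_folds
        Number of CV folds (>= 2).
    standardize
        Standardize predictors internally before penalization.
    """

    penalty: str = "lasso"
    mixing: float = None  # type: ignore[assignment]
    gamma: float = 1.0
    lambda_grid: Union[str, float, Sequence[float]] = "auto"
    cv_folds: int = 5
    standardize: bool = True
    cv_rule: str = "1se"
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    cd_tol: float = 1e-3
    cd_selection: str = "random"
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.penalty not in _PENALTIES:
            raise ValueError(f"penalty must be one of {_PENALTIES}")
        if self.mixing is None:
            self.mixing = 0.5 if self.penalty == "enet" else 1.0
        if not (0.0 < self.mixing <= 1.0):
            raise ValueError("mixing must lie in (0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_rule not in ("min", "1se"):
            raise ValueError("cv_rule must be 'min' or '1se'")
        if not isinstance(self.lambda_grid, str):
            g = np.atleast_1d(np.asarray(self.lambda_grid, dtype=float))
            if g.size == 1:
                if g[0] < 0:
                    raise ValueError("fixed lambda must be nonnegative")
            elif np.any(g <= 0) or np.any(np.diff(g) >= 0):
                raise ValueError("explicit lambda_grid must be positive and strictly decreasing")


@dataclass
class FittedPenalizedModel:
    """Result of a penalized (or limiting OLS) fit on complete rows."""

    intercept: float
    coefficients: np.ndarray
    lambda_selected: float
    residual_scale: float
    n_train: int
    family: str = "gaussian"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients


def _validate_xy(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X must have the same number of rows")
    if y.shape[0] < 2:
        raise InsufficientRowsError("need at least 2 rows")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing entries are not allowed in a penalized fit")
    return y, X


def adaptive_weights(y: np.ndarray, X: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Per-coefficient adaptive-lasso weights ``w_k = 1 / |b_init_k|^gamma``.

    The initial estimator is ridge regression with a CV-chosen penalty when
    ``p >= n`` (where OLS does not exist or is unstable) and OLS otherwise.
    A zero initial coefficient maps to the finite cap ``ZERO_WEIGHT_CAP`` so
    the predictor is effectively excluded from the penalized fit.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] == 0:
        raise ValueError("empty input")
    n, p = X.shape
    if p >= n:
        init = RidgeCV(alphas=np.logspace(-3, 3, 25)).fit(X, y)
        beta0 = init.coef_
    else:
        Xi = np.column_stack([np.ones(n), X])
        beta0 = np.linalg.lstsq(Xi, y, rcond=None)[0][1:]
    return weights_from_initial(beta0, gamma)


def weights_from_initial(beta0: np.ndarray, gamma: float) -> np.ndarray:
    """Turn initial coefficient estimates into capped adaptive weights."""
    beta0 = np.abs(np.asarray(beta0, dtype=float))
    with np.errstate(divide="ignore"):
        w = 1.0 / beta0**gamma
    return np.minimum(w, ZERO_WEIGHT_CAP)


def active_set(model: FittedPenalizedModel, tol: float = 1e-8) -> list[int]:
    """Indices (0-based) of predictors with ``|coefficient| > tol``."""
    return [int(k) for k in np.flatnonzero(np.abs(model.coefficients) > tol)]


def _lambda_max(Xs: np.ndarray, y: np.ndarray, mixing: float) -> float:
    n = y.shape[0]
    lam = np.max(np.abs(Xs.T @ (y - y.mean()))) / (n * mixing)
    return max(lam, 1e-12)


def fit_penalized(
    y: np.ndarray,
    X: np.ndarray,
    spec: PenaltySpec,
    rng: np.random.Generator,
) -> FittedPenalizedModel:
    """Fit a CV-tuned penalized linear regression of ``y`` on ``X``.

    Returns coefficients on the original predictor scale at the
    CV-selected lambda (or at the fixed lambda when ``spec.lambda_grid`` is
    a single value; lambda 0 falls back to least squares).  Constant
    predictor columns receive coefficient 0.  ``residual_scale`` is
    ``sqrt(RSS / n_train)`` on the training rows.

    Raises
    ------
    InsufficientRowsError
        When CV is requested but there are fewer rows than folds.
    """
    y, X = _validate_xy(y, X)
    n, p = X.shape

    coefficients = np.zeros(p)
    if np.ptp(y) == 0.0:
        warnings.warn("all-constant response: returning intercept-only model", stacklevel=2)
        return FittedPenalizedModel(float(y[0]), coefficients, 0.0, 0.0, n)

    # constant columns carry no signal and break standardization
    sd_all = X.std(axis=0)
    keep = np.flatnonzero(sd_all > 0)
    Xk = X[:, keep]
    pk = keep.size

    fixed_lambda = None
    grid = spec.lambda_grid
    if not isinstance(grid, str):
        g = np.atleast_1d(np.asarray(grid, dtype=float))
        if g.size == 1:
            fixed_lambda = float(g[0])

    if pk == 0 or fixed_lambda == 0.0:
        # least-squares limit (or intercept-only when nothing varies)
        Xi = np.column_stack([np.ones(n), Xk])
        beta = np.linalg.lstsq(Xi, y, rcond=None)[0]
        resid = y - Xi @ beta
        coefficients[keep] = beta[1:]
        return FittedPenalizedModel(
            float(beta[0]), coefficients, 0.0, float(np.sqrt(np.mean(resid**2))), n
        )

    if spec.standardize:
        mu = Xk.mean(axis=0)
        sd = Xk.std(axis=0)  # population sd so that mean(xs^2) = 1
    else:
        mu = np.zeros(pk)
        sd = np.ones(pk)
    Xs = (Xk - mu) / sd

    col_scale = np.ones(pk)
    if spec.penalty == "alasso":
        w = adaptive_weights(y, Xs, spec.gamma)
        col_scale = 1.0 / w
        Xs = Xs * col_scale

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if fixed_lambda is not None:
            est = ElasticNet(
                alpha=fixed_lambda,
                l1_ratio=spec.mixing,
                tol=spec.cd_tol,
                max_iter=spec.max_iter,
                selection=spec.cd_selection,
                random_state=int(rng.integers(2**31)),
            ).fit(Xs, y)
            lam_sel = fixed_lambda
        else:
            if isinstance(grid, str):
                lam_max = _lambda_max(Xs, y, spec.mixing)
                alphas = np.geomspace(lam_max, spec.lambda_min_ratio * lam_max, spec.n_lambda)
            else:
                alphas = np.asarray(grid, dtype=float)
            if n < spec.cv_folds:
                raise InsufficientRowsError(
                    f"insufficient rows for CV: {n} rows < {spec.cv_folds} folds"
                )
            folds = KFold(
                n_splits=spec.cv_folds,
                shuffle=True,
                random_state=int(rng.integers(2**31)),
            )
            cv_est = ElasticNetCV(
                alphas=alphas,
                l1_ratio=spec.mixing,
                cv=folds,
                tol=spec.cd_tol,
                max_iter=spec.max_iter,
                selection=spec.cd_selection,
                random_state=int(rng.integers(2**31)),
            ).fit(Xs, y)
            if spec.cv_rule == "1se":
                # glmnet-style one-standard-error rule: the most-penalized
                # lambda whose CV error is within one SE of the minimum
                mse = cv_est.mse_path_.mean(axis=-1)
                se = cv_est.mse_path_.std(axis=-1, ddof=1) / np.sqrt(spec.cv_folds)
                i_min = int(np.argmin(mse))
                ok = np.flatnonzero(mse <= mse[i_min] + se[i_min])
                i_sel = int(ok[0])  # alphas are descending: first = strongest
                lam_sel = float(cv_est.alphas_[i_sel])
                est = ElasticNet(
                    alpha=lam_sel,
                    l1_ratio=spec.mixing,
                    tol=spec.cd_tol,
                    max_iter=spec.max_iter,
                    selection=spec.cd_selection,
                    random_state=int(rng.integers(2**31)),
                ).fit(Xs, y)
            else:
                est = cv_est
                lam_sel = float(cv_est.alpha_)

    beta_s = est.coef_ * col_scale  # undo adaptive rescaling
    resid = y - est.predict(Xs)
    coefficients[keep] = beta_s / sd
    intercept = float(est.intercept_ - np.sum(beta_s * mu / sd))
    return FittedPenalizedModel(
        intercept, coefficients, lam_sel, float(np.sqrt(np.mean(resid**2))), n
    )
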