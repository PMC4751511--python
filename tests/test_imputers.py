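"""Unit and oracle tests for the DURR, IURR and reference imputers."""

import numpy as np
import pytest

from hdmice.data import IncompleteMatrix
from hdmice.engine import initialize_fill
from hdmice.imputers import (
    durr_impute_column,
    iurr_impute_column,
    make_imputer,
    mi_true_impute_column,
    mi_true_imputer,
    norm_posterior_draw,
)
from hdmice.penalties import PenaltySpec


def _toy_problem(rng, n=60, p=6, n_missing=12):
    """Low-dimensional incomplete dataset: z1 depends on z2, z3."""
    X = rng.standard_normal((n, p))
    X[:, 0] = 1.5 * X[:, 1] - X[:, 2] + 0.5 * rng.standard_normal(n)
    mask = np.ones_like(X, dtype=bool)
    mask[rng.choice(n, size=n_missing, replace=False), 0] = False
    return IncompleteMatrix(np.where(mask, X, np.nan), mask)


class TestDurr:
    def test_complete_column_is_noop(self, rng):
        data = IncompleteMatrix(rng.standard_normal((20, 3)))
        state = initialize_fill(data)
        out = durr_impute_column(state, data, 1, PenaltySpec("lasso"), rng)
        assert out.size == 0

    def test_degenerate_mode_matches_ols_fitted_values(self, rng):
        # identity bootstrap + lambda 0 + no predictive noise -> OLS fits
        data = _toy_problem(rng)
        state = initialize_fill(data)
        spec = PenaltySpec("lasso", lambda_grid=[0.0])
        out = durr_impute_column(
            state, data, 0, spec, np.random.default_rng(0),
            fit_rows="observed", resample=False, predictive_noise=False,
        )
        obs = data.mask[:, 0]
        Xi = np.column_stack([np.ones(obs.sum()), state.completed[obs][:, 1:]])
        beta = np.linalg.lstsq(Xi, data.values[obs, 0], rcond=None)[0]
        X_mis = np.column_stack(
            [np.ones((~obs).sum()), state.completed[~obs][:, 1:]]
        )
        assert np.abs(out - X_mis @ beta).max() < 1e-8

    def test_bootstrap_makes_draws_vary_across_seeds(self, rng):
        data = _toy_problem(rng)
        state = initialize_fill(data)
        spec = PenaltySpec("lasso", lambda_grid=0.05)
        a = durr_impute_column(state, data, 0, spec, np.random.default_rng(1))
        b = durr_impute_column(state, data, 0, spec, np.random.default_rng(2))
        assert not np.allclose(a, b)

    def test_predictive_noise_inflates_variance(self, rng):
        # proper imputation: draws spread around the fitted values
        data = _toy_problem(rng)
        state = initialize_fill(data)
        spec = PenaltySpec("lasso", lambda_grid=0.05)
        fitted = durr_impute_column(
            state, data, 0, spec, np.random.default_rng(3),
            resample=False, predictive_noise=False,
        )
        draws = np.array([
            durr_impute_column(state, data, 0, spec, np.random.default_rng(s))
            for s in range(30)
        ])
        assert np.all(draws.std(axis=0) > 0)
        assert draws.var(axis=0).mean() > np.var(fitted) * 0.0  # strictly positive spread
        assert np.abs(draws.mean(axis=0) - fitted).max() < 5 * draws.std(axis=0).max()


class TestIurr:
    def test_full_shrinkage_matches_intercept_only_oracle(self, rng):
        data = _toy_problem(rng)
        state = initialize_fill(data)
        spec = PenaltySpec("lasso", lambda_grid=1e6)
        seed = 77
        out = iurr_impute_column(state, data, 0, spec, np.random.default_rng(seed))

        # independent re-implementation of the intercept-only draw,
        # consuming the rng stream in the same order
        oracle_rng = np.random.default_rng(seed)
        oracle_rng.integers(2**31)  # the fixed-lambda fit's CD seed
        obs = data.mask[:, 0]
        y_obs = data.values[obs, 0]
        r = y_obs.size
        nu = r - 1
        ybar = y_obs.mean()
        rss = np.sum((y_obs - ybar) ** 2)
        sigma2 = rss / oracle_rng.chisquare(nu)
        beta0 = ybar + np.sqrt(sigma2) / np.sqrt(r) * oracle_rng.standard_normal(1)[0]
        expected = beta0 + np.sqrt(sigma2) * oracle_rng.standard_normal(int((~obs).sum()))
        assert np.abs(out - expected).max() < 1e-10

    def test_noiseless_copy_recovered_exactly(self, rng):
        # z1 is an exact copy of z4 on observed rows: the active set finds
        # column 4, the refit has RSS ~ 0, and imputations equal z4
        n = 80
        X = rng.standard_normal((n, 6))
        X[:, 0] = X[:, 3]
        mask = np.ones_like(X, dtype=bool)
        mask[rng.choice(n, 15, replace=False), 0] = False
        data = IncompleteMatrix(np.where(mask, X, np.nan), mask)
        state = initialize_fill(data)
        out = iurr_impute_column(state, data, 0, PenaltySpec("lasso"),
                                 np.random.default_rng(5))
        assert np.abs(out - X[~mask[:, 0], 3]).max() < 1e-6

    def test_parameter_draws_vary_across_seeds(self, rng):
        data = _toy_problem(rng)
        state = initialize_fill(data)
        a = iurr_impute_column(state, data, 0, PenaltySpec("lasso"),
                               np.random.default_rng(1))
        b = iurr_impute_column(state, data, 0, PenaltySpec("lasso"),
                               np.random.default_rng(2))
        assert not np.allclose(a, b)

    def test_active_set_cap_protects_degrees_of_freedom(self, rng):
        # with very few observed rows the selected set must be capped so
        # the chi-square degrees of freedom stay positive
        n, p = 40, 30
        X = rng.standard_normal((n, p))
        X[:, 0] = X[:, 1:6].sum(axis=1) + 0.1 * rng.standard_normal(n)
        mask = np.ones_like(X, dtype=bool)
        mask[rng.choice(n, 26, replace=False), 0] = False  # r_j = 14
        data = IncompleteMatrix(np.where(mask, X, np.nan), mask)
        state = initialize_fill(data)
        out = iurr_impute_column(state, data, 0, PenaltySpec("lasso", cv_folds=3),
                                 np.random.default_rng(0))
        assert out.size == 26 and np.all(np.isfinite(out))


class TestMiTrue:
    def test_noiseless_copy_same_as_iurr(self, rng):
        n = 80
        X = rng.standard_normal((n, 6))
        X[:, 0] = X[:, 3]
        mask = np.ones_like(X, dtype=bool)
        mask[rng.choice(n, 15, replace=False), 0] = False
        data = IncompleteMatrix(np.where(mask, X, np.nan), mask)
        state = initialize_fill(data)
        out = mi_true_impute_column(state, data, 0, np.array([3]),
                                    np.random.default_rng(5))
        assert np.abs(out - X[~mask[:, 0], 3]).max() < 1e-6

    def test_conditioning_set_excludes_target(self, rng):
        data = _toy_problem(rng)
        state = initialize_fill(data)
        # passing the target column itself must be harmless (it is dropped)
        out = mi_true_impute_column(state, data, 0, np.array([0, 1, 2]),
                                    np.random.default_rng(0))
        assert out.size == int((~data.mask[:, 0]).sum())

    def test_imputer_factory_includes_other_incomplete_columns(self, rng):
        X = rng.standard_normal((50, 5))
        mask = np.ones_like(X, dtype=bool)
        mask[:5, 0] = False
        mask[5:8, 1] = False
        data = IncompleteMatrix(np.where(mask, X, np.nan), mask)
        state = initialize_fill(data)
        imputer = mi_true_imputer(np.array([2, 3]), outcome_col=4)
        out = imputer(state, data, 0, np.random.default_rng(0))
        assert out.size == 5


class TestNormPosteriorDraw:
    def test_nu_guard(self, rng):
        X = rng.standard_normal((4, 3))
        y = rng.standard_normal(4)
        with pytest.raises(ValueError, match="active set too large"):
            norm_posterior_draw(y, X, rng)

    def test_registry_names(self):
        with pytest.raises(ValueError, match="unknown imputer"):
            make_imputer("ridge-mice")
        imp = make_imputer("durr-enet")
        assert callable(imp)
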