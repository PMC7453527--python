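"""Spline basis, penalized IRLS, smoothness selection, and diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize, special

from smokegam.errors import ArgumentError, RankDeficiencyError
from smokegam.nb_gam import (
    DesignBundle,
    ModelSpec,
    build_design,
    cubic_regression_spline_basis,
    fit_penalized_nb_glm,
    residual_acf,
    select_smoothness,
)


def make_bundle(y, X, names=None, penalty=None, roles=None):
    n, p = X.shape
    return DesignBundle(
        y=np.asarray(y, dtype=float),
        X=np.asarray(X, dtype=float),
        penalty=np.zeros((p, p)) if penalty is None else penalty,
        col_names=names or [f"x{j}" for j in range(p)],
        roles=roles or {},
        dates=pd.date_range("2015-01-01", periods=n),
        spec=ModelSpec(),
    )


class TestSplineBasis:
    def test_reproduces_linear_function_with_zero_penalty(self):
        x = np.linspace(0, 10, 200)
        X, S, _ = cubic_regression_spline_basis(x, 8)
        y = 2 * x + 1
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(X @ coef, y, atol=1e-8)
        assert coef @ S @ coef == pytest.approx(0.0, abs=1e-10)

    def test_penalty_psd_with_two_zero_eigenvalues(self):
        x = np.linspace(0, 1, 50)
        _, S, _ = cubic_regression_spline_basis(x, 7)
        assert np.allclose(S, S.T)
        vals = np.linalg.eigvalsh(S)
        assert vals.min() > -1e-10
        scale = vals.max()
        assert (np.abs(vals) < 1e-9 * scale).sum() == 2

    def test_interpolation_property(self):
        # column j is 1 at knot j and 0 at the others
        x = np.linspace(0, 1, 11)
        X, _, knots = cubic_regression_spline_basis(x, 5)
        Xk, _, _ = cubic_regression_spline_basis(knots, 5, knots=knots)
        assert np.allclose(Xk, np.eye(5), atol=1e-10)

    def test_c2_continuity_at_knots(self):
        # one-sided finite-difference estimates of the value, first and
        # second derivatives agree across each interior knot; a basis that
        # were only C0/C1 would show O(1) jumps here
        _, _, knots = cubic_regression_spline_basis(np.linspace(0, 1, 30), 6)
        h = 1e-4
        for knot in knots[1:-1]:
            pts = knot + h * np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0])
            B, _, _ = cubic_regression_spline_basis(pts, 6, knots=knots)
            for j in range(6):
                v = B[:, j]
                # second-order one-sided first derivatives at the knot
                d_left = (3 * v[3] - 4 * v[2] + v[1]) / (2 * h)
                d_right = (-3 * v[3] + 4 * v[4] - v[5]) / (2 * h)
                assert d_left == pytest.approx(d_right, abs=1e-4)
                # centered second differences one step either side of the knot
                dd_left = (v[1] - 2 * v[2] + v[3]) / h**2
                dd_right = (v[3] - 2 * v[4] + v[5]) / h**2
                assert dd_left == pytest.approx(dd_right, abs=0.5)

    def test_too_few_points(self):
        with pytest.raises(ArgumentError):
            cubic_regression_spline_basis(np.array([0.0, 1.0, 2.0]), 6)


def _sim_design(seed=0, n=50, p=4):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = rng.normal(0, 0.3, size=p)
    beta[0] = 1.5
    mu = np.exp(X @ beta)
    y = rng.poisson(mu)
    return y.astype(float), X


class TestPenalizedIrls:
    def test_matches_poisson_glm_oracle(self):
        # dispersion -> infinity, no penalty: must equal a Poisson GLM
        y, X = _sim_design(seed=1)
        bundle = make_bundle(y, X)
        fit = fit_penalized_nb_glm(bundle, 0.0, np.inf)
        oracle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        rel = np.abs(fit.beta - oracle.params) / np.maximum(np.abs(oracle.params), 1e-8)
        assert rel.max() <= 1e-8

    def test_intercept_only_closed_form(self):
        y = np.array([2.0, 4.0, 6.0])
        bundle = make_bundle(y, np.ones((3, 1)))
        fit = fit_penalized_nb_glm(bundle, 0.0, 10.0)
        assert fit.beta[0] == pytest.approx(np.log(4.0), abs=1e-8)

    @pytest.mark.parametrize("theta", [0.8, 5.0, 50.0])
    def test_direct_maximization_oracle(self, theta):
        # penalized IRLS at fixed lambda == quasi-Newton maximization of the
        # penalized NB log likelihood, on a <= 12 column design
        rng = np.random.default_rng(42)
        n, p = 120, 8
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        eta = X @ rng.normal(0, 0.25, size=p) + 1.8
        mu = np.exp(eta)
        y = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)
        S = np.zeros((p, p))
        S[2:5, 2:5] = np.eye(3)  # penalize an arbitrary block
        lam = 3.7
        bundle = make_bundle(y, X, penalty=S)
        fit = fit_penalized_nb_glm(bundle, lam, theta, tol=1e-13)

        def negpll(b):
            m = np.exp(np.clip(X @ b, -30, 30))
            ll = np.sum(
                special.gammaln(y + theta)
                - special.gammaln(theta)
                - special.gammaln(y + 1)
                + theta * np.log(theta)
                + y * np.log(m)
                - (y + theta) * np.log(m + theta)
            )
            return -(ll - 0.5 * lam * b @ S @ b)

        def grad(b):
            m = np.exp(np.clip(X @ b, -30, 30))
            g = y - m * (y + theta) / (m + theta)
            return -(X.T @ g - lam * S @ b)

        res = optimize.minimize(
            negpll, np.zeros(p), jac=grad, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 500},
        )
        assert np.abs(fit.beta - res.x).max() <= 1e-6

    def test_infinite_smoothing_collapses_spline_to_line(self, dataset_small):
        ds = dataset_small
        spec = ModelSpec(pm_fraction="pm25", lag_set="0")
        design = build_design(ds.visits, ds.exposures, ds.weather, spec)
        fit = fit_penalized_nb_glm(design, 1e12, 10.0)
        sp = design.spline_cols
        # spline effective dof collapse to the penalty null space (a line)
        assert fit.edf_by_col[sp].sum() + 1.0 == pytest.approx(2.0, abs=0.05)
        smooth = design.X[:, sp] @ fit.beta[sp]
        t = (design.dates - design.dates[0]).days.to_numpy(dtype=float)
        resid = smooth - np.polyval(np.polyfit(t, smooth, 1), t)
        assert np.abs(resid).max() <= 1e-4 * max(np.abs(smooth).max(), 1.0)

    def test_covariance_symmetric_psd(self, fit_small):
        cov = fit_small.cov
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_collinear_design_raises_naming_columns(self):
        y, X = _sim_design(seed=2)
        X = np.column_stack([X, X[:, 1]])  # duplicate a column
        bundle = make_bundle(y, X, names=["intercept", "a", "b", "c", "a_copy"])
        with pytest.raises(RankDeficiencyError) as err:
            fit_penalized_nb_glm(bundle, 0.0, 10.0)
        assert any(name in err.value.columns for name in ("a", "a_copy"))

    def test_scaling_equivariance(self, dataset_small):
        # multiplying the PM scale by c divides the coefficient by c
        ds = dataset_small
        d1 = build_design(ds.visits, ds.exposures, ds.weather,
                          ModelSpec(pm_fraction="pm25", lag_set="0", pm_scale=5.0))
        d2 = build_design(ds.visits, ds.exposures, ds.weather,
                          ModelSpec(pm_fraction="pm25", lag_set="0", pm_scale=10.0))
        f1 = fit_penalized_nb_glm(d1, 10.0, 10.0, tol=1e-13)
        f2 = fit_penalized_nb_glm(d2, 10.0, 10.0, tol=1e-13)
        i1, i2 = d1.roles["pm"][0], d2.roles["pm"][0]
        assert f2.beta[i2] == pytest.approx(2.0 * f1.beta[i1], rel=1e-5)
        assert np.allclose(f1.mu, f2.mu, rtol=1e-6)


class TestSelectSmoothness:
    def test_curved_trend_gets_flexible_spline(self):
        fit = _fit_trend(curved=True)
        assert fit.spline_edf > 2.5

    def test_flat_trend_gets_linear_spline(self):
        fit = _fit_trend(curved=False)
        assert fit.spline_edf == pytest.approx(2.0, abs=0.5)

    def test_optimum_beats_bracketing_grid(self, dataset_small):
        from smokegam.nb_gam import _criterion_value

        ds = dataset_small
        design = build_design(ds.visits, ds.exposures, ds.weather,
                              ModelSpec(pm_fraction="pm25", lag_set="0"))
        fit = select_smoothness(design, n_grid=8, outer_iterations=2)
        lam0, theta = fit.smoothing_parameter, fit.nb_dispersion
        for lam in np.exp(np.linspace(np.log(lam0) - 4, np.log(lam0) + 4, 10)):
            inner = fit_penalized_nb_glm(design, lam, theta)
            other = _criterion_value(design, inner, lam, theta, "reml")
            assert fit.criterion_value <= other + 1e-6

    def test_gcv_criterion_also_works(self, dataset_small):
        ds = dataset_small
        design = build_design(ds.visits, ds.exposures, ds.weather,
                              ModelSpec(pm_fraction="pm25", lag_set="0"))
        fit = select_smoothness(design, criterion="gcv", n_grid=8, outer_iterations=2)
        assert fit.converged and np.isfinite(fit.criterion_value)

    def test_spline_edf_within_bounds(self, fit_small):
        k = fit_small.spec.spline_basis_size
        assert 1.0 <= fit_small.spline_edf <= k + 1e-6

    def test_time_shift_leaves_nonspline_coefficients(self):
        # adding a constant to the time index shifts the auto-placed knots
        # with it: the basis, and hence every coefficient of a model using
        # it, is unchanged
        from smokegam.nb_gam import _centered_spline

        t = np.linspace(0.0, 600.0, 400)
        Xr1, Sr1, _ = cubic_regression_spline_basis(t, 8)
        Xr2, Sr2, _ = cubic_regression_spline_basis(t + 500.0, 8)
        assert np.allclose(Xr1, Xr2, atol=1e-9)
        assert np.allclose(Sr1, Sr2, atol=1e-12)
        X1, S1, _ = _centered_spline(t, 8)
        X2, S2, _ = _centered_spline(t + 500.0, 8)
        rng = np.random.default_rng(6)
        x = rng.normal(size=t.size)
        y = rng.poisson(np.exp(1.5 + 0.2 * x)).astype(float)
        p = X1.shape[1] + 2
        for X_s, S_s in ((X1, S1), (X2, S2)):
            S = np.zeros((p, p))
            S[2:, 2:] = S_s
            bundle = make_bundle(
                y, np.column_stack([np.ones(t.size), x, X_s]), penalty=S,
                roles={"intercept": [0], "x": [1], "spline": list(range(2, p))},
            )
            fit = fit_penalized_nb_glm(bundle, 10.0, 10.0, tol=1e-13)
            assert fit.beta[1] == pytest.approx(0.2, abs=0.1)
            if X_s is X1:
                first = fit.beta.copy()
        assert np.allclose(first, fit.beta, atol=1e-9)


def _fit_trend(curved: bool):
    rng = np.random.default_rng(5)
    n = 600
    t = np.arange(n)
    eta = np.full(n, 2.0) + (0.5 * np.sin(2 * np.pi * t / 300.0) if curved else 0.0)
    y = rng.poisson(np.exp(eta)).astype(float)
    from smokegam.nb_gam import _centered_spline

    Xs, Ss, _ = _centered_spline(t / (n - 1.0), 10)
    X = np.column_stack([np.ones(n), Xs])
    p = X.shape[1]
    S = np.zeros((p, p))
    S[1:, 1:] = Ss
    bundle = DesignBundle(
        y=y, X=X, penalty=S,
        col_names=["intercept"] + [f"spline_{j}" for j in range(Xs.shape[1])],
        roles={"intercept": [0], "spline": list(range(1, p))},
        dates=pd.date_range("2015-01-01", periods=n),
        spec=ModelSpec(),
    )
    return select_smoothness(bundle, n_grid=9, outer_iterations=2)


class TestResidualAcf:
    def test_acf_lag0_is_one(self, fit_small):
        table = residual_acf(fit_small, max_lag=10)
        assert table.loc[0, "acf"] == pytest.approx(1.0)

    def test_white_noise_mostly_inside_band(self, fit_small):
        rng = np.random.default_rng(3)
        fit = fit_small
        fake = fit.deviance_residuals.copy()
        fake[:] = rng.normal(size=len(fake))
        import dataclasses

        wn = dataclasses.replace(fit, deviance_residuals=fake)
        table = residual_acf(wn, max_lag=40)
        frac_inside = (table["acf"].iloc[1:].abs() < table["band"].iloc[1:]).mean()
        assert frac_inside >= 0.85

    def test_ar1_residuals_detected(self, fit_small):
        rng = np.random.default_rng(4)
        n = len(fit_small.deviance_residuals)
        e = np.empty(n)
        e[0] = rng.normal()
        for i in range(1, n):
            e[i] = 0.5 * e[i - 1] + rng.normal() * np.sqrt(0.75)
        import dataclasses

        contaminated = dataclasses.replace(
            fit_small,
            deviance_residuals=pd.Series(e, index=fit_small.deviance_residuals.index),
        )
        table = residual_acf(contaminated, max_lag=5)
        assert table.loc[1, "acf"] == pytest.approx(0.5, abs=0.12)

    def test_max_lag_validation(self, fit_small):
        with pytest.raises(ArgumentError):
            residual_acf(fit_small, max_lag=10**6)


class TestModelSpecValidation:
    def test_bad_fraction(self):
        with pytest.raises(ArgumentError):
            ModelSpec(pm_fraction="pm1")

    def test_bad_scale(self):
        with pytest.raises(ArgumentError):
            ModelSpec(pm_scale=0.0)

    def test_bad_basis(self):
        with pytest.raises(ArgumentError):
            ModelSpec(spline_basis_size=3)

    def test_bad_ar_lags(self):
        with pytest.raises(ArgumentError):
            ModelSpec(ar_lags=(0, 1))

    def test_short_series_clean_error(self):
        from smokegam.synthetic_data import generate_dataset

        ds = generate_dataset(n_days=40, seed=2)
        with pytest.raises(ArgumentError, match="usable rows"):
            build_design(ds.visits, ds.exposures, ds.weather,
                         ModelSpec(pm_fraction="pm25", lag_set="0-6"))
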