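"""Penalized negative-binomial GAM fitting.

The model is a log-link negative-binomial regression with a penalized cubic
regression spline of time plus parametric calendar, weather, autoregressive,
exposure, interaction, and monitor-activity terms.  Fitting is penalized
iteratively reweighted least squares (Fisher scoring) at fixed smoothing
parameter and dispersion; the smoothing parameter is chosen by a Laplace
REML-type criterion (GCV available as a fallback) and the dispersion by
alternating 1-D maximum likelihood updates.

Coefficient covariance is the inverse penalized information matrix (the
Bayesian-style covariance conventional for penalized spline Wald intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

from .errors import ArgumentError, ConvergenceError, RankDeficiencyError, SmokegamError
from .exposure import EXCLUDED, ExposurePanel, lag_tag
from .holidays import DEFAULT_HOLIDAYS, holiday_indicators

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "DesignBundle",
    "GamFit",
    "cubic_regression_spline_basis",
    "build_design",
    "fit_penalized_nb_glm",
    "select_smoothness",
    "residual_acf",
]

TWO_FRACTION = "two_fraction"
_FRACTION_CHOICES = ("pm25", "pmc", "pm10", TWO_FRACTION)


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one model in the fraction x lag grid."""

    pm_fraction: str = "pm25"
    lag_set: str = "0"
    temperature_metric: str = "mean"
    include_rh: bool = False
    pm_scale: float = 5.0
    spline_basis_size: int = 10
    ar_lags: tuple[int, ...] = tuple(range(1, 11))
    holidays: tuple[str, ...] = DEFAULT_HOLIDAYS

    def __post_init__(self) -> None:
        if self.pm_fraction not in _FRACTION_CHOICES:
            raise ArgumentError(f"pm_fraction must be one of {_FRACTION_CHOICES}")
        if self.temperature_metric not in ("min", "mean", "max"):
            raise ArgumentError("temperature_metric must be min, mean, or max")
        if not self.pm_scale > 0:
            raise ArgumentError("pm_scale must be positive")
        if self.spline_basis_size < 4:
            raise ArgumentError("spline_basis_size must be >= 4")
        if any(l < 1 or l > 10 for l in self.ar_lags):
            raise ArgumentError("ar_lags must be a subset of 1..10")
        if self.pm_fraction == TWO_FRACTION and self.lag_set != "0":
            raise ArgumentError("the two-fraction model uses lag 0 only")

    @property
    def label(self) -> str:
        return f"{self.pm_fraction}_{lag_tag(self.lag_set)}"


@dataclass
class DesignBundle:
    """Response, model matrix, spline penalty, and column metadata."""

    y: np.ndarray
    X: np.ndarray
    penalty: np.ndarray  # full p x p, zero outside the spline block
    col_names: list[str]
    roles: dict[str, list[int]]
    dates: pd.DatetimeIndex
    spec: ModelSpec
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def spline_cols(self) -> list[int]:
        return self.roles.get("spline", [])


@dataclass
class GamFit:
    """A fitted model: coefficients, covariance, and diagnostics."""

    beta: np.ndarray
    cov: np.ndarray
    col_names: list[str]
    roles: dict[str, list[int]]
    smoothing_parameter: float
    spline_edf: float
    edf_by_col: np.ndarray
    nb_dispersion: float
    deviance: float
    loglik: float
    iterations: int
    converged: bool
    working_residuals: pd.Series
    deviance_residuals: pd.Series
    fitted: pd.Series
    criterion: str
    criterion_value: float
    spec: ModelSpec | None = None

    @property
    def total_edf(self) -> float:
        return float(self.edf_by_col.sum())

    def coef(self, role: str) -> float:
        idx = self.roles.get(role, [])
        if len(idx) != 1:
            raise ArgumentError(f"role {role!r} does not name a single coefficient")
        return float(self.beta[idx[0]])

    def to_dict(self) -> dict:
        return {
            "col_names": self.col_names,
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "roles": self.roles,
            "smoothing_parameter": self.smoothing_parameter,
            "spline_edf": self.spline_edf,
            "nb_dispersion": self.nb_dispersion,
            "deviance": self.deviance,
            "loglik": self.loglik,
            "iterations": self.iterations,
            "converged": self.converged,
            "criterion": self.criterion,
            "criterion_value": self.criterion_value,
        }


# ---------------------------------------------------------------------------
# Cubic regression spline basis with curvature penalty
# ---------------------------------------------------------------------------

def cubic_regression_spline_basis(x, n_basis: int, knots=None):
    """Knot-value parameterized natural cubic spline basis and its penalty.

    Returns ``(X, S, knots)`` where column j of X evaluates the cardinal
    spline taking value 1 at knot j and 0 at the others, and S is the
    integrated squared second derivative penalty.  The basis reproduces any
    linear function of ``x`` exactly with zero penalty; S is symmetric PSD
    with a two-dimensional null space (constant and linear).
    """
    x = np.asarray(x, dtype=float)
    if n_basis < 4:
        raise ArgumentError("n_basis must be >= 4")
    if knots is None:
        uq = np.unique(x)
        if uq.size < n_basis:
            raise ArgumentError(
                f"need at least {n_basis} distinct points, got {uq.size}"
            )
        knots = np.quantile(uq, np.linspace(0, 1, n_basis))
        knots = np.unique(knots)
        if knots.size < n_basis:
            raise ArgumentError("could not place distinct quantile knots")
    else:
        knots = np.asarray(knots, dtype=float)
        if np.any(np.diff(knots) <= 0):
            raise ArgumentError("knots must be strictly increasing")
    k = knots.size
    h = np.diff(knots)

    # banded systems linking knot values to interior second derivatives
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F = linalg.solve(B, D, assume_a="pos")
    S = D.T @ F
    S = (S + S.T) / 2.0

    Fz = np.zeros((k, k))
    Fz[1:-1] = F  # second derivative of the spline at each knot, per basis fn

    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, k - 2)
    hj = h[j]
    d_lo = x - knots[j]
    d_hi = knots[j + 1] - x
    a_minus = d_hi / hj
    a_plus = d_lo / hj
    c_minus = (d_hi**3 / hj - hj * d_hi) / 6.0
    c_plus = (d_lo**3 / hj - hj * d_lo) / 6.0

    n = x.size
    X = np.zeros((n, k))
    rows = np.arange(n)
    X[rows, j] += a_minus
    X[rows, j + 1] += a_plus
    X += c_minus[:, None] * Fz[j] + c_plus[:, None] * Fz[j + 1]
    return X, S, knots


def _centered_spline(x, n_basis):
    """Basis with the constant direction absorbed (sum-to-zero constraint)."""
    X, S, knots = cubic_regression_spline_basis(x, n_basis)
    c = X.mean(axis=0)
    # orthonormal basis of the null space of c^T
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(len(c))]))
    Z = q[:, 1:]
    Xc = X @ Z
    Sc = Z.T @ S @ Z
    Sc = (Sc + Sc.T) / 2.0
    return Xc, Sc, knots


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(
    visits: pd.Series,
    exposures: ExposurePanel,
    weather: pd.DataFrame,
    spec: ModelSpec,
) -> DesignBundle:
    """Assemble the model matrix, penalty, and row exclusions for one model.

    Rows are dropped when: the tri-state wildfire indicator is EXCLUDED or
    undefined; the exceedance mask fires; any lag average, rolling weather
    control, or AR covariate is undefined (warm-up); or the response is
    missing.  Constant columns (e.g. an always-active monitor indicator)
    are removed and recorded in ``dropped_columns``.
    """
    dates = exposures.dates
    y = visits.reindex(dates)
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, list[int]] = {}

    def add(role: str, name: str, values: np.ndarray) -> None:
        roles.setdefault(role, []).append(len(cols))
        cols[name] = np.asarray(values, dtype=float)

    add("intercept", "intercept", np.ones(len(dates)))
    dow = pd.get_dummies(pd.Series(dates.dayofweek, index=dates))
    dow = dow.reindex(columns=range(7), fill_value=0)
    for d, name in zip(range(1, 7), ("tue", "wed", "thu", "fri", "sat", "sun")):
        add("dow", f"dow_{name}", dow[d].to_numpy(dtype=float))
    hol = holiday_indicators(dates, spec.holidays)
    for name in hol.columns:
        add("holiday", f"hol_{name}", hol[name].to_numpy(dtype=float))

    tdays = (dates - dates[0]).days.to_numpy(dtype=float)
    tscaled = tdays / max(tdays.max(), 1.0)
    Xs, Ss, _ = _centered_spline(tscaled, spec.spline_basis_size)
    for jcol in range(Xs.shape[1]):
        add("spline", f"spline_{jcol}", Xs[:, jcol])

    temp_col = f"temp_{spec.temperature_metric}"
    if temp_col not in weather.columns:
        raise ArgumentError(f"weather table lacks column {temp_col!r}")
    rolltemp = weather[temp_col].reindex(dates).rolling(7, min_periods=7).mean()
    add("temp", "rolltemp7", rolltemp.to_numpy())
    if spec.include_rh:
        if "rh" not in weather.columns:
            raise ArgumentError("weather table lacks column 'rh'")
        rollrh = weather["rh"].reindex(dates).rolling(7, min_periods=7).mean()
        add("rh", "rollrh7", rollrh.to_numpy())

    for lag in spec.ar_lags:
        add("ar", f"ar_log1p_lag{lag}", np.log1p(y.shift(lag)).to_numpy())

    drop = pd.Series(False, index=dates)
    if spec.pm_fraction == TWO_FRACTION:
        wf = exposures.wf_indicator("0")
        pm25 = exposures.concentration("pm25", "0") / spec.pm_scale
        pmc = exposures.concentration("pmc", "0") / spec.pm_scale
        wf01 = wf.where(wf != EXCLUDED).to_numpy()
        add("pm", "pm25_lag0", pm25.to_numpy())
        add("pm_x_wf", "pm25_lag0_x_wf", pm25.to_numpy() * wf01)
        add("pm2", "pmc_lag0", pmc.to_numpy())
        add("pm2_x_wf", "pmc_lag0_x_wf", pmc.to_numpy() * wf01)
        add("wf", "wf_lag0", wf01)
        drop |= (wf == EXCLUDED) | wf.isna() | exposures.exceedance_mask("0")
        for frac in ("pm25", "pmc"):
            mon = exposures.monitor_indicators(frac, "0")
            for m in mon.columns:
                add("monitor", f"mon_{frac}_{m}", mon[m].to_numpy(dtype=float))
    else:
        tag = lag_tag(spec.lag_set)
        wf = exposures.wf_indicator(spec.lag_set)
        pm = exposures.concentration(spec.pm_fraction, spec.lag_set) / spec.pm_scale
        wf01 = wf.where(wf != EXCLUDED).to_numpy()
        add("pm", f"{spec.pm_fraction}_{tag}", pm.to_numpy())
        add("pm_x_wf", f"{spec.pm_fraction}_{tag}_x_wf", pm.to_numpy() * wf01)
        add("wf", f"wf_{tag}", wf01)
        drop |= (wf == EXCLUDED) | wf.isna() | exposures.exceedance_mask(spec.lag_set)
        mon = exposures.monitor_indicators(spec.pm_fraction, spec.lag_set)
        for m in mon.columns:
            add("monitor", f"mon_{spec.pm_fraction}_{m}", mon[m].to_numpy(dtype=float))

    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    keep = (~drop.to_numpy()) & np.isfinite(X).all(axis=1) & y.notna().to_numpy()
    if keep.sum() < X.shape[1] + 1:
        raise ArgumentError(
            f"only {int(keep.sum())} usable rows remain after exclusions for a "
            f"{X.shape[1]}-column design; series too short for lag set {spec.lag_set!r}"
        )
    Xk = X[keep]
    yk = y.to_numpy(dtype=float)[keep]

    # drop constant columns (collinear with the intercept) and exact duplicates
    # (e.g. identical monitor-activity indicators for two fractions)
    keep_cols, dropped = [], []
    seen: dict[bytes, str] = {}
    for jcol, name in enumerate(names):
        col = Xk[:, jcol]
        sig = col.tobytes()
        if name != "intercept" and np.ptp(col) == 0.0:
            dropped.append(name)
        elif sig in seen:
            dropped.append(name)
        else:
            seen[sig] = name
            keep_cols.append(jcol)
    if dropped:
        log.info("dropping constant columns: %s", dropped)
    remap = {old: new for new, old in enumerate(keep_cols)}
    Xk = Xk[:, keep_cols]
    names = [names[jcol] for jcol in keep_cols]
    roles = {
        role: [remap[i] for i in idx if i in remap]
        for role, idx in roles.items()
    }
    roles = {role: idx for role, idx in roles.items() if idx}

    p = Xk.shape[1]
    penalty = np.zeros((p, p))
    sp = roles.get("spline", [])
    if len(sp) == Ss.shape[0]:
        penalty[np.ix_(sp, sp)] = Ss
    elif sp:
        raise ArgumentError("spline columns were dropped as constant; basis too large")
    return DesignBundle(
        y=yk,
        X=Xk,
        penalty=penalty,
        col_names=names,
        roles=roles,
        dates=dates[keep],
        spec=spec,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# Penalized IRLS at fixed smoothing parameter and dispersion
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, theta):
    """NB2 log likelihood; theta = inf gives the Poisson limit."""
    mu = np.clip(mu, 1e-12, None)
    if np.isinf(theta):
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta)
            + y * np.log(mu)
            - (y + theta) * np.log(mu + theta)
        )
    )


def _nb_deviance(y, mu, theta):
    mu = np.clip(mu, 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    if np.isinf(theta):
        return float(2.0 * np.sum(term - (y - mu)))
    yt = y + theta
    return float(2.0 * np.sum(term - yt * np.log(yt / (mu + theta))))


@dataclass
class InnerFit:
    """Result of penalized IRLS at fixed (lambda, theta)."""

    beta: np.ndarray
    cov: np.ndarray
    eta: np.ndarray
    mu: np.ndarray
    weights: np.ndarray
    deviance: float
    penalized_deviance: float
    loglik: float
    edf_by_col: np.ndarray
    iterations: int
    converged: bool
    info_logdet: float  # log|X'WX + lam*S|


def fit_penalized_nb_glm(
    design: DesignBundle,
    smoothing_parameter: float,
    nb_dispersion: float,
    max_iter: int = 200,
    tol: float = 1e-10,
    beta_start: np.ndarray | None = None,
) -> InnerFit:
    """Penalized IRLS for the NB log-link model at fixed hyperparameters.

    Maximizes the NB log likelihood minus (lambda/2) b'Sb by Fisher scoring
    with step halving; the covariance is the inverse penalized information.
    """
    y, X, S = design.y, design.X, design.penalty
    lam, theta = float(smoothing_parameter), float(nb_dispersion)
    if lam < 0:
        raise ArgumentError("smoothing_parameter must be >= 0")
    if not (theta > 0):
        raise ArgumentError("nb_dispersion must be positive")
    n, p = X.shape

    if beta_start is None:
        mu = np.clip(y + 0.5, 0.5, None)
        eta = np.log(mu)
        beta = None
    else:
        beta = beta_start.copy()
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)

    pdev = _nb_deviance(y, mu, theta) + (lam * 0.0 if beta is None else lam * beta @ S @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu / (1.0 + mu / theta) if np.isfinite(theta) else mu
        w = np.clip(w, 1e-10, None)
        z = eta + (y - mu) / mu
        WX = X * w[:, None]
        A = X.T @ WX + lam * S
        b = WX.T @ z
        try:
            c, low = linalg.cho_factor(A)
            beta_new = linalg.cho_solve((c, low), b)
        except linalg.LinAlgError:
            _raise_rank_deficiency(A, design)
        step = 1.0
        while True:
            beta_try = beta_new if beta is None else beta + step * (beta_new - beta)
            eta_try = np.clip(X @ beta_try, -30, 30)
            mu_try = np.exp(eta_try)
            pdev_try = _nb_deviance(y, mu_try, theta) + lam * beta_try @ S @ beta_try
            if pdev_try <= pdev + 1e-10 or beta is None or step < 1e-10:
                break
            step /= 2.0
        delta = abs(pdev - pdev_try)
        beta, eta, mu = beta_try, eta_try, mu_try
        prev_pdev, pdev = pdev, pdev_try
        if delta <= tol * (abs(pdev) + 0.1):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"penalized IRLS did not converge in {max_iter} iterations "
            f"(last |delta penalized deviance| = {abs(prev_pdev - pdev):.3g})",
            diagnostics={"beta": beta, "penalized_deviance": pdev, "iterations": it},
        )

    w = np.clip(mu / (1.0 + mu / theta) if np.isfinite(theta) else mu, 1e-10, None)
    WX = X * w[:, None]
    XtWX = X.T @ WX
    A = XtWX + lam * S
    try:
        c, low = linalg.cho_factor(A)
    except linalg.LinAlgError:
        _raise_rank_deficiency(A, design)
    cov = linalg.cho_solve((c, low), np.eye(p))
    cov = (cov + cov.T) / 2.0
    edf_by_col = np.einsum("ij,ji->i", cov, XtWX)
    info_logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return InnerFit(
        beta=beta,
        cov=cov,
        eta=eta,
        mu=mu,
        weights=w,
        deviance=_nb_deviance(y, mu, theta),
        penalized_deviance=pdev,
        loglik=_nb_loglik(y, mu, theta),
        edf_by_col=edf_by_col,
        iterations=it,
        converged=converged,
        info_logdet=info_logdet,
    )


def _raise_rank_deficiency(A: np.ndarray, design: DesignBundle):
    vals, vecs = np.linalg.eigh((A + A.T) / 2.0)
    bad = []
    scale = max(vals.max(), 1.0)
    for k in np.where(vals < 1e-10 * scale)[0]:
        weights = np.abs(vecs[:, k])
        for idx in np.argsort(weights)[::-1][:3]:
            if weights[idx] > 0.1:
                bad.append(design.col_names[idx])
    raise RankDeficiencyError(
        f"design is rank deficient; offending columns: {sorted(set(bad))}",
        columns=sorted(set(bad)),
    )


# ---------------------------------------------------------------------------
# Smoothness and dispersion selection
# ---------------------------------------------------------------------------

def _penalty_rank_and_logdet(S: np.ndarray, spline_cols: list[int]):
    if not spline_cols:
        return 0, 0.0
    Sb = S[np.ix_(spline_cols, spline_cols)]
    vals = np.linalg.eigvalsh((Sb + Sb.T) / 2.0)
    pos = vals[vals > 1e-9 * max(vals.max(), 1.0)]
    return pos.size, float(np.sum(np.log(pos)))


def _criterion_value(
    design: DesignBundle, fit: InnerFit, lam: float, theta: float, criterion: str
) -> float:
    if criterion == "reml":
        rank, logdet_s = _penalty_rank_and_logdet(design.penalty, design.spline_cols)
        pen = float(lam * fit.beta @ design.penalty @ fit.beta)
        val = (
            -fit.loglik
            + 0.5 * pen
            + 0.5 * fit.info_logdet
            - 0.5 * (rank * np.log(lam) + logdet_s if lam > 0 and rank else 0.0)
        )
    elif criterion == "gcv":
        n = design.n
        edf = float(fit.edf_by_col.sum())
        denom = max(n - edf, 1e-6)
        val = n * fit.deviance / denom**2
    else:
        raise ArgumentError(f"unknown smoothness criterion {criterion!r}")
    return float(val)


def _estimate_theta(y: np.ndarray, mu: np.ndarray, bounds=(-4.0, 12.0)) -> float:
    res = optimize.minimize_scalar(
        lambda lt: -_nb_loglik(y, mu, np.exp(lt)), bounds=bounds, method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def select_smoothness(
    design: DesignBundle,
    criterion: str = "reml",
    n_grid: int = 11,
    log_lambda_range: tuple[float, float] = (-6.0, 18.0),
    outer_iterations: int = 3,
    theta_start: float = 10.0,
    refine: bool = True,
) -> GamFit:
    """Choose the smoothing parameter and NB dispersion, return the full fit.

    Alternates (a) a grid search plus bounded refinement of the smoothness
    criterion over log(lambda) at fixed dispersion with (b) a 1-D ML update
    of the dispersion at the selected lambda, then assembles the GamFit.
    """
    if not design.spline_cols:
        # no smooth term: only the dispersion needs selecting
        theta = theta_start
        fit = fit_penalized_nb_glm(design, 0.0, theta)
        for _ in range(outer_iterations * 3):
            theta_new = _estimate_theta(design.y, fit.mu)
            if abs(np.log(theta_new) - np.log(theta)) < 1e-8:
                theta = theta_new
                break
            theta = theta_new
            fit = fit_penalized_nb_glm(design, 0.0, theta, beta_start=fit.beta)
        return _assemble(design, fit, 0.0, theta, criterion, float("nan"))

    theta = theta_start
    grid = np.linspace(*log_lambda_range, n_grid)
    lam_best = None
    fit_best = None
    for _ in range(outer_iterations):
        values = []
        fits = {}
        warm = fit_best.beta if fit_best is not None else None
        for ll in grid:
            lam = float(np.exp(ll))
            try:
                f = fit_penalized_nb_glm(design, lam, theta, beta_start=warm)
                warm = f.beta
                v = _criterion_value(design, f, lam, theta, criterion)
            except (ConvergenceError, RankDeficiencyError):
                v, f = np.inf, None
            values.append(v)
            fits[ll] = f
        values = np.asarray(values)
        if not np.isfinite(values).any():
            raise SmokegamError(
                f"smoothness criterion {criterion!r} is non-finite across the whole grid"
            )
        kbest = int(np.nanargmin(values))
        ll_best = grid[kbest]
        if refine and 0 < kbest < len(grid) - 1:
            lo, hi = grid[kbest - 1], grid[kbest + 1]
            warm_beta = fits[grid[kbest]].beta if fits[grid[kbest]] is not None else None

            def obj(ll):
                try:
                    f = fit_penalized_nb_glm(
                        design, float(np.exp(ll)), theta, beta_start=warm_beta
                    )
                except (ConvergenceError, RankDeficiencyError):
                    return np.inf
                return _criterion_value(design, f, float(np.exp(ll)), theta, criterion)

            res = optimize.minimize_scalar(
                obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3}
            )
            if np.isfinite(res.fun) and res.fun < values[kbest]:
                ll_best = float(res.x)
        lam_best = float(np.exp(ll_best))
        fit_best = fit_penalized_nb_glm(
            design, lam_best, theta,
            beta_start=fits[grid[kbest]].beta if fits[grid[kbest]] is not None else None,
        )
        theta_new = _estimate_theta(design.y, fit_best.mu)
        if abs(np.log(theta_new) - np.log(theta)) < 1e-6:
            theta = theta_new
            break
        theta = theta_new
    fit_best = fit_penalized_nb_glm(design, lam_best, theta, beta_start=fit_best.beta)
    crit_val = _criterion_value(design, fit_best, lam_best, theta, criterion)
    return _assemble(design, fit_best, lam_best, theta, criterion, crit_val)


def _assemble(
    design: DesignBundle,
    fit: InnerFit,
    lam: float,
    theta: float,
    criterion: str,
    crit_val: float,
) -> GamFit:
    y, mu = design.y, fit.mu
    work = (y - mu) / mu
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    if np.isinf(theta):
        d_i = 2.0 * (term - (y - mu))
    else:
        yt = y + theta
        d_i = 2.0 * (term - yt * np.log(yt / (mu + theta)))
    dres = np.sign(y - mu) * np.sqrt(np.clip(d_i, 0.0, None))
    sp = design.spline_cols
    # count the centered-out constant toward the smooth, so a fully smoothed
    # spline (a line in time) reports edf 2
    spline_edf = float(fit.edf_by_col[sp].sum()) + 1.0 if sp else 0.0
    return GamFit(
        beta=fit.beta,
        cov=fit.cov,
        col_names=design.col_names,
        roles=design.roles,
        smoothing_parameter=lam,
        spline_edf=spline_edf,
        edf_by_col=fit.edf_by_col,
        nb_dispersion=theta,
        deviance=fit.deviance,
        loglik=fit.loglik,
        iterations=fit.iterations,
        converged=fit.converged,
        working_residuals=pd.Series(work, index=design.dates),
        deviance_residuals=pd.Series(dres, index=design.dates),
        fitted=pd.Series(mu, index=design.dates),
        criterion=criterion,
        criterion_value=crit_val,
        spec=design.spec,
    )


# ---------------------------------------------------------------------------
# Residual diagnostics
# ---------------------------------------------------------------------------

def residual_acf(fit: GamFit, max_lag: int = 30) -> pd.DataFrame:
    """Sample ACF/PACF of the deviance residuals with the white-noise band.

    Returns a frame indexed by lag (0..max_lag) with columns ``acf``,
    ``pacf`` (NaN at lag 0), and ``band`` (the +-1.96/sqrt(n) reference).
    """
    from statsmodels.tsa.stattools import acf as sm_acf, pacf as sm_pacf

    r = fit.deviance_residuals.to_numpy()
    n = r.size
    if max_lag >= n:
        raise ArgumentError(f"max_lag ({max_lag}) must be < series length ({n})")
    if max_lag < 1:
        raise ArgumentError("max_lag must be >= 1")
    a = sm_acf(r, nlags=max_lag, fft=True)
    p = np.concatenate([[np.nan], sm_pacf(r, nlags=max_lag, method="ywm")[1:]])
    band = 1.96 / np.sqrt(n)
    return pd.DataFrame(
        {"acf": a, "pacf": p, "band": band}, index=pd.RangeIndex(max_lag + 1, name="lag")
    )
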