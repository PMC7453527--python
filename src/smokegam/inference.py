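"""Post-fit inference: rate ratios, wildfire modification, percent surfaces.

Every derived quantity is a linear combination of log-rate coefficients:
its variance is w' Sigma w, intervals are Wald at 95% on the log scale and
exponentiated, and multiplicative factors are reported also as percents via
(factor - 1) x 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError
from .nb_gam import GamFit, ModelSpec

log = logging.getLogger(__name__)

__all__ = [
    "ContrastResult",
    "SurfaceGrid",
    "WildfireModification",
    "linear_combination_variance",
    "factor_to_percent",
    "percent_to_factor",
    "modification_from_rate_ratios",
    "linear_contrast",
    "wildfire_modification",
    "two_fraction_percent_increase",
    "evaluate_two_fraction_surface",
    "model_grid_report",
    "two_fraction_fit_from_estimates",
]

Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class ContrastResult:
    """A linear combination of coefficients on the log-rate scale."""

    estimate: float
    se: float
    rate_ratio: float
    ci_low: float
    ci_high: float
    percent_change: float
    p_value: float


@dataclass
class SurfaceGrid:
    """Percent-increase surface over a (PM2.5, PM10-2.5) grid in ug/m3."""

    pm25: np.ndarray
    pmc: np.ndarray
    percent: np.ndarray  # shape (len(pmc), len(pm25)); NaN outside support
    p_value: np.ndarray
    significant: np.ndarray
    in_support: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: pm25, pmc, percent, p, in_support, significant."""
        g25, gc = np.meshgrid(self.pm25, self.pmc)
        return pd.DataFrame(
            {
                "pm25": g25.ravel(),
                "pmc": gc.ravel(),
                "percent": self.percent.ravel(),
                "p_value": self.p_value.ravel(),
                "in_support": self.in_support.ravel(),
                "significant": self.significant.ravel(),
            }
        )


def factor_to_percent(factor: float) -> float:
    """Multiplicative factor -> percent change, (factor - 1) x 100."""
    return (factor - 1.0) * 100.0


def percent_to_factor(percent: float) -> float:
    return percent / 100.0 + 1.0


def modification_from_rate_ratios(rr_wildfire: float, rr_non_wildfire: float) -> dict:
    """Modification implied by a (wildfire, non-wildfire) rate-ratio pair.

    The factor is the ratio of the two rate ratios; also returned as percent.
    """
    if rr_wildfire <= 0 or rr_non_wildfire <= 0:
        raise ArgumentError("rate ratios must be positive")
    factor = rr_wildfire / rr_non_wildfire
    return {"factor": factor, "percent": factor_to_percent(factor)}


def linear_combination_variance(covariance: np.ndarray, weights: np.ndarray) -> float:
    """Var(w'b) = w' Sigma w for a symmetric PSD coefficient covariance."""
    cov = np.asarray(covariance, dtype=float)
    w = np.asarray(weights, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ArgumentError("covariance must be a square matrix")
    if w.shape != (cov.shape[0],):
        raise ArgumentError(
            f"weights length {w.shape} does not match coefficient count {cov.shape[0]}"
        )
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ArgumentError("covariance must be symmetric")
    eig_min = float(np.linalg.eigvalsh((cov + cov.T) / 2.0).min())
    if eig_min < -1e-8 * max(1.0, float(np.abs(cov).max())):
        raise ArgumentError(f"covariance is not positive semidefinite (min eig {eig_min:.3g})")
    return float(w @ cov @ w)


def linear_contrast(beta: np.ndarray, cov: np.ndarray, weights: np.ndarray) -> ContrastResult:
    """Full Wald summary of w'beta on the log-rate and rate-ratio scales."""
    w = np.asarray(weights, dtype=float)
    est = float(np.asarray(beta, dtype=float) @ w)
    var = linear_combination_variance(cov, w)
    se = float(np.sqrt(var))
    rr = float(np.exp(est))
    lo, hi = float(np.exp(est - Z95 * se)), float(np.exp(est + Z95 * se))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(est) / se))
    else:
        p = 0.0 if est != 0 else 1.0
    return ContrastResult(
        estimate=est,
        se=se,
        rate_ratio=rr,
        ci_low=lo,
        ci_high=hi,
        percent_change=factor_to_percent(rr),
        p_value=p,
    )


@dataclass(frozen=True)
class WildfireModification:
    """Rate ratios with and without smoke plus the modification contrast."""

    non_wildfire: ContrastResult  # exp(b1)
    wildfire: ContrastResult  # exp(b1 + b2)
    modification: ContrastResult  # exp(b2)


def _single_index(fit: GamFit, role: str) -> int:
    idx = fit.roles.get(role, [])
    if len(idx) != 1:
        raise ArgumentError(
            f"fit does not contain a single {role!r} coefficient (found {len(idx)})"
        )
    return idx[0]


def wildfire_modification(fit: GamFit) -> WildfireModification:
    """PM rate ratios with/without smoke and the interaction contrast.

    Requires a single-fraction fit with roles ``pm`` (slope off smoke) and
    ``pm_x_wf`` (added slope on smoke days); the wildfire-day rate ratio
    uses the variance of the sum of the two coefficients.
    """
    i1 = _single_index(fit, "pm")
    i2 = _single_index(fit, "pm_x_wf")
    p = fit.beta.size
    e1 = np.zeros(p)
    e1[i1] = 1.0
    e2 = np.zeros(p)
    e2[i2] = 1.0
    return WildfireModification(
        non_wildfire=linear_contrast(fit.beta, fit.cov, e1),
        wildfire=linear_contrast(fit.beta, fit.cov, e1 + e2),
        modification=linear_contrast(fit.beta, fit.cov, e2),
    )


def _two_fraction_weights(fit: GamFit, pm25_ugm3, pmc_ugm3, pm_scale: float) -> np.ndarray:
    i2 = _single_index(fit, "pm_x_wf")
    i4 = _single_index(fit, "pm2_x_wf")
    i5 = _single_index(fit, "wf")
    w = np.zeros(fit.beta.size)
    w[i2] = pm25_ugm3 / pm_scale
    w[i4] = pmc_ugm3 / pm_scale
    w[i5] = 1.0
    return w


def two_fraction_percent_increase(
    fit: GamFit, pm25_ugm3: float, pmc_ugm3: float
) -> ContrastResult:
    """Percent change in visits due to smoke at given raw PM levels.

    Evaluates exp(b2*PM2.5 + b4*PM10-2.5 + b5) - 1 (as a percent) with the
    PM inputs rescaled internally to the model's per-5-ug/m3 units, and its
    Wald p-value from the linear-combination variance.
    """
    pm_scale = fit.spec.pm_scale if fit.spec is not None else 5.0
    w = _two_fraction_weights(fit, pm25_ugm3, pmc_ugm3, pm_scale)
    return linear_contrast(fit.beta, fit.cov, w)


def evaluate_two_fraction_surface(
    fit: GamFit,
    pm25_grid: np.ndarray | None = None,
    pmc_grid: np.ndarray | None = None,
    wildfire_observations: pd.DataFrame | None = None,
    support_radius: float = 5.0,
    alpha: float = 0.05,
    grid_step: float = 0.5,
) -> SurfaceGrid:
    """Percent-increase surface with significance and support masking.

    ``wildfire_observations`` holds the retained wildfire-day (pm25, pmc)
    points in raw ug/m3; a cell is in support iff its Euclidean distance to
    the nearest such point is <= ``support_radius`` ug/m3 (measured in the
    raw concentration plane).  Cells outside support carry no estimate.
    """
    if wildfire_observations is None or len(wildfire_observations) == 0:
        raise ArgumentError(
            "support is undefined without at least one wildfire observation"
        )
    obs = wildfire_observations[["pm25", "pmc"]].dropna().to_numpy(dtype=float)
    if obs.shape[0] == 0:
        raise ArgumentError("wildfire observations contain no complete (pm25, pmc) pairs")
    if pm25_grid is None:
        hi = float(obs[:, 0].max()) + support_radius
        pm25_grid = np.arange(0.0, hi + grid_step / 2, grid_step)
    if pmc_grid is None:
        hi = float(obs[:, 1].max()) + support_radius
        pmc_grid = np.arange(0.0, hi + grid_step / 2, grid_step)
    pm25_grid = np.asarray(pm25_grid, dtype=float)
    pmc_grid = np.asarray(pmc_grid, dtype=float)

    pm_scale = fit.spec.pm_scale if fit.spec is not None else 5.0
    i2 = _single_index(fit, "pm_x_wf")
    i4 = _single_index(fit, "pm2_x_wf")
    i5 = _single_index(fit, "wf")
    b2, b4, b5 = fit.beta[i2], fit.beta[i4], fit.beta[i5]
    v22, v44, v55 = fit.cov[i2, i2], fit.cov[i4, i4], fit.cov[i5, i5]
    c24, c25, c45 = fit.cov[i2, i4], fit.cov[i2, i5], fit.cov[i4, i5]

    G25, GC = np.meshgrid(pm25_grid / pm_scale, pmc_grid / pm_scale)
    est = b2 * G25 + b4 * GC + b5
    var = (
        G25**2 * v22
        + GC**2 * v44
        + v55
        + 2 * G25 * GC * c24
        + 2 * G25 * c25
        + 2 * GC * c45
    )
    se = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(est) / np.where(se > 0, se, np.nan))
    percent = (np.exp(est) - 1.0) * 100.0

    g25_raw, gc_raw = np.meshgrid(pm25_grid, pmc_grid)
    cells = np.column_stack([g25_raw.ravel(), gc_raw.ravel()])
    d2 = (
        (cells[:, None, 0] - obs[None, :, 0]) ** 2
        + (cells[:, None, 1] - obs[None, :, 1]) ** 2
    )
    in_support = (d2.min(axis=1) <= support_radius**2).reshape(est.shape)

    percent = np.where(in_support, percent, np.nan)
    p = np.where(in_support, p, np.nan)
    significant = in_support & (p < alpha)
    return SurfaceGrid(
        pm25=pm25_grid,
        pmc=pmc_grid,
        percent=percent,
        p_value=p,
        significant=significant,
        in_support=in_support,
    )


def model_grid_report(fits: list[GamFit], alpha: float = 0.05) -> pd.DataFrame:
    """One row per single-fraction model: rate ratios, modification, flags."""
    rows = []
    for fit in fits:
        if fit is None:
            continue
        spec = fit.spec
        try:
            mod = wildfire_modification(fit)
        except ArgumentError as exc:
            log.warning("skipping fit %s: %s", getattr(spec, "label", "?"), exc)
            continue
        rows.append(
            {
                "fraction": spec.pm_fraction if spec else "",
                "lag_set": spec.lag_set if spec else "",
                "rr_nonwf": mod.non_wildfire.rate_ratio,
                "rr_nonwf_lo": mod.non_wildfire.ci_low,
                "rr_nonwf_hi": mod.non_wildfire.ci_high,
                "rr_wf": mod.wildfire.rate_ratio,
                "rr_wf_lo": mod.wildfire.ci_low,
                "rr_wf_hi": mod.wildfire.ci_high,
                "factor": mod.modification.rate_ratio,
                "factor_lo": mod.modification.ci_low,
                "factor_hi": mod.modification.ci_high,
                "percent": mod.modification.percent_change,
                "p_value": mod.modification.p_value,
                "significant": mod.modification.p_value < alpha,
            }
        )
    if len(rows) < len([f for f in fits if f is not None]):
        log.warning("model grid report has gaps: %d of %d fits usable", len(rows), len(fits))
    return pd.DataFrame(rows)


def two_fraction_fit_from_estimates(
    beta2: float,
    beta4: float,
    beta5: float,
    cov: np.ndarray | None = None,
    pm_scale: float = 5.0,
) -> GamFit:
    """Minimal two-fraction fit object from externally reported coefficients.

    Useful for evaluating the percent-increase surface from published
    estimates (per 5 ug/m3) when the full fit is unavailable.  Without a
    covariance, a zero matrix is used and p-values are not meaningful.
    """
    beta = np.array([beta2, beta4, beta5], dtype=float)
    cov = np.zeros((3, 3)) if cov is None else np.asarray(cov, dtype=float)
    n = len(beta)
    empty = pd.Series(dtype=float)
    return GamFit(
        beta=beta,
        cov=cov,
        col_names=["pm25_lag0_x_wf", "pmc_lag0_x_wf", "wf_lag0"],
        roles={"pm_x_wf": [0], "pm2_x_wf": [1], "wf": [2]},
        smoothing_parameter=float("nan"),
        spline_edf=float("nan"),
        edf_by_col=np.full(n, np.nan),
        nb_dispersion=float("nan"),
        deviance=float("nan"),
        loglik=float("nan"),
        iterations=0,
        converged=True,
        working_residuals=empty,
        deviance_residuals=empty,
        fitted=empty,
        criterion="external",
        criterion_value=float("nan"),
        spec=ModelSpec(pm_fraction="two_fraction", lag_set="0", pm_scale=pm_scale),
    )
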