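"""Synthetic daily panels with known ground truth.

Generates everything the downstream stages consume — multi-monitor PM
panels with staggered activity windows, seasonal weather, warm-season
wildfire-smoke episode calendars, and overdispersed daily visit counts
driven by calendar structure, temperature, autoregression, and PM x
wildfire effects — so the full pipeline is testable without any download.

All generators take explicit seeds; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ArgumentError, GenerationError
from .exposure import FRACTIONS, ExposurePanel, MonitorPanel, build_exposure_panel
from .holidays import DEFAULT_HOLIDAYS, holiday_indicators

__all__ = [
    "TrueParams",
    "WildfireCalendar",
    "SyntheticDataset",
    "generate_wildfire_calendar",
    "generate_monitor_panel",
    "generate_weather",
    "generate_visits",
    "generate_dataset",
]

#: Default study length in days: six calendar years, 2013-2018.
DEFAULT_N_DAYS = 2192
DEFAULT_START = "2013-01-01"
PM_SCALE = 5.0  # ug/m3 per model unit


@dataclass
class TrueParams:
    """Ground-truth parameters of the count-generating process.

    PM slopes are on the log-rate scale per 5 ug/m3 (one model unit);
    ``ar_coefs`` multiply log(1 + lagged count) for lags 1..10.
    """

    intercept: float = float(np.log(8.6))
    dow_effects: np.ndarray = field(
        default_factory=lambda: np.array([0.03, 0.01, 0.0, 0.02, 0.05, -0.12])
    )  # Tue..Sun offsets, Monday is baseline
    holiday_effects: np.ndarray = field(
        default_factory=lambda: np.full(len(DEFAULT_HOLIDAYS), -0.05)
    )
    trend_amplitude: float = 0.12
    seasonal_phase: float = 0.0
    temp_coef: float = -0.004  # per deg C of the 7-day rolling mean
    ar_coefs: np.ndarray = field(default_factory=lambda: np.full(10, 0.008))
    beta1_pm: float = 0.01
    beta2_interaction: float = 0.0
    beta3_wf: float = 0.0
    nb_dispersion: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.dow_effects = np.asarray(self.dow_effects, dtype=float)
        self.holiday_effects = np.asarray(self.holiday_effects, dtype=float)
        self.ar_coefs = np.asarray(self.ar_coefs, dtype=float)
        if self.dow_effects.shape != (6,):
            raise ArgumentError("dow_effects must have six entries (Tue..Sun)")
        if self.ar_coefs.shape != (10,):
            raise ArgumentError("ar_coefs must have ten entries (lags 1..10)")
        if not self.nb_dispersion > 0:
            raise ArgumentError("nb_dispersion must be positive")
        scalars = [
            self.intercept,
            self.trend_amplitude,
            self.seasonal_phase,
            self.temp_coef,
            self.beta1_pm,
            self.beta2_interaction,
            self.beta3_wf,
        ]
        if not all(np.isfinite(scalars)):
            raise ArgumentError("all effect magnitudes must be finite")
        if not (np.isfinite(self.dow_effects).all() and np.isfinite(self.ar_coefs).all()):
            raise ArgumentError("all effect magnitudes must be finite")


@dataclass
class WildfireCalendar:
    """Daily count of smoke-affected hours (0-24) at the reference monitor."""

    hours: pd.Series

    def __post_init__(self) -> None:
        h = self.hours.to_numpy()
        if ((h < 0) | (h > 24)).any():
            raise ArgumentError("smoke-affected hours must lie in [0, 24]")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.hours.index

    @property
    def wildfire_day(self) -> pd.Series:
        return (self.hours >= 1).rename("wildfire_day")

    @property
    def n_smoke_days(self) -> int:
        return int((self.hours >= 1).sum())


def _dates(n_days: int, start: str) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_days, freq="D")


def generate_wildfire_calendar(
    n_days: int,
    episode_rate: float = 5.5,
    episode_length_dist: dict | None = None,
    seed: int = 0,
    start: str = DEFAULT_START,
) -> WildfireCalendar:
    """Warm-season smoke episode calendar.

    Episode starts arrive at ``episode_rate`` per year with day-of-year
    probability concentrated in July-September; lengths are drawn from
    ``episode_length_dist`` (``{"kind": "geometric", "mean": m}`` or
    ``{"kind": "fixed", "value": k}``).  Most smoke days get > 20 affected
    hours; a small minority get partial-day smoke.
    """
    if n_days < 1:
        raise ArgumentError("n_days must be >= 1")
    if episode_rate < 0:
        raise ArgumentError("episode_rate must be >= 0")
    dist = dict(episode_length_dist or {"kind": "geometric", "mean": 5.5})
    rng = np.random.default_rng(seed)
    dates = _dates(n_days, start)
    hours = np.zeros(n_days, dtype=np.int64)
    n_episodes = rng.poisson(episode_rate * n_days / 365.25)
    if n_episodes:
        doy = dates.dayofyear.to_numpy()
        weight = np.exp(-0.5 * ((doy - 225) / 40.0) ** 2) + 0.01
        starts = rng.choice(n_days, size=n_episodes, p=weight / weight.sum())
        for s in np.sort(starts):
            length = _draw_length(dist, rng)
            for d in range(s, min(s + length, n_days)):
                u = rng.random()
                if u < 0.70:
                    hours[d] = 24
                elif u < 0.97:
                    hours[d] = int(rng.integers(21, 24))
                else:
                    hours[d] = int(rng.integers(1, 21))
    return WildfireCalendar(pd.Series(hours, index=dates, name="smoke_hours"))


def _draw_length(dist: dict, rng: np.random.Generator) -> int:
    kind = dist.get("kind", "geometric")
    if kind == "fixed":
        return int(dist["value"])
    if kind == "geometric":
        mean = float(dist.get("mean", 5.5))
        if mean < 1:
            raise ArgumentError("geometric episode length mean must be >= 1")
        return int(rng.geometric(1.0 / mean))
    if kind == "poisson":
        return 1 + int(rng.poisson(float(dist.get("mean", 5.5)) - 1))
    raise ArgumentError(f"unknown episode length distribution {kind!r}")


def generate_monitor_panel(
    calendar: WildfireCalendar,
    n_monitors: int = 4,
    activity_windows: list[tuple] | None = None,
    weights=None,
    seed: int = 0,
    spike_amplitude: float = 12.0,
    coarse_bump: float = 0.7,
) -> MonitorPanel:
    """Multi-monitor PM panel with wildfire spikes on the fine fraction.

    Baseline PM2.5 is seasonally modulated lognormal; wildfire days add a
    spike (scaled by the fraction of smoke-affected hours) predominantly to
    PM2.5, with only a small additive bump on the coarse fraction.  PM10 is
    the per-monitor-day sum of the two.  Values outside a monitor's activity
    window are missing and flagged inactive.
    """
    dates = calendar.dates
    n_days = len(dates)
    if activity_windows is None:
        activity_windows = _default_windows(dates, n_monitors)
    if weights is None:
        weights = [5000, 3000, 2000, 1200, 800][:n_monitors]
        weights += [500] * (n_monitors - len(weights))
    if len(activity_windows) != n_monitors or len(weights) != n_monitors:
        raise ArgumentError("need one activity window and one weight per monitor")

    rng = np.random.default_rng(seed)
    doy = dates.dayofyear.to_numpy()
    smoke_frac = calendar.hours.to_numpy() / 24.0

    # shared regional AR(1) signals on the log scale
    z25 = _ar1(rng, n_days, rho=0.6, sigma=0.35)
    zc = _ar1(rng, n_days, rho=0.5, sigma=0.30)
    season25 = 0.30 * np.cos(2 * np.pi * (doy - 10) / 365.25)  # winter inversions
    seasonc = 0.25 * np.sin(2 * np.pi * (doy - 80) / 365.25)  # spring/summer dust
    base25 = np.exp(np.log(6.3) + season25 + z25)
    basec = np.exp(np.log(9.6) + seasonc + zc)
    spike = spike_amplitude * smoke_frac * rng.lognormal(0.0, 0.45, size=n_days)

    monitor_ids = [f"M{i}" for i in range(n_monitors)]
    values = {f: {} for f in FRACTIONS}
    active = {f: {} for f in FRACTIONS}
    for i, mid in enumerate(monitor_ids):
        site25 = np.exp(rng.normal(0.0, 0.10, size=n_days) + rng.normal(0.0, 0.05))
        sitec = np.exp(rng.normal(0.0, 0.12, size=n_days) + rng.normal(0.0, 0.05))
        pm25 = base25 * site25 + spike * np.exp(rng.normal(0.0, 0.10, size=n_days))
        pmc = basec * sitec + coarse_bump * smoke_frac
        pm10 = pm25 + pmc
        window = _window_mask(dates, activity_windows[i])
        for f, arr in zip(FRACTIONS, (pm25, pmc, pm10)):
            values[f][mid] = np.where(window, arr, np.nan)
            active[f][mid] = window
    values_df = {f: pd.DataFrame(values[f], index=dates) for f in FRACTIONS}
    active_df = {f: pd.DataFrame(active[f], index=dates) for f in FRACTIONS}
    return MonitorPanel(
        values=values_df,
        active=active_df,
        weights=pd.Series(list(weights), index=monitor_ids, dtype=float),
    )


def _default_windows(dates: pd.DatetimeIndex, n_monitors: int) -> list[tuple]:
    """Staggered activity windows; monitor 0 spans the whole study."""
    n = len(dates)
    full = (dates[0], dates[-1])
    windows = [full]
    cuts = [(0.2, 1.0), (0.0, 0.8), (0.25, 0.85), (0.1, 0.9)]
    for i in range(1, n_monitors):
        lo, hi = cuts[(i - 1) % len(cuts)]
        windows.append((dates[int(lo * (n - 1))], dates[int(hi * (n - 1))]))
    return windows


def _window_mask(dates: pd.DatetimeIndex, window: tuple) -> np.ndarray:
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    return np.asarray((dates >= lo) & (dates <= hi))


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    innov = rng.normal(0.0, sigma, size=n)
    out = np.empty(n)
    out[0] = innov[0] / np.sqrt(1 - rho**2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + innov[i]
    return out


def generate_weather(
    n_days: int,
    seed: int = 0,
    start: str = DEFAULT_START,
    seasonal_amplitude: float = 10.0,
    noise_sd: float = 3.0,
) -> pd.DataFrame:
    """Daily min/mean/max temperature (deg C) and mean RH (%).

    Temperature is sinusoidal-seasonal plus AR(1) noise; RH is negatively
    coupled to the temperature anomaly (sample correlation near -0.8).
    """
    if n_days < 1:
        raise ArgumentError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    dates = _dates(n_days, start)
    doy = dates.dayofyear.to_numpy()
    seasonal = seasonal_amplitude * np.sin(2 * np.pi * (doy - 105) / 365.25)
    noise = _ar1(rng, n_days, rho=0.7, sigma=noise_sd * np.sqrt(1 - 0.7**2)) if noise_sd > 0 else 0.0
    temp_mean = 12.5 + seasonal + noise
    # desert diurnal range widens in the warm season, so daily min and max
    # carry seasonal information the daily mean does not
    cycle = np.sin(2 * np.pi * (doy - 105) / 365.25) if seasonal_amplitude > 0 else 0.0
    spread_lo = np.clip(
        7.0 + 2.0 * cycle + rng.normal(0.0, 0.3 * noise_sd, size=n_days), 0.5, None
    )
    spread_hi = np.clip(
        8.0 + 3.0 * cycle + rng.normal(0.0, 0.3 * noise_sd, size=n_days), 0.5, None
    )
    if noise_sd == 0:
        spread_lo = np.clip(np.full(n_days, 7.0) + 2.0 * cycle, 0.5, None)
        spread_hi = np.clip(np.full(n_days, 8.0) + 3.0 * cycle, 0.5, None)
    rh = np.clip(
        43.0 - 1.3 * (temp_mean - 12.5) + rng.normal(0.0, 8.0, size=n_days), 5.0, 100.0
    )
    return pd.DataFrame(
        {
            "temp_min": temp_mean - spread_lo,
            "temp_mean": temp_mean,
            "temp_max": temp_mean + spread_hi,
            "rh": rh,
        },
        index=dates,
    )


def true_linear_predictor_terms(
    exposures: ExposurePanel, weather: pd.DataFrame, truth: TrueParams
) -> pd.DataFrame:
    """Deterministic (non-AR) pieces of the true log-rate, by date."""
    dates = exposures.dates
    t = np.arange(len(dates))
    dow = pd.get_dummies(pd.Series(dates.dayofweek, index=dates)).reindex(
        columns=range(7), fill_value=0
    )
    dow_term = dow.iloc[:, 1:].to_numpy(dtype=float) @ truth.dow_effects
    hol = holiday_indicators(dates)
    hol_term = hol.to_numpy(dtype=float) @ truth.holiday_effects
    cycle = 2 * np.pi * t / 365.25
    trend = truth.trend_amplitude * (
        np.sin(cycle + truth.seasonal_phase) + 0.3 * np.sin(2 * cycle + truth.seasonal_phase)
    )
    rolltemp = (
        weather["temp_mean"].reindex(dates).rolling(7, min_periods=1).mean().to_numpy()
    )
    temp_term = truth.temp_coef * (rolltemp - 13.0)
    pm25 = exposures.concentration("pm25", "0") / PM_SCALE
    wf = (exposures.wf_indicator("0") == 1.0).astype(float)
    pm_term = truth.beta1_pm * pm25.to_numpy()
    inter_term = truth.beta2_interaction * pm25.to_numpy() * wf.to_numpy()
    wf_term = truth.beta3_wf * wf.to_numpy()
    return pd.DataFrame(
        {
            "dow": dow_term,
            "holiday": hol_term,
            "trend": trend,
            "temp": temp_term,
            "pm": pm_term,
            "pm_x_wf": inter_term,
            "wf": wf_term,
        },
        index=dates,
    )


def generate_visits(
    exposures: ExposurePanel,
    weather: pd.DataFrame,
    calendar: WildfireCalendar,
    truth: TrueParams,
) -> pd.Series:
    """Negative-binomial daily counts from the true model, with AR feedback.

    The log-mean is the true linear predictor; autoregressive feedback enters
    as log(1 + lagged generated count) for lags 1..10 (pre-sample lags use
    the baseline mean exp(intercept)).  Reproducible under ``truth.seed``.
    """
    dates = exposures.dates
    if not (weather.index.equals(dates) and calendar.dates.equals(dates)):
        raise ArgumentError("exposures, weather, and calendar must share the same dates")
    pm25 = exposures.concentration("pm25", "0")
    if pm25.isna().any():
        bad = pm25.index[pm25.isna()][:5].strftime("%Y-%m-%d").tolist()
        raise GenerationError(f"missing lag-0 PM2.5 exposure on non-excluded days, e.g. {bad}")
    terms = true_linear_predictor_terms(exposures, weather, truth)
    eta_fixed = truth.intercept + terms.sum(axis=1).to_numpy()
    rng = np.random.default_rng(truth.seed)
    theta = truth.nb_dispersion
    n_days = len(dates)
    y = np.zeros(n_days, dtype=np.int64)
    baseline_ar = np.log1p(np.exp(truth.intercept))
    for i in range(n_days):
        ar = 0.0
        for j, coef in enumerate(truth.ar_coefs, start=1):
            ar += coef * (np.log1p(y[i - j]) if i - j >= 0 else baseline_ar)
        mu = float(np.exp(np.clip(eta_fixed[i] + ar, -20, 20)))
        y[i] = rng.negative_binomial(theta, theta / (theta + mu))
    return pd.Series(y, index=dates, name="visits")


@dataclass
class SyntheticDataset:
    """A complete simulated study: inputs plus derived exposure columns."""

    calendar: WildfireCalendar
    monitors: MonitorPanel
    weather: pd.DataFrame
    visits: pd.Series
    exposures: ExposurePanel
    truth: TrueParams


def generate_dataset(
    n_days: int = DEFAULT_N_DAYS,
    seed: int = 0,
    truth: TrueParams | None = None,
    start: str = DEFAULT_START,
    n_monitors: int = 4,
    episode_rate: float = 5.5,
    spike_amplitude: float = 12.0,
) -> SyntheticDataset:
    """Generate a full study dataset from a single seed.

    Independent child seeds are spawned for the calendar, monitor panel,
    weather, and counts so components can be regenerated in isolation.
    """
    ss = np.random.SeedSequence(seed)
    s_cal, s_mon, s_wx, s_visits = [int(c.generate_state(1)[0]) for c in ss.spawn(4)]
    calendar = generate_wildfire_calendar(n_days, episode_rate=episode_rate, seed=s_cal, start=start)
    monitors = generate_monitor_panel(
        calendar, n_monitors=n_monitors, seed=s_mon, spike_amplitude=spike_amplitude
    )
    weather = generate_weather(n_days, seed=s_wx, start=start)
    exposures = build_exposure_panel(monitors, calendar.hours)
    truth = replace(truth, seed=s_visits) if truth is not None else TrueParams(seed=s_visits)
    visits = generate_visits(exposures, weather, calendar, truth)
    return SyntheticDataset(
        calendar=calendar,
        monitors=monitors,
        weather=weather,
        visits=visits,
        exposures=exposures,
        truth=truth,
    )
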