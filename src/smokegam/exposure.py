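"""Exposure construction: monitor weighting, lag averages, wildfire indicators.

Turns per-monitor PM series and daily smoke-qualifier hour counts into the
analysis-ready exposure columns:

* population-weighted daily concentrations per PM fraction,
* rolling lag-set averages (same day; 3-day; 7-day),
* tri-state wildfire indicators per lag set (1 = all lags smoke-affected,
  0 = none, EXCLUDED = a mixture, which removes the observation),
* an exceedance-exclusion mask per lag set dropping wildfire observations
  whose lag-averaged PM2.5 exceeds the non-wildfire maximum, and
* per-monitor activity indicators (active at any included lag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConfigurationError, ValidationError

__all__ = [
    "FRACTIONS",
    "LAG_SETS",
    "EXCLUDED",
    "MonitorPanel",
    "ExposurePanel",
    "classify_wildfire_day",
    "weighted_daily_exposure",
    "rolling_lag_average",
    "wildfire_lag_indicator",
    "exceedance_exclusion",
    "monitor_activity_indicators",
    "build_exposure_panel",
]

#: PM fractions handled by the pipeline.  ``pmc`` is the coarse fraction
#: (PM10 minus PM2.5); ``pm10`` the total below 10 um.
FRACTIONS: tuple[str, ...] = ("pm25", "pmc", "pm10")

#: Lag sets: name -> window length in days (lag 0 is the same day).
LAG_SETS: dict[str, int] = {"0": 1, "0-2": 3, "0-6": 7}

#: Tri-state wildfire indicator code for observations dropped because the
#: lag window mixes wildfire and non-wildfire days.
EXCLUDED: float = -1.0


def lag_tag(lag_set: str) -> str:
    """Column-name suffix for a lag set, e.g. ``'0-2' -> 'lag0_2'``."""
    _check_lag_set(lag_set)
    return "lag" + lag_set.replace("-", "_")


def _check_lag_set(lag_set: str) -> int:
    if lag_set not in LAG_SETS:
        raise ArgumentError(f"unknown lag set {lag_set!r}; expected one of {sorted(LAG_SETS)}")
    return LAG_SETS[lag_set]


@dataclass
class MonitorPanel:
    """Per-monitor daily PM values, activity flags, and patient-count weights.

    ``values[fraction]`` and ``active[fraction]`` are (dates x monitors)
    frames; ``weights`` maps monitor id to its patient count.
    """

    values: dict[str, pd.DataFrame]
    active: dict[str, pd.DataFrame]
    weights: pd.Series

    def __post_init__(self) -> None:
        missing = [f for f in FRACTIONS if f not in self.values or f not in self.active]
        if missing:
            raise ValidationError(f"panel missing fractions: {missing}")
        ref = self.values[FRACTIONS[0]]
        for f in FRACTIONS:
            v, a = self.values[f], self.active[f]
            if not (v.index.equals(ref.index) and a.index.equals(ref.index)):
                raise ValidationError(f"date index mismatch for fraction {f!r}")
            if not (v.columns.equals(ref.columns) and a.columns.equals(ref.columns)):
                raise ValidationError(f"monitor columns mismatch for fraction {f!r}")
            if (v.to_numpy() < 0).any():
                raise ValidationError(f"negative {f} concentrations in panel")
        self.weights = self.weights.reindex(ref.columns)
        if self.weights.isna().any():
            raise ValidationError("every monitor needs a weight")
        if (self.weights <= 0).any():
            raise ValidationError("monitor weights must be positive")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values[FRACTIONS[0]].index

    @property
    def monitors(self) -> list:
        return list(self.values[FRACTIONS[0]].columns)

    def availability(self, fraction: str) -> pd.DataFrame:
        """Active and reporting a value, per monitor-day."""
        if fraction not in FRACTIONS:
            raise ArgumentError(f"unknown fraction {fraction!r}")
        return self.active[fraction].astype(bool) & self.values[fraction].notna()


@dataclass
class ExposurePanel:
    """Analysis-ready daily exposure columns for every fraction x lag set."""

    data: pd.DataFrame
    activity: dict[tuple[str, str], pd.DataFrame]
    wildfire_day: pd.Series
    exceedance_thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    def concentration(self, fraction: str, lag_set: str) -> pd.Series:
        return self.data[f"{fraction}_{lag_tag(lag_set)}"]

    def wf_indicator(self, lag_set: str) -> pd.Series:
        return self.data[f"wf_{lag_tag(lag_set)}"]

    def exceedance_mask(self, lag_set: str) -> pd.Series:
        return self.data[f"excl_{lag_tag(lag_set)}"].astype(bool)

    def monitor_indicators(self, fraction: str, lag_set: str) -> pd.DataFrame:
        return self.activity[(fraction, lag_set)]


def classify_wildfire_day(qualifier_hours):
    """True iff at least one hour of the day was smoke-affected.

    Accepts a scalar or array of integer hour counts in [0, 24].  Smoke from
    prescribed burns is not distinguished from wildfire smoke.
    """
    hours = np.asarray(qualifier_hours)
    if hours.size and (np.any(hours < 0) or np.any(hours > 24)):
        raise ArgumentError("qualifier hours must lie in [0, 24]")
    result = hours >= 1
    return bool(result) if np.isscalar(qualifier_hours) else result


def weighted_daily_exposure(panel: MonitorPanel, fraction: str, date=None):
    """Patient-count-weighted average over the monitors active each day.

    Weights are renormalized daily over the monitors reporting that fraction;
    days with no active monitor are missing (NaN), not an error.  With
    ``date`` given, returns the scalar for that day; otherwise the full
    daily series.
    """
    if fraction not in FRACTIONS:
        raise ArgumentError(f"unknown fraction {fraction!r}")
    avail = panel.availability(fraction)
    w = avail.mul(panel.weights, axis=1).astype(float)
    num = (panel.values[fraction].fillna(0.0) * w).sum(axis=1)
    den = w.sum(axis=1)
    out = num.divide(den.where(den > 0))
    out.name = fraction
    if date is not None:
        ts = pd.Timestamp(date)
        if ts not in out.index:
            raise ArgumentError(f"panel does not cover {date}")
        return float(out.loc[ts])
    return out


def rolling_lag_average(series: pd.Series, lag_set: str) -> pd.Series:
    """Rolling mean over the lag window ending at lag 0 (the same day).

    Any missing lag in the window makes the average missing; the first
    ``max(lag)`` days are therefore always missing for multi-day sets.
    """
    window = _check_lag_set(lag_set)
    if window == 1:
        return series.copy()
    return series.rolling(window, min_periods=window).mean()


def wildfire_lag_indicator(wf_flags: pd.Series, lag_set: str) -> pd.Series:
    """Tri-state indicator: 1 if all lags are wildfire days, 0 if none,
    EXCLUDED (-1) for a mixture.  Undefined (NaN) while the window is
    incomplete at the start of the series."""
    window = _check_lag_set(lag_set)
    flags = wf_flags.astype(float)
    if flags.isna().any():
        raise ArgumentError("wildfire flags must be defined on all days")
    total = flags.rolling(window, min_periods=window).sum()
    out = pd.Series(EXCLUDED, index=wf_flags.index, dtype=float)
    out[total == window] = 1.0
    out[total == 0] = 0.0
    out[total.isna()] = np.nan
    out.name = f"wf_{lag_tag(lag_set)}"
    return out


def exceedance_exclusion(
    pm25_lagavg: pd.Series, wf_indicator: pd.Series, return_threshold: bool = False
):
    """Mask (True = drop) wildfire observations whose lag-averaged PM2.5
    strictly exceeds the maximum over non-wildfire observations.

    The threshold is the max of ``pm25_lagavg`` over rows with indicator 0;
    only rows with indicator 1 can be masked, and the exclusion keys on
    PM2.5 alone.  Computed separately per lag set by the caller.
    """
    if not pm25_lagavg.index.equals(wf_indicator.index):
        raise ArgumentError("PM2.5 series and wildfire indicator must share an index")
    nonwf = pm25_lagavg[wf_indicator == 0.0].dropna()
    if nonwf.empty:
        raise ConfigurationError(
            "no non-wildfire observations: the exceedance threshold is undefined"
        )
    threshold = float(nonwf.max())
    mask = (wf_indicator == 1.0) & (pm25_lagavg > threshold)
    mask.name = "excl"
    if return_threshold:
        return mask, threshold
    return mask


def monitor_activity_indicators(panel: MonitorPanel, fraction: str, lag_set: str) -> pd.DataFrame:
    """One 0/1 column per monitor: 1 if the monitor reported that fraction at
    any lag in the window."""
    window = _check_lag_set(lag_set)
    avail = panel.availability(fraction).astype(float)
    any_lag = avail.rolling(window, min_periods=1).max()
    return any_lag.astype(np.int8)


def build_exposure_panel(panel: MonitorPanel, qualifier_hours: pd.Series) -> ExposurePanel:
    """Assemble every exposure column for all fractions and lag sets.

    ``qualifier_hours`` is the daily count (0-24) of smoke-affected hours at
    the reference monitor; it must cover the panel's date range exactly.
    """
    if not qualifier_hours.index.equals(panel.dates):
        raise ArgumentError("qualifier hours must be aligned with the monitor panel dates")
    wf_day = pd.Series(
        classify_wildfire_day(qualifier_hours.to_numpy()), index=panel.dates, name="wildfire_day"
    )
    cols: dict[str, pd.Series] = {}
    daily = {f: weighted_daily_exposure(panel, f) for f in FRACTIONS}
    for lag_set in LAG_SETS:
        tag = lag_tag(lag_set)
        for f in FRACTIONS:
            cols[f"{f}_{tag}"] = rolling_lag_average(daily[f], lag_set)
        cols[f"wf_{tag}"] = wildfire_lag_indicator(wf_day, lag_set)
    thresholds: dict[str, float] = {}
    for lag_set in LAG_SETS:
        tag = lag_tag(lag_set)
        mask, thr = exceedance_exclusion(
            cols[f"pm25_{tag}"], cols[f"wf_{tag}"], return_threshold=True
        )
        cols[f"excl_{tag}"] = mask
        thresholds[lag_set] = thr
    activity = {
        (f, s): monitor_activity_indicators(panel, f, s) for f in FRACTIONS for s in LAG_SETS
    }
    data = pd.DataFrame(cols, index=panel.dates)
    return ExposurePanel(
        data=data, activity=activity, wildfire_day=wf_day, exceedance_thresholds=thresholds
    )
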