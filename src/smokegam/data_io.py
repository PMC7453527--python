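"""File formats, run configuration, and the end-to-end pipeline driver.

CSV dialects (ISO-8601 dates, header rows, empty fields for missing):

* monitor CSV: ``monitor_id,date,parameter,value_ugm3,active`` with
  parameter in {PM25, PM10_25, PM10};
* qualifier CSV: ``monitor_id,date,hour,smoke_flag`` (hour 0-23; only
  flagged hours need to be listed);
* weather CSV: ``date,temp_min,temp_mean,temp_max,rh``;
* visits CSV: ``date,visits`` (non-negative integers);
* weights config (YAML): ``monitor_id -> {patients, radius_km}``.

The synthetic writers emit exactly the dialects the readers parse, so a
simulated run exercises the real parsers end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ArgumentError, ConfigurationError, ParseError, SmokegamError
from .exposure import FRACTIONS, LAG_SETS, ExposurePanel, MonitorPanel, build_exposure_panel
from .inference import evaluate_two_fraction_surface, model_grid_report
from .nb_gam import TWO_FRACTION, GamFit, ModelSpec, build_design, select_smoothness
from .sensitivity import SensitivityVariant, run_variants
from .synthetic_data import (
    SyntheticDataset,
    TrueParams,
    WildfireCalendar,
    generate_dataset,
)

log = logging.getLogger(__name__)

__all__ = [
    "PARAMETER_CODES",
    "RunConfig",
    "write_monitor_csv",
    "read_monitor_csv",
    "write_qualifier_csv",
    "read_qualifier_csv",
    "write_weather_csv",
    "read_weather_csv",
    "write_visits_csv",
    "read_visits_csv",
    "write_weights_yaml",
    "read_weights_yaml",
    "write_dataset",
    "load_study_tables",
    "run_pipeline",
]

PARAMETER_CODES = {"PM25": "pm25", "PM10_25": "pmc", "PM10": "pm10"}
_CODES_BY_FRACTION = {v: k for k, v in PARAMETER_CODES.items()}
DATE_FMT = "%Y-%m-%d"


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_monitor_csv(panel: MonitorPanel, path) -> None:
    rows = []
    for fraction in FRACTIONS:
        values = panel.values[fraction]
        active = panel.active[fraction]
        for mid in values.columns:
            sub = pd.DataFrame(
                {
                    "monitor_id": mid,
                    "date": values.index.strftime(DATE_FMT),
                    "parameter": _CODES_BY_FRACTION[fraction],
                    "value_ugm3": values[mid].to_numpy(),
                    "active": active[mid].astype(int).to_numpy(),
                }
            )
            rows.append(sub)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def write_qualifier_csv(calendar: WildfireCalendar, path, monitor_id: str = "M0") -> None:
    """Hourly smoke flags; the first ``hours`` hours of each day are flagged."""
    rows = []
    for date, hours in calendar.hours.items():
        for hour in range(int(hours)):
            rows.append((monitor_id, date.strftime(DATE_FMT), hour, 1))
    frame = pd.DataFrame(rows, columns=["monitor_id", "date", "hour", "smoke_flag"])
    frame.to_csv(path, index=False)


def write_weather_csv(weather: pd.DataFrame, path) -> None:
    out = weather.copy()
    out.insert(0, "date", out.index.strftime(DATE_FMT))
    out.to_csv(path, index=False, float_format="%.6g")


def write_visits_csv(visits: pd.Series, path) -> None:
    pd.DataFrame(
        {"date": visits.index.strftime(DATE_FMT), "visits": visits.to_numpy()}
    ).to_csv(path, index=False)


def write_weights_yaml(weights: pd.Series, path, radius_km: float = 5.0, overrides=None) -> None:
    overrides = overrides or {}
    doc = {
        str(mid): {"patients": int(w), "radius_km": float(overrides.get(mid, radius_km))}
        for mid, w in weights.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def write_dataset(dataset: SyntheticDataset, directory) -> dict:
    """Write a synthetic dataset in the standard input dialects."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "monitor": directory / "monitors.csv",
        "qualifier": directory / "qualifiers.csv",
        "weather": directory / "weather.csv",
        "visits": directory / "visits.csv",
        "weights": directory / "weights.yaml",
    }
    write_monitor_csv(dataset.monitors, paths["monitor"])
    write_qualifier_csv(dataset.calendar, paths["qualifier"])
    write_weather_csv(dataset.weather, paths["weather"])
    write_visits_csv(dataset.visits, paths["visits"])
    write_weights_yaml(dataset.monitors.weights, paths["weights"])
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Readers (with validation)
# ---------------------------------------------------------------------------

def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"could not read {path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return frame


def _parse_dates(frame: pd.DataFrame, path) -> pd.DataFrame:
    parsed = pd.to_datetime(frame["date"], format=DATE_FMT, errors="coerce")
    bad = frame.index[parsed.isna()]
    if len(bad):
        raise ParseError(f"{path}: unparseable dates at rows {list(bad[:10] + 2)}")
    frame = frame.copy()
    frame["date"] = parsed
    return frame


def read_monitor_csv(path, weights: pd.Series) -> MonitorPanel:
    frame = _parse_dates(
        _read_csv(path, ["monitor_id", "date", "parameter", "value_ugm3", "active"]), path
    )
    unknown = set(frame["parameter"]) - set(PARAMETER_CODES)
    if unknown:
        raise ParseError(f"{path}: unknown parameter codes {sorted(unknown)}")
    dup = frame.duplicated(subset=["monitor_id", "date", "parameter"], keep=False)
    if dup.any():
        rows = list(frame.index[dup][:10] + 2)
        raise ParseError(f"{path}: duplicate monitor-date-parameter rows at lines {rows}")
    if (frame["value_ugm3"].dropna() < 0).any():
        bad = list(frame.index[frame["value_ugm3"] < 0][:10] + 2)
        raise ParseError(f"{path}: negative concentrations at lines {bad}")
    dates = pd.DatetimeIndex(sorted(frame["date"].unique()))
    monitors = sorted(frame["monitor_id"].unique())
    values, active = {}, {}
    for code, fraction in PARAMETER_CODES.items():
        sub = frame[frame["parameter"] == code]
        vals = sub.pivot(index="date", columns="monitor_id", values="value_ugm3").reindex(
            index=dates, columns=monitors
        )
        act = (
            sub.pivot(index="date", columns="monitor_id", values="active")
            .reindex(index=dates, columns=monitors)
            .fillna(0)
            .astype(bool)
        )
        for frame_ in (vals, act):
            frame_.index.name = None
            frame_.columns.name = None
        values[fraction] = vals
        active[fraction] = act
    return MonitorPanel(values=values, active=active, weights=weights.reindex(monitors))


def read_qualifier_csv(path, dates: pd.DatetimeIndex, monitor_id: str | None = None) -> WildfireCalendar:
    frame = _parse_dates(_read_csv(path, ["monitor_id", "date", "hour", "smoke_flag"]), path)
    if ((frame["hour"] < 0) | (frame["hour"] > 23)).any():
        raise ParseError(f"{path}: hour values outside 0-23")
    if monitor_id is not None:
        frame = frame[frame["monitor_id"] == monitor_id]
    dup = frame.duplicated(subset=["monitor_id", "date", "hour"], keep=False)
    if dup.any():
        raise ParseError(f"{path}: duplicate monitor-date-hour rows")
    flagged = frame[frame["smoke_flag"] == 1]
    hours = flagged.groupby("date").size().reindex(dates, fill_value=0).astype(np.int64)
    hours.name = "smoke_hours"
    return WildfireCalendar(hours)


def read_weather_csv(path) -> pd.DataFrame:
    frame = _parse_dates(
        _read_csv(path, ["date", "temp_min", "temp_mean", "temp_max", "rh"]), path
    )
    dup = frame.duplicated(subset=["date"], keep=False)
    if dup.any():
        raise ParseError(f"{path}: duplicate dates")
    return frame.set_index("date").sort_index()


def read_visits_csv(path) -> pd.Series:
    frame = _parse_dates(_read_csv(path, ["date", "visits"]), path)
    dup = frame.duplicated(subset=["date"], keep=False)
    if dup.any():
        rows = list(frame.index[dup][:10] + 2)
        raise ParseError(f"{path}: duplicate dates at lines {rows}")
    bad = frame["visits"].isna() | (frame["visits"] < 0) | (frame["visits"] % 1 != 0)
    if bad.any():
        rows = list(frame.index[bad][:10] + 2)
        raise ParseError(f"{path}: visits must be non-negative integers; bad lines {rows}")
    series = frame.set_index("date")["visits"].astype(np.int64).sort_index()
    return series


def read_weights_yaml(path) -> pd.Series:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ParseError(f"could not read {path}: {exc}") from exc
    if not isinstance(doc, dict) or not doc:
        raise ParseError(f"{path}: expected a mapping of monitor_id -> weight spec")
    weights = {}
    for mid, spec in doc.items():
        patients = spec.get("patients") if isinstance(spec, dict) else spec
        if not isinstance(patients, (int, float)) or patients <= 0:
            raise ParseError(f"{path}: monitor {mid!r} needs a positive patient count")
        weights[str(mid)] = float(patients)
    return pd.Series(weights, name="weight")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed for a full pipeline run.

    Exactly one of ``paths`` (real input files) or ``synthetic`` (generation
    parameters) must be provided.
    """

    outdir: str = "scratch/run"
    seed: int = 0
    paths: dict | None = None
    synthetic: dict | None = None
    reference_monitor: str | None = None
    fractions: tuple[str, ...] = ("pm25", "pmc", "pm10")
    lag_sets: tuple[str, ...] = ("0", "0-2", "0-6")
    two_fraction: bool = True
    pm_scale: float = 5.0
    spline_basis_size: int = 10
    criterion: str = "reml"
    ar_lags: tuple[int, ...] = tuple(range(1, 11))
    select_n_grid: int = 8
    select_outer_iterations: int = 2
    grid_step: float = 0.5
    support_radius: float = 5.0
    sensitivity: bool = True
    sensitivity_lag_sets: tuple[str, ...] = ("0",)
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.paths is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of 'paths' and 'synthetic' must be configured"
            )
        for s in list(self.lag_sets) + list(self.sensitivity_lag_sets):
            if s not in LAG_SETS:
                raise ConfigurationError(f"unknown lag set {s!r}")
        for f in self.fractions:
            if f not in FRACTIONS:
                raise ConfigurationError(f"unknown fraction {f!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fractions", "lag_sets", "ar_lags", "sensitivity_lag_sets"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key, val in out.items():
            if isinstance(val, tuple):
                out[key] = list(val)
        return out

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output path excluded)."""
        doc = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        canon = json.dumps(doc, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def model_specs(self) -> list[ModelSpec]:
        common = dict(
            pm_scale=self.pm_scale,
            spline_basis_size=self.spline_basis_size,
            ar_lags=self.ar_lags,
        )
        specs = [
            ModelSpec(pm_fraction=f, lag_set=s, **common)
            for f in self.fractions
            for s in self.lag_sets
        ]
        if self.two_fraction:
            specs.append(ModelSpec(pm_fraction=TWO_FRACTION, lag_set="0", **common))
        return specs


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def load_study_tables(config: RunConfig):
    """Load (or generate-then-reload) the validated, date-aligned inputs.

    Returns ``(MonitorPanel, weather, visits, WildfireCalendar)``.  Synthetic
    configurations write the standard CSVs under the run directory and then
    read them back through the real parsers.
    """
    if config.synthetic is not None:
        params = dict(config.synthetic)
        truth_params = params.pop("truth", None)
        truth = TrueParams(**truth_params) if truth_params else None
        dataset = generate_dataset(seed=config.seed, truth=truth, **params)
        indir = Path(config.outdir) / "inputs"
        paths = write_dataset(dataset, indir)
    else:
        paths = dict(config.paths)
        missing = [k for k in ("monitor", "qualifier", "weather", "visits", "weights") if k not in paths]
        if missing:
            raise ConfigurationError(f"input paths missing entries: {missing}")
    weights = read_weights_yaml(paths["weights"])
    panel = read_monitor_csv(paths["monitor"], weights)
    calendar = read_qualifier_csv(
        paths["qualifier"], panel.dates, monitor_id=config.reference_monitor
    )
    weather = read_weather_csv(paths["weather"]).reindex(panel.dates)
    visits = read_visits_csv(paths["visits"]).reindex(panel.dates)
    if visits.isna().any():
        raise ParseError("visit counts do not cover the monitor panel's date range")
    return panel, weather, visits.astype(np.int64), calendar


def _fit_all(config: RunConfig, visits, exposures, weather):
    """Fit the whole model grid; individual failures become gaps.

    Returns ``(fits, failures)`` where failed models contribute None and a
    label->message entry (e.g. a degenerate wildfire indicator on a short
    series leaves the rest of the grid usable).
    """
    fits, failures = [], {}
    for spec in config.model_specs():
        try:
            design = build_design(visits, exposures, weather, spec)
            fit = select_smoothness(
                design,
                criterion=config.criterion,
                n_grid=config.select_n_grid,
                outer_iterations=config.select_outer_iterations,
            )
        except SmokegamError as exc:
            log.warning("model %s failed: %s", spec.label, exc)
            fits.append(None)
            failures[spec.label] = str(exc)
            continue
        fits.append(fit)
        log.info(
            "fitted %s: edf=%.2f theta=%.2f lambda=%.3g",
            spec.label, fit.spline_edf, fit.nb_dispersion, fit.smoothing_parameter,
        )
    if not any(fit is not None for fit in fits):
        raise SmokegamError(f"every model in the grid failed: {failures}")
    return fits, failures


def _retained_wildfire_observations(exposures: ExposurePanel) -> pd.DataFrame:
    keep = (exposures.wf_indicator("0") == 1.0) & ~exposures.exceedance_mask("0")
    return pd.DataFrame(
        {
            "pm25": exposures.concentration("pm25", "0")[keep],
            "pmc": exposures.concentration("pmc", "0")[keep],
        }
    ).dropna()


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> Path:
    """Execute the pipeline and write all artifacts under ``config.outdir``.

    Stages (in order): ``inputs``, ``exposure``, ``fit``, ``infer``,
    ``sensitivity``.  A stage error aborts the run with the stage name;
    artifacts written by earlier stages are left in place.
    """
    all_stages = ("inputs", "exposure", "fit", "infer", "sensitivity")
    stages = tuple(stages) if stages is not None else all_stages
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages_run": [],
    }
    state: dict = {}
    stage = None
    try:
        for stage in stages:
            if stage == "inputs":
                panel, weather, visits, calendar = load_study_tables(config)
                state.update(panel=panel, weather=weather, visits=visits, calendar=calendar)
                summary["n_days"] = int(len(panel.dates))
                summary["n_monitors"] = len(panel.monitors)
                summary["n_smoke_days"] = int(calendar.n_smoke_days)
            elif stage == "exposure":
                exposures = build_exposure_panel(state["panel"], state["calendar"].hours)
                state["exposures"] = exposures
                exposures.data.to_csv(outdir / "exposure.csv", float_format="%.6g")
                summary["exceedance_thresholds"] = {
                    k: round(v, 6) for k, v in exposures.exceedance_thresholds.items()
                }
                summary["wf_observations_retained"] = {
                    s: int(
                        (
                            (exposures.wf_indicator(s) == 1.0)
                            & ~exposures.exceedance_mask(s)
                        ).sum()
                    )
                    for s in config.lag_sets
                }
            elif stage == "fit":
                fits, failures = _fit_all(
                    config, state["visits"], state["exposures"], state["weather"]
                )
                state["fits"] = fits
                if failures:
                    summary["models_failed"] = failures
                fitdir = outdir / "fits"
                fitdir.mkdir(exist_ok=True)
                for fit in fits:
                    if fit is None:
                        continue
                    name = fit.spec.label if fit.spec else "model"
                    (fitdir / f"{name}.json").write_text(
                        json.dumps(fit.to_dict(), sort_keys=True, indent=1)
                    )
            elif stage == "infer":
                fits = [f for f in state["fits"] if f is not None]
                singles = [f for f in fits if f.spec.pm_fraction != TWO_FRACTION]
                report = model_grid_report(singles)
                report.to_csv(outdir / "model_grid.csv", index=False, float_format="%.10g")
                summary["model_grid"] = report.round(6).to_dict(orient="records")
                twofs = [f for f in fits if f.spec.pm_fraction == TWO_FRACTION]
                if twofs:
                    obs = _retained_wildfire_observations(state["exposures"])
                    surface = evaluate_two_fraction_surface(
                        twofs[0],
                        wildfire_observations=obs,
                        support_radius=config.support_radius,
                        grid_step=config.grid_step,
                    )
                    surface.to_frame().to_csv(
                        outdir / "surface.csv", index=False, float_format="%.10g"
                    )
                    summary["surface_cells_in_support"] = int(surface.in_support.sum())
                    summary["surface_cells_significant"] = int(surface.significant.sum())
                if config.make_plots:
                    from .plots import plot_rate_ratio_grid, plot_surface

                    figdir = outdir / "figures"
                    figdir.mkdir(exist_ok=True)
                    plot_rate_ratio_grid(report, figdir / "rate_ratios.png")
                    if twofs:
                        plot_surface(surface, figdir / "surface.png")
            elif stage == "sensitivity":
                if not config.sensitivity:
                    continue
                sens_specs = [
                    s
                    for s in config.model_specs()
                    if s.pm_fraction != TWO_FRACTION and s.lag_set in config.sensitivity_lag_sets
                ]
                table = run_variants(
                    state["visits"],
                    state["exposures"],
                    state["weather"],
                    sens_specs,
                    criterion=config.criterion,
                    n_grid=config.select_n_grid,
                    outer_iterations=config.select_outer_iterations,
                )
                table.to_csv(outdir / "sensitivity.csv", index=False, float_format="%.10g")
                summary["sensitivity_rows"] = int(len(table))
            summary["stages_run"].append(stage)
    except SmokegamError as exc:
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
        raise SmokegamError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    # runtime deliberately kept out of summary.json so reruns are bit-identical
    (outdir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))
    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, outdir)
    return outdir
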