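"""Sensitivity analyses: alternative meteorological controls.

Re-runs the model grid replacing the 7-day rolling mean-temperature control
with rolling min or max temperature, or adding a 7-day rolling mean-RH
control, and tabulates the estimates side by side against the primary
(mean-temperature, no-RH) variant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import ArgumentError
from .exposure import ExposurePanel
from .inference import model_grid_report
from .nb_gam import ModelSpec, build_design, select_smoothness

__all__ = ["SensitivityVariant", "PRIMARY_VARIANT", "default_variants", "run_variants"]


@dataclass(frozen=True)
class SensitivityVariant:
    """One meteorological-control configuration."""

    label: str
    temperature_metric: str = "mean"
    include_rh: bool = False

    @property
    def is_primary(self) -> bool:
        return self.temperature_metric == "mean" and not self.include_rh


PRIMARY_VARIANT = SensitivityVariant("primary", "mean", False)


def default_variants() -> list[SensitivityVariant]:
    return [
        PRIMARY_VARIANT,
        SensitivityVariant("min_temperature", "min", False),
        SensitivityVariant("max_temperature", "max", False),
        SensitivityVariant("mean_temperature_plus_rh", "mean", True),
    ]


def run_variants(
    visits: pd.Series,
    exposures: ExposurePanel,
    weather: pd.DataFrame,
    specs: list[ModelSpec],
    variants: list[SensitivityVariant] | None = None,
    criterion: str = "reml",
    **select_kwargs,
) -> pd.DataFrame:
    """Fit every model spec under every variant; report with deltas.

    The primary variant is always present and listed first; per variant x
    model the table carries the modification factor, its CI and percent, and
    the difference of the percent from the primary variant's value.
    """
    variants = list(variants) if variants else default_variants()
    if not any(v.is_primary for v in variants):
        variants.insert(0, PRIMARY_VARIANT)
    variants.sort(key=lambda v: 0 if v.is_primary else 1)

    for v in variants:
        needed = f"temp_{v.temperature_metric}"
        if needed not in weather.columns:
            raise ArgumentError(f"variant {v.label!r} needs missing weather column {needed!r}")
        if v.include_rh and "rh" not in weather.columns:
            raise ArgumentError(f"variant {v.label!r} needs missing weather column 'rh'")

    frames = []
    for v in variants:
        fits = []
        for spec in specs:
            vspec = replace(
                spec, temperature_metric=v.temperature_metric, include_rh=v.include_rh
            )
            design = build_design(visits, exposures, weather, vspec)
            fits.append(select_smoothness(design, criterion=criterion, **select_kwargs))
        report = model_grid_report(fits)
        report.insert(0, "variant", v.label)
        frames.append(report)
    table = pd.concat(frames, ignore_index=True)

    primary = table[table["variant"] == variants[0].label]
    key = ["fraction", "lag_set"]
    base = primary.set_index(key)["percent"]
    table["delta_percent_vs_primary"] = [
        row.percent - base.get((row.fraction, row.lag_set), float("nan"))
        for row in table.itertuples()
    ]
    return table
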