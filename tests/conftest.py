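import numpy as np
import pandas as pd
import pytest

from smokegam.exposure import FRACTIONS, MonitorPanel, build_exposure_panel
from smokegam.nb_gam import TWO_FRACTION, ModelSpec, build_design, select_smoothness
from smokegam.synthetic_data import TrueParams, generate_dataset


def make_monitor_panel(dates, monitors):
    """Build a MonitorPanel from {monitor_id: (weight, pm25, pmc, active)}.

    ``pm25``/``pmc`` are per-day lists (None = missing); ``active`` is a
    per-day 0/1 list applied to all fractions.  PM10 is the sum.
    """
    idx = pd.DatetimeIndex(dates)
    values = {f: {} for f in FRACTIONS}
    active = {f: {} for f in FRACTIONS}
    weights = {}
    for mid, (weight, pm25, pmc, act) in monitors.items():
        weights[mid] = weight
        a25 = np.array([np.nan if v is None else float(v) for v in pm25])
        ac = np.array([np.nan if v is None else float(v) for v in pmc])
        for f, arr in zip(FRACTIONS, (a25, ac, a25 + ac)):
            values[f][mid] = arr
            active[f][mid] = np.asarray(act, dtype=bool)
    return MonitorPanel(
        values={f: pd.DataFrame(values[f], index=idx) for f in FRACTIONS},
        active={f: pd.DataFrame(active[f], index=idx) for f in FRACTIONS},
        weights=pd.Series(weights, dtype=float),
    )


@pytest.fixture(scope="session")
def dataset_small():
    """400-day synthetic study with a non-null interaction."""
    truth = TrueParams(beta1_pm=0.01, beta2_interaction=0.06, beta3_wf=0.02)
    return generate_dataset(n_days=400, seed=7, truth=truth)


@pytest.fixture(scope="session")
def dataset_6yr():
    """Full-length (six-year) synthetic study, null interaction."""
    return generate_dataset(n_days=2192, seed=11)


@pytest.fixture(scope="session")
def fit_small(dataset_small):
    ds = dataset_small
    design = build_design(
        ds.visits, ds.exposures, ds.weather, ModelSpec(pm_fraction="pm25", lag_set="0")
    )
    return select_smoothness(design, n_grid=8, outer_iterations=2)


@pytest.fixture(scope="session")
def two_fraction_fit_small(dataset_small):
    ds = dataset_small
    design = build_design(
        ds.visits, ds.exposures, ds.weather, ModelSpec(pm_fraction=TWO_FRACTION, lag_set="0")
    )
    return select_smoothness(design, n_grid=8, outer_iterations=2)


TOY_HOURS = [0, 0, 0, 0, 24, 24, 23, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]


@pytest.fixture()
def toy_panel():
    """17-day two-monitor panel with a staggered activity window."""
    dates = pd.date_range("2015-06-01", periods=17)
    return make_monitor_panel(
        dates,
        {
            "A": (3.0,
                  [10, 12, 8, 9, 30, 50, 45, 12, 11, 10, 9, 8, 10, 11, 12, 9, 10],
                  [5, 6, 5, 5, 8, 9, 7, 6, 5, 5, 4, 5, 6, 5, 5, 6, 5],
                  [1] * 17),
            "B": (1.0,
                  [20, 14, None, 11, 34, 54, 49, 16, 13, 12, 11, 10, 12, 13, 14, 11, 12],
                  [7, 8, None, 6, 9, 10, 8, 7, 6, 6, 5, 6, 7, 6, 6, 7, 6],
                  [1, 1, 0] + [1] * 14),
        },
    )


@pytest.fixture()
def toy_exposures(toy_panel):
    hours = pd.Series(TOY_HOURS, index=toy_panel.dates)
    return build_exposure_panel(toy_panel, hours)
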