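# smokegam

A tested, reusable pipeline for time-series analysis of daily asthma
emergency/urgent-care visit counts against particulate matter (PM) in the
presence versus absence of wildfire smoke:

* **Exposure construction** — population-weighted daily PM2.5 / PM10–2.5 /
  PM10 from multiple monitors with staggered activity windows, rolling
  lag-set averages (lag 0, lags 0–2, lags 0–6), tri-state wildfire
  indicators (1 = all lags smoke-affected, 0 = none, excluded otherwise),
  strict exceedance exclusion of wildfire observations above the
  non-wildfire PM2.5 maximum, and per-monitor activity indicators.
* **Model fitting** — penalized negative-binomial GAMs (log link) with a
  cubic regression spline of time (curvature penalty, REML-type automatic
  smoothness selection, GCV fallback), day-of-week and 17 holiday
  indicators, 7-day rolling temperature (optionally RH), autoregressive
  terms log(1 + lagged count) for lags 1–10, and PM × wildfire interaction
  terms, fitted by penalized IRLS with alternating 1-D ML dispersion
  updates.
* **Inference** — rate ratios per 5 µg/m³ with and without smoke, the
  wildfire modification factor and its percent form, delta-method
  (linear-combination) variances, and the two-fraction percent-increase
  surface over the (PM2.5, PM10–2.5) plane with Wald significance and
  support masking (within 5 µg/m³ of an observed wildfire point).
* **Sensitivity analyses** — min/max temperature and added-RH control
  variants, tabulated against the primary analysis.
* **Synthetic data** — generators for smoke-episode calendars, monitor
  panels, weather, and overdispersed NB counts with known ground truth, so
  the entire pipeline is testable offline.

## CLI

All stages run from a single YAML config (see `RunConfig` in
`smokegam.data_io` for the keys):

```yaml
# run.yaml
synthetic:
  n_days: 2192
seed: 1
outdir: scratch/demo
```

```bash
smokegam run-all --config run.yaml              # everything
smokegam simulate --config run.yaml             # write input CSVs only
smokegam build-exposure --config run.yaml       # + exposure columns
smokegam fit --config run.yaml                  # + 9 single-fraction and the
                                                #   two-fraction model fits
smokegam infer --config run.yaml                # + rate-ratio grid, surface
smokegam sensitivity --config run.yaml          # + meteorological variants
```

Outputs land under `outdir`: input CSVs (`inputs/`), `exposure.csv`, fit
artifacts (`fits/*.json`), `model_grid.csv`, `surface.csv`,
`sensitivity.csv`, and a machine-readable `summary.json` (seed, config
hash, versions). Runs are bit-reproducible under a fixed seed.

Real data can be supplied instead of the synthetic block via `paths:`
(`monitor`, `qualifier`, `weather`, `visits`, `weights`); the CSV dialects
are documented in `smokegam/data_io.py`.

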