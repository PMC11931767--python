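# microconc

Spatial concentration of point events — shootings, crashes, overdoses — at
street-network **microplaces** (individual street segments and
intersections), and how that concentration changes over time.

Place-based violence prevention rests on the observation that events
chronically recur at a small set of microplaces. `microconc` implements a
case-only design that tests whether this concentration persists: every
event gets a binary **repeat** indicator (1 if any other event in the study
period, past or future, occurred at the same microplace), annual
concentration is the share of a year's events with repeat = 1, and the time
trend of the repeat probability is fit with log-binomial regression,

P(repeat = 1) = exp(β₀ + β₁ · year),

so RR = exp(β₁) is the relative risk of being a repeat event per one-year
increment (RR = 0.982 means a 1.8% annual decline in spatial
concentration). A Monte Carlo permutation null — reshuffle the observed
date–location pairs, recompute repeat, refit — checks that the fitted trend
is not an artifact of the study design or of the declining annual caseload.

Because incident-level police data of this kind are typically not
shareable, the package includes a synthetic-data generator that reproduces
the statistical structure of a Boston-scale study (31,152 microplaces,
~3,341 events over 14.75 years, concentration declining from the high 50s
to the high 40s percent), so the entire pipeline is testable end to end.

## Worked example

```python
from microconc import (
    boston_like_config, generate_network, generate_case_series,
    compute_repeat_indicators, annual_concentration, summary_table,
    monte_carlo_null,
)
from microconc.trend import RepeatTrendModel

cfg = boston_like_config(seed=42)
network = generate_network(cfg.n_segments, cfg.n_intersections, seed=cfg.seed)
series = compute_repeat_indicators(generate_case_series(network, cfg))

tab = summary_table(series, network)
print(f"{tab['n_events']} cases; {tab['repeat_pct']}% at repeat locations")

fit = RepeatTrendModel.from_case_series(series).fit()
print(fit.summary())

annual = annual_concentration(series, year_end=cfg.year_end)
d = fit.derive_quantities(14, annual.concentration.iloc[0], len(series) / 14.75)
print(f"aggregate reduction over 14 years: {d.aggregate_relative_reduction:.1f}%")

perm = monte_carlo_null(series, n_trials=999, seed=42, observed=fit)
print(f"Monte Carlo p: {perm.empirical_p:.4g}"
      + (" (upper bound)" if perm.p_is_upper_bound else ""))
```

prints

```
3345 cases; 52.9% at repeat locations
Repeat-location trend (log-binomial / relative-risk scale)
==========================================================
n cases:            3345
family:             log_binomial
RR per year:        0.979
95% CI:             (0.971, 0.987)
p (Wald, 2-sided):  1.16e-07
annual change:      -2.1% per year
aggregate reduction over 14 years: 25.7%
Monte Carlo p: 0.001001 (upper bound)
```

Read: in this synthetic study the probability that a case sits at a repeat
location falls by a factor 0.979 per year (a 2.1% annual decline), the
Wald test rejects a flat trend, and none of the 999 permutation trials
produced a trend of equal magnitude, so the decline is not an artifact of
the shrinking annual caseload.

## Command line

Each stage is also a subcommand of the `microconc` CLI:

```bash
microconc simulate --out-network net.geojson --out-events events.csv --seed 1
microconc assign --network net.geojson --events events.csv --out assigned.csv
microconc concentration --events assigned.csv --network net.geojson \
    --out-annual annual.csv --out-summary summary.csv
microconc trend --events assigned.csv --out trend.json
microconc null --events assigned.csv --trials 10000 --seed 1 --out null.json
microconc report --events events.csv --network net.geojson --out-dir report/
```

`report` runs the whole pipeline and writes a bundle: summary and annual
CSV tables, a model JSON (RR, 95% CI, conventional and Monte Carlo
p-values), annual-count / annual-concentration / map figures, and a run
log.

## Scope

Coordinates are planar (projected); the package performs no geocoding or
CRS transformation. The synthetic generator does not attempt realistic
street topology or covariates — see `docs/methods.md` for the generative
model, its calibration and its limitations.
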