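# Methods

## The design

The analysis is case-only: all units are events (cases), and the question
is whether a characteristic of cases — occurring at a *repeat* microplace —
changes over calendar time. No non-case controls exist for this outcome
(only an event can be a repeat event), which is the standard setting for
case-only designs in epidemiology.

A **microplace** is one street segment or one intersection. The **repeat
indicator** of a case is 1 exactly when the full study series contains at
least one other case at the same microplace — past *or* future; membership
is never evaluated within-year. **Annual spatial concentration** is the
share of a calendar year's cases with repeat = 1. Because membership is
global, a microplace with one case in the first year and one in the last
contributes a repeat case to both years.

## Trend model

The repeat probability is modelled on the log scale,

```
P(repeat_i = 1) = exp(b0 + b1 * year_i)
```

a Bernoulli GLM with log link (log-binomial regression). The log link is
chosen over the logit because exp(b1) is then a **relative risk** per year,
the natural scale for "concentration declined by x% per year" statements;
an odds ratio would overstate the decline at baseline probabilities near
0.5.

* **Year coding.** Default is the integer calendar year, centered at the
  first study year (centering affects only numerics, not the slope). A
  fractional option (`year + (day-of-year - 0.5)/365.25`) is available for
  sensitivity analysis.
* **Fitting.** The Bernoulli likelihood is collapsed to per-year binomial
  counts (identical likelihood, far cheaper — this is what makes a
  10,000-trial permutation null fast). IRLS starts from an OLS line
  through the empirical log-proportions.
* **Fallback.** Log-binomial likelihoods can fail to converge because the
  log link does not respect the (0, 1] range. On non-convergence (or
  fitted probabilities above 1) the model refits as a modified Poisson
  working model on the individual-level data with HC1 sandwich standard
  errors — the standard fallback for risk-ratio estimation. The results
  object records which family was used. On well-behaved data the two
  routes agree within one standard error (tested).
* **Inference.** Wald 95% intervals and two-sided p-values on the log-RR
  scale.
* **Degenerate inputs.** All-0 or all-1 outcomes and single-year series
  raise typed errors rather than returning a fit.

Derived presentation-scale quantities, for a fitted RR over a span of `S`
years with baseline concentration `c0` and mean annual caseload `m`:
annual percent change `100·(RR−1)`; aggregate relative reduction
`100·(1−RR^S)`; absolute reduction `c0·100·(1−RR^S)` percentage points;
events shifted `c0·(1−RR^S)·m`. The span and the caseload divisor are
explicit parameters because different elapsed-time conventions (14 whole
years vs 14.75 fractional years) change the aggregate numbers by a few
percent.

## Permutation null

The null of interest is "the repeat indicator has no association with time
beyond what the design induces". Each trial keeps every case's date and
uniformly permutes the observed multiset of microplace ids across cases,
then recomputes repeat and refits the trend with identical settings. Two
consequences are exact, not approximate: the date vector and location
multiset are conserved, so the pooled repeat count is identical in every
trial; only the location–year association is destroyed. The empirical
p-value is the two-sided extremity fraction `#{|log RR_null| >= |log
RR_obs|}/N`, reported as the upper bound `1/N` when no trial is as extreme;
the bias-safe `(k+1)/(N+1)` estimator is emitted alongside. Trials whose
refit is degenerate are excluded from the denominator (and counted); more
than 50% failures aborts.

A uniform-redraw null (`null_mode="uniform"`), in which each trial draws
locations uniformly over the whole network, is available as a sensitivity
option only: at realistic scales (thousands of events on tens of thousands
of microplaces) uniform redraws collapse the pooled repeat rate to the
birthday-problem floor (~10%), making the null distribution incomparable
with the observed statistic. Permutation is the default for that reason.

Trial RNG streams are derived from the root seed by trial index, so trials
are individually reproducible and order-independent.

## Synthetic data generator

The generator emulates the study conditions the pipeline is designed for;
its defaults (`boston_like_config`) are: 19,071 segments + 12,081
intersections (61.2%/38.8%); study window 2007–2021.75 (the final year
truncated at the end of September, with its expected count scaled by
0.75); annual expected counts declining linearly from 309 (2007) to 156
(2019), a spike of 230 in 2020 and a 118 full-year rate in 2021 — in
expectation ≈3,341 events.

Mechanism: a fixed random **hot set** of microplaces (fraction `f` of the
network) receives routing weight `w0 · d^(y − y0)` in year `y`; all other
microplaces have weight 1. Yearly event counts are Poisson; dates are
uniform within the (possibly truncated) year; locations are drawn
independently with the year's weights. This is the simplest mechanism that
produces both a high repeat baseline and a near-linear decline: as the hot
weight decays, allocation drifts toward uniform and the repeat probability
falls smoothly.

Calibration (by simulation, averaged over 12 seeds): `f = 0.01`,
`w0 = 120`, `d = 0.969` give first-year concentration 0.574 ± 0.006 and
final-year 0.470 ± 0.015, with a fitted RR around 0.987. A note on scale:
concentration has a hard floor at the uniform-allocation birthday value
`1 − (1 − 1/M)^(n−1)`, which is ≈0.10 at the full scale (M = 31,152,
n ≈ 3,341) but ≈0.66 if the network alone is shrunk tenfold while keeping
the caseload. The preset therefore runs at full scale; the `scale`
argument shrinks network and counts *together*, which approximately
preserves concentration levels for cheaper runs.

With `hot_weight0 = 1` the generator reduces to uniform allocation and the
per-event repeat probability equals the closed birthday form above — used
throughout the tests as an independent oracle.

A second generator, `generate_bernoulli_series`, bypasses space entirely
and draws repeat labels directly from `p0 · rr^t`; it is the
parameter-recovery harness for the trend model (the fitted RR should
recover the generative `rr` on average, with nominal CI coverage — both
tested across 200 replicates).

What the generator does **not** emulate: realistic street topology or
lengths, spatial autocorrelation between neighbouring microplaces,
within-year seasonality, covariates (fatal vs nonfatal, demographics), or
displacement dynamics. Tests passing on synthetic data therefore establish
the correctness of the statistical machinery under the stated generative
model, not substantive conclusions about any real city.

## Assignment rules

Raw locations resolve in a fixed precedence: cross-street pair →
intersection (unordered match on normalized labels: lowercase, punctuation
stripped, whitespace collapsed); address/street reference → segment by
normalized label; planar coordinates → nearest microplace by geometric
distance (STRtree-backed; verified against an exhaustive scan), rejected
beyond a snap threshold (default 100 planar units — explicit so exclusions
are reproducible); pre-assigned id → passthrough with validation.
Distance ties are broken by lexicographically smallest id, making
assignment fully deterministic. Events with no usable location are never
guessed: they go to an exclusion log with a reason, and
`|assigned| + |excluded| = |input|` always.

## Numerical and reporting conventions

* Percentages in summary tables are rounded half-up to one decimal at
  display time only; raw proportions are kept at full precision.
* RRs are displayed to 3 decimals; all JSON output carries full precision.
* Years with zero events have undefined (NaN) concentration and are
  flagged rather than imputed; a fractional study end flags the final year
  as partial.
* One root seed drives each operation through named child streams
  (`default_rng([seed, stream, index])`), so outputs are bit-reproducible
  across runs and adding events in one year does not perturb another's
  draws.

## Problem sizes used in the shipped checks

The test suite runs the parameter-recovery study at 200 replicates of
15 years × 10,000 cases, the permutation-calibration study at 200 null
datasets × 199 trials (~300 cases each), and the oracle comparisons at
n ≤ 500; the acceptance script runs the full-scale synthetic study with a
10,000-trial null and a 50-replicate recovery run. These sizes keep Monte
Carlo error comfortably inside the asserted tolerances.
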