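# Methods

## Model

careproj implements a deterministic budget-impact projection for one care
setting over an N-year horizon. The inputs are yearly *schedules* —
constant, linear-between-endpoints, compound-rate or explicit per-year
values — for patients per day per hospital P(t), hospital count H(t) and
minutes saved per patient s(t), plus a year-1 unit cost C0 (currency per
hour of clinical process time), an annual growth rate g applied to that
unit cost, and D operating days per year. Per year,

    T(t)     = P(t) s(t) / 60
    C(t)     = C0 (1 + g)^(t−1)
    S_day(t) = T(t) C(t)

with annual, system-wide and cumulative aggregates derived by multiplying
by D and H(t) and summing. The model assumes time saved converts to money
at the full unit cost (no capacity slack, no partial redeployment), that
inflation acts on the unit cost only and is compounded at the year level,
and that fractional patient or hospital counts are expected values — the
engine never rounds internally. Currency is unit-agnostic; the shipped
baselines use USD.

### Conventions

- **Year indexing is 1-based** and growth uses exponent t−1: the year-1
  unit cost is C0 exactly. The calibrated baselines are only consistent
  with the published year-1 figures under this convention; the year-10
  cost figures in turn pin down the (1+g)^(t−1) compounding — an off-by-one
  exponent, or applying the growth to the hours rather than the cost,
  misses them by more than 7 %.
- Linear schedules return their endpoints bit-exactly (year 1 and year N
  are special-cased; the interior uses start + span·(t−1)/(N−1)).
- All quantities are kept at full double precision; rounding to the
  configured number of decimals (default 2) happens only in report CSVs.
  Checks against published figures use a relative tolerance of 1e−4, which
  absorbs the truncation in those figures (e.g. 1666.66 for 1666.666…).

## Calibrated baselines

The two shipped scenarios reproduce the published endpoints of a 10-year
projection for AI-assisted cardiovascular diagnosis and treatment. Volumes
are published directly (diagnosis: 20→65 patients/day/hospital, 20→38
hospitals; treatment: 20→55, 15→21; both linear). Per-patient saved
minutes are *calibration constants*: the publication gives daily hours
saved and daily patients at years 1 and 10, and dividing the one by the
other fixes the minute endpoints uniquely (diagnosis 200/20 = 10 and
910/65 = 14; treatment 1300/20 = 65 and 7370/55 = 134). Intermediate years
are linearly interpolated, matching the linear style of the volume
schedules; intermediate-year values are therefore a modelling choice, not
published ground truth. Unit costs are USD 500/h (diagnosis) and
USD 1000/h (treatment) with g = 0.10. One parameterization per setting
reproduces all eight published time/cost endpoints simultaneously within
relative 1e−4; this joint consistency is the package's headline check.

## Comparison and net savings

`combine` pairs two projections year by year, reporting the ratio of daily
savings (flagged NaN where the denominator is zero) and the summed
cumulative system savings. `net_savings` subtracts an AI cost model with
two nonnegative parameters: a one-time per-hospital acquisition cost
(capex), charged in year 1 for the year-1 hospital count, and a recurring
per-hospital running cost (opex) charged on each year's hospital count.
Charging capex only for the initial cohort is the simplest defensible
choice when adoption costs for late joiners are unknown; hospitals added
later are treated as equipped out of opex. The payback year is the first
year with cumulative net savings ≥ 0 — the boundary counts as repaid — or
none within the horizon.

## Sensitivity analysis

One-way sweeps replace a single scalar field, addressed by a dotted path
(`cost_growth_rate`, `saved_minutes.end_value`, …), with each grid value
and re-project; grid points that make the scenario invalid yield flagged
missing outcomes rather than aborting. Outcomes are final-year scalars:
daily saving per hospital, cumulative system saving, or daily hours saved.
The elasticity is a central-difference estimate of %Δoutcome/%Δparameter
at the baseline (default relative step 1e−4, capped at 0.1); it is
undefined — and signalled — when the baseline parameter or outcome is
zero. Two closed forms anchor the numerics: savings are exactly linear in
C0 (elasticity 1), and the final-year daily saving scales as (1+g)^(N−1),
giving elasticity (N−1)g/(1+g). One-way sweeps plus elasticities were
chosen as the minimal standard deterministic-sensitivity toolkit;
probabilistic sensitivity analysis is out of scope.

## Synthetic scenarios

The detailed year-by-year assumption tables behind the published model are
not available, so `synthetic` generates structurally faithful stand-ins:
linear patient/hospital/minute schedules with endpoints drawn uniformly
from prior intervals (a decreasing draw is swapped to keep schedules
monotone non-decreasing, as in the baseline curves), and uniform unit cost
and growth rate. Default intervals bracket the two baselines (patients
10–30 → 30–80, hospitals 10–25 → 15–45, saved minutes 5–70 → 10–140, unit
cost 250–1500 USD/h, growth 0–20 %, horizon 10): the realistic range for a
regional hospital network adopting one AI tool. Generation is a
deterministic function of (prior, integer seed); suites use consecutive
seeds. The generator emulates the *structure* of real assumption tables,
not their empirical correlations (volumes, staffing and prices are drawn
independently), so passing property tests demonstrates engine correctness,
not forecast validity.

`recover_inflation` is the matching oracle: on any projection table the
per-year ratio S_day(t)/T(t) equals C(t), so an ordinary least-squares fit
of ln C(t) on t−1, exponentiated, returns g. On noiseless engine output
this recovers the input rate to ~1e−8 across 100 generated scenarios,
which guards jointly against indexing and compounding defects.

## Configuration and I/O

Run configs are JSON, mirroring the scenario types field for field, with
one or two scenarios keyed by role (`diagnosis`, `treatment`), an optional
`ai_costs` block, an output directory and report rounding. Validation is
pydantic-based and the machine-readable JSON Schema is published via
`run_config_schema()`; violations are reported with JSON-pointer-style
locations. Report CSVs use a fixed documented column order, '.' decimals,
no thousands separators and 2-decimal rounding; JSON outputs keep full
precision. The CLI (`careproj`) is a thin composition of the library
stages and is byte-deterministic for fixed inputs.

## Limitations

- No present-value discounting, multi-currency support or per-disease
  submodels; savings are gross of any clinical-outcome effects.
- The AI cost model has no financing or amortization schedule and reports
  no ROI percentage beyond the payback year and net totals.
- Intermediate-year baseline values are interpolations (see above), so
  only endpoint figures are comparable to the published projection.
- Third-party diagnostic-accuracy figures sometimes quoted alongside such
  projections are results of external studies; this model projects time
  and cost only and makes no accuracy claims.
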