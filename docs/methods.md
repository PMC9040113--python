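# Methods

## Scope and model

`cvcrossover` estimates when cardiovascular (CVD) mortality overtakes
cancer mortality during cancer survivorship, on the time-since-diagnosis
axis.  Follow-up begins 1 year after diagnosis (survivors of the acute
treatment period) and ends at all-cause death or administrative
censoring, never later than 25 years.  Censoring at all-cause death
makes every fitted quantity a **cause-specific hazard**: the mortality
rate from one cause among people still alive at that time.  This
conditions on survival to each time point — appropriate for counselling
current survivors — and deliberately differs from subdistribution
(Fine–Gray) modelling, which is out of scope.

Four cause-of-death categories are used throughout: `cvd`,
`primary_cancer` (the person's own first cancer), `other_cancer`, and
`other`.  Reported outcomes are CVD, the primary cancer, and *any*
cancer (primary + other).  Each death carries an underlying and an
immediate cause; analyses can switch between them (sensitivity
analysis for death-certificate coding).

## Person-time splitting

Follow-up is split into half-open bands `[a, b)`; defaults
`[1,2), [2,3), [3,4), [4,5), [5,10), [10,15), [15,25)` years with
midpoints 1.5, 2.5, 3.5, 4.5, 7.5, 12.5, 20.  A death at an exact
boundary belongs to the band being entered (half-open convention,
matching "1 to <2"-style definitions); a death at the exact end of
coverage (25.0) stays in the last band so no event is lost.  Band
person-years are interval overlaps, so they re-sum to `exit − entry`
exactly (the suite asserts ≤ 1e-9 years over randomized records).
Tabulation is a pure aggregation and is invariant to record order.

## Rate models

Per site, cause, and (by default) age stratum, deaths over person-years
per band follow a Poisson log-linear model with a `log PY` offset and
categorical band effects.

* **Stratified (default, `age_interaction=True`)** — one fit per age
  stratum is saturated in band, so the MLE predicted rate in each cell
  is the crude rate `d / PY`; the closed form is used directly, and a
  test cross-checks it against an independently specified statsmodels
  GLM fit.  The stratified default reproduces age-specific curve
  *shapes* without borrowing across ages.
* **Main effects (`age_interaction=False`)** — a single multiplicative
  age + band model fitted by IRLS (statsmodels GLM; maxiter 100,
  tolerance 1e-10, convergence failure raised, never silently
  accepted).  Kept because the analysis description that motivated the
  pipeline is ambiguous about age × time interactions; on tables with
  exactly multiplicative structure it reproduces the generating rates.

Cells with zero person-years are **undefined**, never zero — a silent
zero would fabricate a crossover.  Rates are reported per 1,000
person-years.

CIs are log-rate Wald intervals `rate · exp(±z/√d)`; with zero deaths
the lower bound is 0 and the upper is the exact Poisson bound
`−ln(α/2)/PY`.  The construction is a package choice (plot bands of
this kind rarely state theirs).  Curves can be truncated at the first
band whose CI width exceeds a threshold (default 50 per 1,000 p-y);
zero-death and undefined bands trip the rule regardless of nominal
width, and every later band is suppressed with the first offender.

## Crossover estimation

Predicted rates sit at band midpoints.  The crossover is the first
adjacent pair of defined midpoints where (CVD − cancer) changes sign
from negative to non-negative; both curves are interpolated linearly on
the natural rate scale between those midpoints (log-scale interpolation
is available as a sensitivity switch).  Exact equality at a midpoint
returns that midpoint.  Statuses: `crossed`,
`already_overtaken_at_first_midpoint` (no numeric time),
`never_within_horizon` (including interpolated times past the
reporting horizon, default 20 years), `undefined_cells`.  When an
interior band is undefined, the scan bridges the gap by interpolating
between the nearest defined midpoints rather than aborting.  Only the
first overtaking is reported; later re-crossings are ignored.

Bootstrap CIs resample individuals (not person-time cells) with
replacement within the site cohort, size preserved, unstratified by age
by default (an age-stratified option is provided); the full pipeline is
re-run per replicate.  The CI is the 2.5th/97.5th percentile of
replicate crossover times using numpy's linear interpolation between
order statistics, so endpoints are bit-for-bit reproducible at a fixed
seed.  Replicates that do not cross are excluded from the percentiles
but always counted and reported — dropping them silently would bias the
CI invisibly — and the CI is flagged unstable when they exceed 5% of
replicates.

## Synthetic cohorts

The generator inverts the structure the pipeline estimates: each
stratum carries piecewise-constant or piecewise-linear cause-specific
hazards λ_c(t) on [1, 25] (both admit closed-form cumulative hazards).
A total-hazard event time is drawn by exact inversion sampling — solve
H(t) = E with E ~ Exp(1), piecewise-quadratic H — and the cause is
multinomial with probabilities λ_c(t)/Σλ(t) at the drawn time.
Administrative censoring is a per-person uniform draw on a window of
potential follow-up (default [5, 24] years after entry), emulating
staggered diagnosis dates against a fixed study end; a scalar gives
fixed censoring and `None` censors only at the horizon.  The recorded
immediate cause equals the underlying cause except with probability
`p_disagree` (default 0.05), when another category is drawn uniformly —
a deliberately mechanism-free stand-in for discordant death
certificates.

Because the hazards are analytic, `true_crossover` returns the exact
first time one hazard overtakes another (root within a linear piece,
touch-and-rise, or jump at a piecewise-constant breakpoint), giving
ground truth for end-to-end recovery tests.  The `survivor_cohort_specs`
preset encodes the qualitative survivorship pattern — primary-cancer
mortality declining with time since diagnosis, CVD mortality rising
steeply in the oldest stratum — across 9 sites × 3 age groups with
cohort sizes of the order of a large national primary-care cohort;
its values are illustrative, not fitted.  `linear_crossing_specs(t*)`
builds a single stratum whose CVD hazard (2 + 2(t−1) per 1,000 p-y)
crosses a declining cancer hazard (slope −3 per 1,000 p-y per year,
floored at 0.5) at exactly `t*`.

What the generator does **not** emulate: calendar-time and
age-period-cohort structure, treatment/stage/recurrence effects,
within-stratum frailty, or informative censoring.  Passing recovery
tests therefore demonstrate correctness of the estimation machinery
under the stated hazard families, not fidelity of any particular
real-world cohort.

## Known limitation: discretisation bias of midpoint interpolation

Band-level crude rates estimate the *person-time-weighted mean* hazard
over each band, not the hazard at the band midpoint.  With declining
within-band risk sets (depletion by death, and administrative censoring
falling inside a band) the effective time of a band sits earlier than
its midpoint, so for a rising CVD curve and a falling cancer curve the
interpolated crossover converges, as n grows, to a value slightly
*later* than the generating crossover.  For the default
`linear_crossing_specs(8.0)` conditions the large-sample limit is
≈ 8.22 years (computed by numerically integrating the S(t)·G(t)-weighted
hazards over bands) — an offset of about +0.22 years, well inside the
±0.5-year recovery tolerance but larger than a percentile-bootstrap CI
halfwidth at n = 100,000.  The bootstrap quantifies sampling noise
only; it cannot see this deterministic offset, so at very large n the
CI concentrates around the biased limit rather than the generating
truth.  One acceptance test documents exactly this (it asserts CI
coverage of the generating value and fails).  The bias shrinks with
narrower bands and grows in the wide late bands — the 20-configuration
recovery experiment shows errors of ~0.05 years for early crossovers
and ~1.9 years at 18 years, with median ≈ 0.3.

## Problem sizes and determinism

The verification experiments use n = 100,000 persons per simulated
stratum for distributional checks and crossover recovery (binomial /
truncated-exponential standard errors small enough for 3-SE
assertions), B = 50 bootstrap replicates for the recovery CI, 10,000
records for conservation, and 1,000 randomized curve pairs against a
1e-5-step grid; unit tests use cohorts of 2,000–50,000.  All
randomness flows through `numpy.random.default_rng` seeds; identical
seeds and specs give identical cohorts, identical bootstrap CIs, and
byte-identical pipeline reports.
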