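# Methods

## Exposure construction

Monitor-level daily PM2.5 readings are processed in a fixed order:
instrument correction, county averaging, neighbor imputation, baseline
pairing.

**Nephelometer correction.** Optical nephelometers, calibrated against
gravimetric FRM monitors under routine conditions, overestimate PM2.5 in
dense smoke because the smoke aerosol's size distribution differs from the
calibration aerosol's. Readings from nephelometer-type monitors that exceed
20 µg/m³ are divided by 1.207 (a 20.7% overestimate); FRM-type readings and
readings at or below 20 µg/m³ are untouched. The correction is applied per
reading, *before* county averaging, because the bias is a property of the
instrument, not of the county mean — averaging first would blend biased and
unbiased mass and make the correction threshold ill-defined.

**County averaging and imputation.** A county-day exposure is the unweighted
arithmetic mean of that county's reporting monitors. Counties with no
monitor borrow the unweighted mean of their adjacent monitored counties'
same-day values ("neighbor-imputed" provenance). Imputation touches only
missing county-days and never chains through other imputed values, which
makes the aggregate-then-impute step idempotent; an unmonitored county with
no monitored neighbor on some day is a hard error naming the county and
date rather than a silent gap.

**Baseline pairing.** The counterfactual is the identical calendar window
one year earlier (default: September 7–19). Episode day k is paired with
baseline day k by position within the window; no weekday alignment is
attempted because the windows are matched calendar dates. The resulting
Δc = episode − baseline keeps its sign in the delta table — flooring is an
attribution-stage policy, not an exposure fact — and the smoke-day flag uses
the strict rule PM2.5 > 20.4 µg/m³ on the episode concentration. A
documented secondary classification for the 9.0–20.4 µg/m³ band exists in
the case-crossover literature but is not reproduced here; the threshold is
a parameter and a user-supplied classifier can replace the rule.

## Burden estimation

**Acute.** AF = 1 − e^(−βΔc⁺) per county-day under the CRF convention, with
β = ln(1 + p/100)/10. The log-linear conversion (rather than the linear
p/1000) is the form consistent with the exponential AF; the linear variant
is available via `beta_from_percent(..., form="linear")` for comparison with
tools that linearize the CRF. Negative Δc is floored at zero per county-day:
the estimand is the burden of *increased* exposure, and un-floored negative
days would report negative deaths. Under the OR convention
AF = (OR − 1)/OR on smoke days and 0 elsewhere; baseline-period days are
assumed non-smoke (the baseline window is by construction a low-smoke
period). Daily deaths are AF × (annual rate/365) × population, summed over
the 13 days and then over counties; the statewide row is the exact sum of
county rows.

**Intervals.** Reported intervals propagate only the response-function CI,
by re-running the identical computation at the lower/central/upper
coefficient. This reproduces the characteristic hard zero floor: when the
CRF's lower bound is 0.00% (or the OR's is 1.00), the burden lower bound is
exactly 0, not a small positive number. Exposure uncertainty is handled
separately (below), not folded into these intervals.

**Chronic.** The episode's summed floored increase is spread over the year,
c_annual = Σ_k Δc_k⁺ / 365 (a constant 97.1 µg/m³ over 13 days gives
3.458 µg/m³), and annual-cohort CRFs (all-cause 5.60%, cardiorespiratory
12.90% per 10 µg/m³) are applied to the *annual* mortality rate:
ΔY = AF × Y₀ × Pop with no /365. Flooring matches the acute policy so the
two horizons share one delta table.

## Intervention scenarios

A scenario scales what people breathe: episode concentrations become
(1 − f) × PM2.5 while the baseline is untouched, and smoke-day status is
re-classified on the scaled values. Avoided mortality is
burden(unmitigated) − burden(reduced), computed bound-by-bound so the zero
floors survive. Under the CRF convention avoided mortality is continuous
and nondecreasing in f; under the OR convention it is a step function whose
jumps sit exactly at f = 1 − 20.4/c for each county-day concentration c —
scenario grids that straddle such a crossing show abrupt gains. The
conventional grid 10/40/70/80% carries the field's rounding of measured
indoor infiltration factors (windows open 0.92, windows closed 0.56, MERV-13
box fan 0.3, HEPA PAC 0.19); the labels keep those round figures rather
than re-derived complements. Poverty-targeted scenarios use the poverty
population as the exposed population in both runs — the untargeted
remainder is identical in both worlds and cancels. PAC program cost is
households = round(poverty population / household size), default 2.55
persons per household, times $150 per device.

## Monte Carlo exposure sensitivity

Within-county spatial variation is summarized by the relative standard
deviation RSD = SD/mean over a county-day's monitors (sample SD, ddof = 1),
computable only where ≥ 2 monitors report; all other county-days receive
the pooled mean of the multi-monitor county-day RSDs. Each episode
county-day concentration is then redrawn n_draws times (default 5,000,
default seed 123) from a log-normal with arithmetic mean equal to the
observed value and that RSD, reflecting the right skew of daily PM2.5;
baseline concentrations are held fixed. Draws are independent across
county-days — no spatiotemporal correlation is imposed.

The log-normal is parameterized by the method of moments, σ² = ln(1 + r²),
μ = ln m − σ²/2, so the configured (mean, RSD) are exactly recoverable;
r = 0 degenerates to the observed value exactly (no exp/log round trip),
making the RSD → 0 collapse to the deterministic estimate exact rather than
approximate.

The combined interval convention is
[2.5th percentile of draw totals at β_low, 97.5th percentile at β_high]:
the lower edge keeps the exact zero floor (a response-CI effect) while the
upper edge exceeds the deterministic upper bound whenever exposure
variation is material. The central estimate is the mean of draw totals at
the central coefficient; with any symmetric-enough draw distribution it
stays at the deterministic point, which is why the Monte Carlo analysis
changes the interval but not the headline estimate.

## Synthetic study region

The generator emulates a Pacific-Northwest-scale smoke event and nothing
more — its purpose is statistical structure, not geography:

* ~39 counties with 0–8 monitors each; the sampled network is patched so
  that (where the configuration permits) at least one county is unmonitored
  and at least one has ≥ 2 monitors, so the imputation and RSD paths are
  always exercised, and every unmonitored county touches a monitored
  neighbor. Adjacency is a ring plus random chords — connected and
  symmetric, with no pretense of real county geometry.
* Baseline county-day true means: Normal(6.0, 4.6) µg/m³ truncated at zero
  by redraw. Episode true means add a county-level increase drawn once per
  county from Normal(97.1, 28.5), truncated at zero by redraw; at 3.4σ from
  zero the truncation bias is negligible (< 0.05 µg/m³). An
  `episode_increase_mean` of exactly 0 is the no-episode null and sets all
  increases identically to zero — a truncated draw around zero would
  otherwise have mean ≈ 22.7 µg/m³ and not be a null at all.
* Monitor readings scatter around the true county-day mean with a
  within-county RSD of 0.25 by default. No published figure pins this
  magnitude (only that a pooled multi-monitor average was used), so 0.25 was
  chosen once as a realistic spatial RSD for daily PM2.5 during a regional
  smoke event and is a config field, not an estimate.
* Half the monitors are nephelometer-type, and by default their readings
  above 20 µg/m³ are inflated by 1.207 — exactly the bias the exposure
  stage's correction removes, so on synthetic data correction-then-recovery
  is an exact round trip.
* Demographics are drawn once per county: population log-uniform on
  2.2×10³–2.25×10⁶ (county sizes spanning rural to metropolitan), poverty
  fraction uniform on 0.06–0.22, annual mortality rates uniform on
  6.0–11.0 (all-cause), 0.6–1.2 (respiratory) and 2.0–4.2
  (cardiorespiratory) per 1,000 person-years — magnitudes matching US
  county vital statistics.
* A single seed (default 123) drives the whole generation; identical seeds
  give byte-identical tables.

The generator also records the true county-day means it drew (the
ground-truth sidecar) and computes the burden they imply in one closed-form
vectorized expression, independent of the attribution module. Feeding the
true means through the pipeline reproduces that analytic burden to
≤ 10⁻⁹ relative error, which tests the bookkeeping (pairing, flooring,
summing) end to end.

What the generator does *not* emulate: meteorology and plume transport,
monitor siting, population-weighted within-county exposure, weekday
structure, or measurement error beyond the log-normal scatter and the
nephelometer bias. Passing tests therefore demonstrate that the pipeline's
arithmetic and invariants are correct under the stated statistical
assumptions — not that those assumptions describe any particular real
episode.

## Numerical choices and problem sizes

* All burden arithmetic is float64; `log1p`/`expm1` are used where the
  argument is small.
* Smoke-day and nephelometer thresholds are strict (`>`), so boundary
  values (20.4, 20.0) fall on the inactive side.
* Household counts round half away from zero to the nearest household.
* Per-capita rankings sort descending with ties broken by county id under a
  stable sort.
* The test suite runs the full 39-county region for recovery and summary
  checks, a 10-county region for Monte Carlo integration checks, and
  reduced draw counts (200–1,000; 5,000 only where convergence itself is
  the claim). These sizes keep the default suite under a minute while
  leaving every statistical check at ≥ 3σ separation.

## Known limitations

* Imputation uses the unweighted mean of all adjacent monitored counties;
  no designated-donor or distance weighting.
* The OR convention's secondary smoke-day criteria for the 9.0–20.4 µg/m³
  band are not implemented (pluggable classifier instead).
* Intervals treat response-function and exposure uncertainty asymmetrically
  (re-run bounds vs. Monte Carlo percentiles); they are not a joint
  posterior.
* No age stratification, lag structure, or mortality displacement
  adjustment; cardiovascular-only ORs are excluded as non-significant in
  the source evidence.
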