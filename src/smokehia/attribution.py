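"""Attributable-fraction burden estimation.

Two attribution conventions are supported, bracketing the uncertainty about
how toxic wildfire-smoke PM2.5 is relative to everyday ambient PM2.5:

* CRF convention — a log-linear concentration-response function for total
  PM2.5: AF = 1 - exp(-beta * delta_c), with beta = ln(1 + p/100) / 10 for a
  published p% increase in mortality per 10 ug/m3. Applied to every episode
  day's concentration increase over baseline (floored at zero: burden is
  attributed to *increased* exposure only).
* OR convention — a smoke-day odds ratio from case-crossover evidence:
  AF = (OR - 1)/OR, applied only on days classified as smoke days,
  irrespective of concentration magnitude.

Daily excess deaths follow the standard burden identity
    dY = AF * (Y0 / 365) * Pop
with Y0 the county's cause-specific annual mortality rate and Pop its exposed
population; county-days are summed over the episode and then over counties.

Chronic (annualized) burden spreads the episode's summed concentration
increase over the year and applies annual-cohort CRFs to the *annual* rate
(no /365).

Uncertainty intervals propagate the response-function confidence bounds by
re-running the pipeline at the lower/central/upper coefficient; a published
lower bound of 0.00% (or OR = 1.00) therefore yields a burden lower bound of
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDemographicsError

RF_KINDS = ("crf_percent_per_10", "smoke_day_or", "annual_crf_percent_per_10")


@dataclass(frozen=True)
class ResponseFunction:
    """A mortality response function with its 95% confidence bounds.

    ``central``/``ci_low``/``ci_high`` are percent-per-10-ug/m3 for the CRF
    kinds and dimensionless odds ratios for ``smoke_day_or``.
    """

    kind: str
    endpoint: str
    central: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if self.kind not in RF_KINDS:
            raise ValueError(f"unknown response-function kind {self.kind!r}")
        if not (self.ci_low <= self.central <= self.ci_high):
            raise ValueError("require ci_low <= central <= ci_high")

    @property
    def flagged_protective(self) -> bool:
        """True when any bound implies a negative attributable fraction."""
        if self.kind == "smoke_day_or":
            return self.ci_low < 1.0 - 1e-12
        return self.ci_low < 0.0


# Published coefficients used throughout: a West Coast time-series CRF for
# daily all-cause mortality, Washington case-crossover smoke-day ORs, and the
# American Cancer Society cohort CRFs for annual exposure.
CRF_ACUTE_ALL_CAUSE = ResponseFunction("crf_percent_per_10", "all_cause", 0.50, 0.00, 1.01)
OR_SMOKE_DAY_ALL_CAUSE = ResponseFunction("smoke_day_or", "all_cause", 1.02, 1.00, 1.05)
OR_SMOKE_DAY_RESPIRATORY = ResponseFunction("smoke_day_or", "respiratory", 1.09, 1.00, 1.18)
CRF_ANNUAL_ALL_CAUSE = ResponseFunction(
    "annual_crf_percent_per_10", "all_cause", 5.60, 3.50, 7.80
)
CRF_ANNUAL_CARDIORESPIRATORY = ResponseFunction(
    "annual_crf_percent_per_10", "cardiorespiratory", 12.90, 9.50, 16.40
)

DEFAULT_ACUTE_RFS = (CRF_ACUTE_ALL_CAUSE, OR_SMOKE_DAY_ALL_CAUSE, OR_SMOKE_DAY_RESPIRATORY)
DEFAULT_ANNUAL_RFS = (CRF_ANNUAL_ALL_CAUSE, CRF_ANNUAL_CARDIORESPIRATORY)


def beta_from_percent(percent_per_10: float, form: str = "log_linear") -> float:
    """Convert a percent increase per 10 ug/m3 into beta per ug/m3.

    The log-linear form ln(1 + p/100)/10 is consistent with the exponential
    attributable fraction; ``form="linear"`` (p/100/10) is exposed for
    sensitivity comparisons with tools that linearize the CRF.
    """
    if percent_per_10 <= -100:
        raise ValueError("percent_per_10 must exceed -100")
    if form == "log_linear":
        return float(np.log1p(percent_per_10 / 100.0) / 10.0)
    if form == "linear":
        return percent_per_10 / 100.0 / 10.0
    raise ValueError(f"unknown CRF form {form!r}")


def af_crf(beta: float, delta_c) -> np.ndarray | float:
    """Attributable fraction 1 - exp(-beta * delta_c).

    ``delta_c`` is assumed already floored at zero under the acute policy;
    for beta, delta_c >= 0 the result lies in [0, 1).
    """
    return -np.expm1(-beta * np.asarray(delta_c, dtype=float))


def af_or(or_value: float) -> float:
    """Attributable fraction (OR - 1)/OR of the smoke-day convention."""
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    return (or_value - 1.0) / or_value


def excess_daily(af, annual_rate, population):
    """Daily excess deaths dY = AF * (annual rate / 365) * population."""
    return np.asarray(af, dtype=float) * (
        np.asarray(annual_rate, dtype=float) / 365.0
    ) * np.asarray(population, dtype=float)


def _check_demographics(deltas, demo, endpoint):
    rate_col = f"rate_{endpoint}"
    if rate_col not in demo.columns:
        raise MissingDemographicsError([f"<rate column {rate_col}>"])
    missing = set(deltas["county_id"]) - set(demo["county_id"])
    if missing:
        raise MissingDemographicsError(sorted(missing))
    return rate_col


def _acute_county_totals(deltas, demo, rf, value, population_col):
    """Per-county summed excess deaths at one response-coefficient value."""
    rate_col = f"rate_{rf.endpoint}"
    d = deltas.merge(demo[["county_id", population_col, rate_col]], on="county_id")
    if rf.kind == "crf_percent_per_10":
        floored = np.maximum(d["delta_c"].to_numpy(), 0.0)
        af = af_crf(beta_from_percent(value), floored)
    elif rf.kind == "smoke_day_or":
        af = np.where(d["smoke_day"].to_numpy(), af_or(value), 0.0)
    else:
        raise ValueError(f"{rf.kind!r} is not an acute response function")
    d = d.assign(dy=excess_daily(af, d[rate_col], d[population_col]))
    return d.groupby("county_id")["dy"].sum()


def _assemble(county_totals, demo, rf, approach, horizon, population_col):
    """Stack per-county central/low/high totals plus the statewide sum."""
    central, low, high = county_totals
    pop = demo.set_index("county_id")[population_col].reindex(central.index)
    rows = pd.DataFrame(
        {
            "scope": "county",
            "county_id": central.index,
            "endpoint": rf.endpoint,
            "approach": approach,
            "horizon": horizon,
            "excess_deaths_central": central.to_numpy(),
            "excess_deaths_low": low.reindex(central.index).to_numpy(),
            "excess_deaths_high": high.reindex(central.index).to_numpy(),
            "per_100k": central.to_numpy() * 1e5 / pop.to_numpy(),
        }
    )
    state = pd.DataFrame(
        {
            "scope": ["statewide"],
            "county_id": [pd.NA],
            "endpoint": [rf.endpoint],
            "approach": [approach],
            "horizon": [horizon],
            "excess_deaths_central": [central.sum()],
            "excess_deaths_low": [low.sum()],
            "excess_deaths_high": [high.sum()],
            "per_100k": [central.sum() * 1e5 / pop.sum()],
        }
    )
    return pd.concat([rows, state], ignore_index=True)


def run_acute(
    deltas: pd.DataFrame,
    demo: pd.DataFrame,
    rf: ResponseFunction,
    population_col: str = "population",
) -> pd.DataFrame:
    """Episode-scale excess mortality per county and statewide.

    CRF convention: every county-day contributes via its floored delta_c.
    OR convention: only smoke days contribute, with a constant AF.
    Interval bounds re-run the computation at ``rf.ci_low``/``rf.ci_high``.

    Returns a burden table with one row per county plus a statewide row
    (columns: scope, county_id, endpoint, approach, horizon,
    excess_deaths_central/low/high, per_100k).
    """
    _check_demographics(deltas, demo, rf.endpoint)
    approach = "crf" if rf.kind == "crf_percent_per_10" else "or"
    totals = tuple(
        _acute_county_totals(deltas, demo, rf, v, population_col)
        for v in (rf.central, rf.ci_low, rf.ci_high)
    )
    return _assemble(totals, demo, rf, approach, "acute_episode", population_col)


def annual_increment(deltas: pd.DataFrame) -> pd.Series:
    """Per-county annualized concentration increase, ug/m3.

    The episode's summed (floored) daily increases spread over 365 days:
    sum_k max(delta_c_k, 0) / 365.
    """
    floored = deltas.assign(f=np.maximum(deltas["delta_c"], 0.0))
    return floored.groupby("county_id")["f"].sum() / 365.0


def run_chronic(
    deltas: pd.DataFrame,
    demo: pd.DataFrame,
    rf: ResponseFunction,
    population_col: str = "population",
) -> pd.DataFrame:
    """Annualized (chronic-scale) burden of the episode's exposure increment.

    Applies an annual-cohort CRF to the per-county annual increment; the
    excess is AF * annual rate * population (a per-year quantity, so no /365
    conversion).
    """
    if rf.kind != "annual_crf_percent_per_10":
        raise ValueError("run_chronic requires an annual CRF response function")
    rate_col = _check_demographics(deltas, demo, rf.endpoint)
    inc = annual_increment(deltas)
    base = demo.set_index("county_id").loc[inc.index]

    def _totals(value):
        af = af_crf(beta_from_percent(value), inc.to_numpy())
        return pd.Series(
            af * base[rate_col].to_numpy() * base[population_col].to_numpy(),
            index=inc.index,
        )

    totals = tuple(_totals(v) for v in (rf.central, rf.ci_low, rf.ci_high))
    return _assemble(totals, demo, rf, "crf", "chronic_annual", population_col)


def statewide(burden: pd.DataFrame) -> pd.Series:
    """The statewide row of a burden table, as a Series."""
    rows = burden[burden["scope"] == "statewide"]
    if len(rows) != 1:
        raise ValueError("expected exactly one statewide row")
    return rows.iloc[0]
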