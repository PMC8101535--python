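"""Synthetic study-region generator.

Builds a complete, self-contained set of inputs for the county-level wildfire
smoke health impact assessment: a monitor network over a configurable number
of counties (some unmonitored, so neighbor imputation is exercised; some with
several monitors, so spatial RSD estimation is exercised), daily monitor-level
PM2.5 series for a quiet baseline window and a smoke-episode window, and
county demographics (population, poverty population, cause-specific annual
mortality rates).

The generator emulates the statistical structure of a Pacific-Northwest-style
regional smoke event: a low, stable baseline (daily means around 6 ug/m3 with
SD 4.6), a multi-day episode that raises county means by roughly 97 ug/m3
with a cross-county SD of 28.5, and right-skewed within-county monitor
readings drawn from a moment-matched log-normal.

Alongside the observable monitor table, the generator records the true
county-day means it drew ("ground truth sidecar") and can compute the burden
those true means imply in closed form, so downstream stages can be tested for
exact parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import draw_lognormal
from .errors import ConfigurationError

ENDPOINTS = ("all_cause", "respiratory", "cardiorespiratory")

MONITOR_TYPES = ("frm", "nephelometer")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study region.

    Concentration parameters are in ug/m3; mortality rates in deaths per
    person-year. ``episode_increase_mean == 0`` encodes the no-episode null:
    county-level increases are then identically zero rather than drawn from a
    truncated normal (whose truncation would otherwise shift the mean).
    """

    n_counties: int = 39
    monitors_per_county_range: tuple[int, int] = (0, 8)
    episode_days: int = 13
    baseline_mean: float = 6.0
    baseline_sd: float = 4.6
    episode_increase_mean: float = 97.1
    episode_increase_cross_county_sd: float = 28.5
    within_county_rsd: float = 0.25
    population_range: tuple[int, int] = (2_200, 2_250_000)
    poverty_fraction_range: tuple[float, float] = (0.06, 0.22)
    annual_mortality_rate_range: dict = field(
        default_factory=lambda: {
            "all_cause": (0.0060, 0.0110),
            "respiratory": (0.0006, 0.0012),
            "cardiorespiratory": (0.0020, 0.0042),
        }
    )
    nephelometer_fraction: float = 0.5
    simulate_neph_bias: bool = True
    neph_bias_fraction: float = 0.207
    neph_bias_above: float = 20.0
    episode_start: str = "2020-09-07"
    baseline_start: str = "2019-09-07"
    seed: int = 123

    def validate(self) -> None:
        lo, hi = self.monitors_per_county_range
        if self.n_counties < 1:
            raise ConfigurationError("n_counties must be >= 1")
        if lo < 0 or hi < lo:
            raise ConfigurationError("monitors_per_county_range must satisfy 0 <= min <= max")
        if hi == 0:
            raise ConfigurationError(
                "all counties forced to zero monitors: no county could ever be monitored"
            )
        if self.episode_days < 1:
            raise ConfigurationError("episode_days must be >= 1")
        if self.within_county_rsd < 0:
            raise ConfigurationError("within_county_rsd must be >= 0")
        for name, (a, b) in (
            ("population_range", self.population_range),
            ("poverty_fraction_range", self.poverty_fraction_range),
        ):
            if a < 0 or b < a:
                raise ConfigurationError(f"{name} must satisfy 0 <= min <= max")
        if self.population_range[0] < 1:
            raise ConfigurationError("population_range minimum must be >= 1")
        if self.poverty_fraction_range[1] > 1:
            raise ConfigurationError("poverty fractions must lie in [0, 1]")
        for ep in ENDPOINTS:
            a, b = self.annual_mortality_rate_range[ep]
            if not (0 <= a <= b < 1):
                raise ConfigurationError(f"mortality rate range for {ep} must lie in [0, 1)")
        if self.baseline_mean <= 0 or self.baseline_sd < 0:
            raise ConfigurationError("baseline_mean must be > 0 and baseline_sd >= 0")
        if self.episode_increase_mean < 0 or self.episode_increase_cross_county_sd < 0:
            raise ConfigurationError("episode increase parameters must be non-negative")
        if not (0 <= self.nephelometer_fraction <= 1):
            raise ConfigurationError("nephelometer_fraction must lie in [0, 1]")
        if self.neph_bias_fraction <= -1 or self.neph_bias_above < 0:
            raise ConfigurationError(
                "neph_bias_fraction must be > -1 and neph_bias_above >= 0"
            )


def _county_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"C{i:0{width}d}" for i in range(1, n + 1)]


def generate_counties(cfg: SyntheticConfig):
    """Draw the county table, monitor network and adjacency structure.

    Returns
    -------
    counties : DataFrame
        county_id, n_monitors, population, poverty_population and one
        ``rate_<endpoint>`` column per mortality endpoint.
    monitors : DataFrame
        monitor_id, county_id, monitor_type.
    adjacency : DataFrame
        county_id, neighbor_id; symmetric (both directions present).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_counties
    ids = _county_ids(n)
    lo, hi = cfg.monitors_per_county_range

    n_monitors = rng.integers(lo, hi + 1, size=n)
    # Guarantee the network exercises every downstream path that the
    # configuration permits: at least one monitored county always; at least
    # one unmonitored county when min allows 0; at least one multi-monitor
    # county when max allows >= 2.
    if n_monitors.max() == 0:
        n_monitors[int(rng.integers(n))] = hi
    if lo == 0 and n >= 2 and not (n_monitors == 0).any():
        monitored = np.flatnonzero(n_monitors > 0)
        n_monitors[monitored[int(rng.integers(monitored.size))]] = 0
        if n_monitors.max() == 0:  # n == the only monitored one we just zeroed
            n_monitors[int(rng.integers(n))] = hi
    if hi >= 2 and not (n_monitors >= 2).any():
        candidates = np.flatnonzero(n_monitors > 0)
        if candidates.size == 0:
            candidates = np.arange(n)
        n_monitors[candidates[int(rng.integers(candidates.size))]] = 2
    if (n_monitors == 0).all():
        raise ConfigurationError("configuration leaves every county unmonitored")
    if n == 1 and n_monitors[0] == 0:
        raise ConfigurationError("a single-county region must be monitored")

    # Adjacency: a ring (connected) plus random chords, then patched so every
    # unmonitored county touches at least one monitored county.
    edges: set[tuple[int, int]] = set()
    if n > 1:
        for i in range(n):
            j = (i + 1) % n
            edges.add((min(i, j), max(i, j)))
        n_chords = n // 3
        for _ in range(n_chords):
            i, j = rng.choice(n, size=2, replace=False)
            edges.add((min(i, j), max(i, j)))
    monitored_idx = np.flatnonzero(n_monitors > 0)
    for i in np.flatnonzero(n_monitors == 0):
        neigh = {b for a, b in edges if a == i} | {a for a, b in edges if b == i}
        if not any(n_monitors[j] > 0 for j in neigh):
            j = int(monitored_idx[int(rng.integers(monitored_idx.size))])
            edges.add((min(i, j), max(i, j)))

    adjacency = pd.DataFrame(
        [(ids[a], ids[b]) for a, b in sorted(edges)] + [(ids[b], ids[a]) for a, b in sorted(edges)],
        columns=["county_id", "neighbor_id"],
    ).sort_values(["county_id", "neighbor_id"], ignore_index=True)

    p_lo, p_hi = cfg.population_range
    population = np.exp(rng.uniform(np.log(p_lo), np.log(p_hi), size=n)).round().astype(int)
    pov_frac = rng.uniform(*cfg.poverty_fraction_range, size=n)
    counties = pd.DataFrame(
        {
            "county_id": ids,
            "n_monitors": n_monitors,
            "population": population,
            "poverty_population": np.round(population * pov_frac).astype(int),
        }
    )
    for ep in ENDPOINTS:
        a, b = cfg.annual_mortality_rate_range[ep]
        counties[f"rate_{ep}"] = rng.uniform(a, b, size=n)

    rows = []
    for cid, m in zip(ids, n_monitors):
        for k in range(int(m)):
            mtype = "nephelometer" if rng.random() < cfg.nephelometer_fraction else "frm"
            rows.append((f"{cid}-M{k + 1}", cid, mtype))
    monitors = pd.DataFrame(rows, columns=["monitor_id", "county_id", "monitor_type"])
    return counties, monitors, adjacency


def _truncated_positive_normal(rng, mean, sd, size):
    """Normal(mean, sd) truncated at 0 by redraw (no point mass at zero)."""
    out = rng.normal(mean, sd, size=size)
    while True:
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))


def generate_series(cfg: SyntheticConfig, counties, monitors):
    """Draw monitor-level daily PM2.5 readings for both study windows.

    Per county, each baseline day's true mean is a positive draw around
    ``baseline_mean``; each episode day adds a county-level smoke increase
    drawn once per county around ``episode_increase_mean`` with the
    cross-county SD (truncated at zero by redraw). Monitor readings scatter
    around the true county-day mean with the configured within-county RSD.

    When ``simulate_neph_bias`` is on (the default), nephelometer readings
    whose unbiased value exceeds ``neph_bias_above`` are inflated by
    ``1 + neph_bias_fraction`` — the smoke-season overestimation the
    exposure stage's instrument correction is built to undo, so the two are
    exact inverses on synthetic data.

    Returns
    -------
    readings : DataFrame
        county_id, monitor_id, monitor_type, date, period, pm25.
    truth : DataFrame
        Ground-truth sidecar: county_id, period, day_index, date, true_pm25.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = len(counties)
    days = cfg.episode_days
    windows = {
        "baseline": pd.date_range(cfg.baseline_start, periods=days, freq="D"),
        "episode": pd.date_range(cfg.episode_start, periods=days, freq="D"),
    }

    if cfg.episode_increase_mean == 0:
        increases = np.zeros(n)
    else:
        increases = _truncated_positive_normal(
            rng, cfg.episode_increase_mean, cfg.episode_increase_cross_county_sd, n
        )

    truth_rows = []
    true_means = {}
    for period, dates in windows.items():
        base = _truncated_positive_normal(rng, cfg.baseline_mean, cfg.baseline_sd, (n, days))
        means = base + increases[:, None] if period == "episode" else base
        true_means[period] = means
        for ci, cid in enumerate(counties["county_id"]):
            for di, date in enumerate(dates):
                truth_rows.append((cid, period, di + 1, date, means[ci, di]))
    truth = pd.DataFrame(
        truth_rows, columns=["county_id", "period", "day_index", "date", "true_pm25"]
    )

    mon_by_county = {
        cid: grp[["monitor_id", "monitor_type"]].to_numpy()
        for cid, grp in monitors.groupby("county_id")
    }
    rows = []
    for period, dates in windows.items():
        means = true_means[period]
        for ci, cid in enumerate(counties["county_id"]):
            mons = mon_by_county.get(cid)
            if mons is None:
                continue
            for di, date in enumerate(dates):
                vals = draw_lognormal(
                    rng,
                    np.full(len(mons), means[ci, di]),
                    cfg.within_county_rsd,
                )
                for (mid, mtype), v in zip(mons, vals):
                    if (
                        cfg.simulate_neph_bias
                        and mtype == "nephelometer"
                        and v > cfg.neph_bias_above
                    ):
                        v = v * (1.0 + cfg.neph_bias_fraction)
                    rows.append((cid, mid, mtype, date, period, float(v)))
    readings = pd.DataFrame(
        rows, columns=["county_id", "monitor_id", "monitor_type", "date", "period", "pm25"]
    )
    return readings, truth


def truth_deltas(truth: pd.DataFrame) -> pd.DataFrame:
    """Pair true episode and baseline means by day index into a delta table.

    Output matches the exposure module's delta schema (county_id, day_index,
    baseline_pm25, episode_pm25, delta_c, smoke_day with the 20.4 ug/m3 rule)
    but is computed directly from the sidecar, independent of the monitor
    readings.
    """
    wide = truth.pivot_table(
        index=["county_id", "day_index"], columns="period", values="true_pm25"
    ).reset_index()
    out = pd.DataFrame(
        {
            "county_id": wide["county_id"],
            "day_index": wide["day_index"],
            "baseline_pm25": wide["baseline"],
            "episode_pm25": wide["episode"],
        }
    )
    out["delta_c"] = out["episode_pm25"] - out["baseline_pm25"]
    out["smoke_day"] = out["episode_pm25"] > 20.4
    return out


def analytic_acute_burden(
    truth: pd.DataFrame,
    demographics: pd.DataFrame,
    percent_per_10: float | None = None,
    odds_ratio: float | None = None,
    endpoint: str = "all_cause",
) -> float:
    """Closed-form statewide acute burden implied by the true county-day means.

    One vectorized expression, independent of the attribution module, for use
    as an exact-recovery oracle. Exactly one of ``percent_per_10`` (CRF
    convention, AF = 1 - exp(-ln(1+p/100)/10 * max(delta, 0))) or
    ``odds_ratio`` (smoke-day convention, AF = (OR-1)/OR on days where the
    true episode mean exceeds 20.4 ug/m3) must be given.
    """
    if (percent_per_10 is None) == (odds_ratio is None):
        raise ValueError("give exactly one of percent_per_10 or odds_ratio")
    d = truth_deltas(truth).merge(
        demographics[["county_id", "population", f"rate_{endpoint}"]], on="county_id"
    )
    daily_rate = d[f"rate_{endpoint}"].to_numpy() / 365.0
    pop = d["population"].to_numpy()
    if percent_per_10 is not None:
        beta = np.log1p(percent_per_10 / 100.0) / 10.0
        af = -np.expm1(-beta * np.maximum(d["delta_c"].to_numpy(), 0.0))
    else:
        af = np.where(d["smoke_day"].to_numpy(), (odds_ratio - 1.0) / odds_ratio, 0.0)
    return float(np.sum(af * daily_rate * pop))


def write_synthetic_inputs(cfg: SyntheticConfig, outdir) -> dict:
    """Generate and write all pipeline input CSVs plus the ground-truth sidecar.

    Files: readings.csv, demographics.csv, adjacency.csv, monitors.csv,
    truth.csv. Returns the paths keyed by table name.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counties, monitors, adjacency = generate_counties(cfg)
    readings, truth = generate_series(cfg, counties, monitors)
    paths = {}
    for name, df in {
        "readings": readings,
        "demographics": counties,
        "adjacency": adjacency,
        "monitors": monitors,
        "truth": truth,
    }.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
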