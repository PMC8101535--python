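"""From monitor readings to county-day exposures and episode/baseline deltas.

Stages, in pipeline order:

1. ``correct_nephelometers`` — instrument-level recalibration of nephelometer
   readings, which overestimate PM2.5 during dense smoke; applied per reading,
   before any averaging.
2. ``aggregate_county_day`` — unweighted mean over a county's reporting
   monitors for each day; counties without monitors are emitted as empty rows
   awaiting imputation.
3. ``impute_unmonitored`` — unmonitored county-days borrow the unweighted
   mean of their adjacent monitored counties' same-day values.
4. ``compute_deltas`` — episode day k is paired with baseline day k (same
   calendar window one year apart); delta_c = episode - baseline, negative
   values retained (the attribution stage floors them).
5. ``classify_smoke_day`` — strict threshold rule, daily PM2.5 > 20.4 ug/m3.
6. ``summarize_exposure`` — distributional summary over county-level period
   means (one value per county per period).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ImputationError

#: Primary smoke-day rule: daily county PM2.5 strictly above this (ug/m3).
SMOKE_DAY_THRESHOLD = 20.4


@dataclass(frozen=True)
class NephCalibration:
    """Smoke-season recalibration of nephelometer monitors.

    Relative to their routine FRM calibration, nephelometers overestimate
    PM2.5 by ``overestimation_fraction`` during dense smoke; the correction
    divides affected readings by (1 + overestimation_fraction) and applies
    only above ``apply_above`` ug/m3, the range the recalibration covers.
    """

    overestimation_fraction: float = 0.207
    apply_above: float = 20.0

    def __post_init__(self):
        if self.overestimation_fraction <= -1:
            raise ValueError("overestimation_fraction must be > -1")
        if self.apply_above < 0:
            raise ValueError("apply_above must be >= 0")


def correct_nephelometers(
    readings: pd.DataFrame, calib: NephCalibration | None = None
) -> pd.DataFrame:
    """Divide nephelometer readings above the calibration threshold by (1+bias).

    FRM(-like) monitors and readings at or below ``calib.apply_above`` are
    returned unchanged. Operates per reading, so it must run before county
    averaging (averaging first would mix corrected and uncorrected mass).
    """
    calib = calib or NephCalibration()
    out = readings.copy()
    mask = (out["monitor_type"] == "nephelometer") & (out["pm25"] > calib.apply_above)
    out.loc[mask, "pm25"] = out.loc[mask, "pm25"] / (1.0 + calib.overestimation_fraction)
    return out


def classify_smoke_day(pm25, threshold: float = SMOKE_DAY_THRESHOLD):
    """True iff daily PM2.5 strictly exceeds the smoke-day threshold.

    Vectorized; 20.4 itself is not a smoke day.
    """
    return np.asarray(pm25, dtype=float) > threshold


def aggregate_county_day(
    readings: pd.DataFrame, all_county_ids=None
) -> pd.DataFrame:
    """Average each county's reporting monitors per day.

    Parameters
    ----------
    readings : DataFrame
        Monitor-level table (county_id, monitor_id, date, pm25, optionally
        period).
    all_county_ids : iterable, optional
        Full study-region county list. Counties present here but absent from
        ``readings`` are emitted for every observed date with pm25 = NaN,
        n_monitors = 0 and provenance ``pending`` so the imputation stage can
        fill them.

    Returns
    -------
    DataFrame with county_id, date, (period,) pm25, n_monitors, provenance.
    """
    if readings.empty:
        return pd.DataFrame(
            columns=["county_id", "date", "pm25", "n_monitors", "provenance"]
        )
    keys = ["county_id", "date"]
    has_period = "period" in readings.columns
    grouped = readings.groupby(keys, as_index=False).agg(
        pm25=("pm25", "mean"), n_monitors=("pm25", "size")
    )
    if has_period:
        period_map = readings.groupby(keys, as_index=False)["period"].first()
        grouped = grouped.merge(period_map, on=keys)
    grouped["provenance"] = "monitored"

    if all_county_ids is not None:
        missing = sorted(set(all_county_ids) - set(grouped["county_id"]))
        if missing:
            if has_period:
                dates = readings[["date", "period"]].drop_duplicates()
                filler = dates.merge(pd.DataFrame({"county_id": missing}), how="cross")
            else:
                filler = pd.DataFrame(
                    [(c, d) for c in missing for d in sorted(readings["date"].unique())],
                    columns=["county_id", "date"],
                )
            filler["pm25"] = np.nan
            filler["n_monitors"] = 0
            filler["provenance"] = "pending"
            grouped = pd.concat([grouped, filler], ignore_index=True)
    cols = ["county_id", "date"] + (["period"] if has_period else []) + [
        "pm25", "n_monitors", "provenance"
    ]
    return grouped[cols].sort_values(["county_id", "date"], ignore_index=True)


def impute_unmonitored(
    county_days: pd.DataFrame, adjacency: pd.DataFrame
) -> pd.DataFrame:
    """Fill unmonitored county-days with the mean of monitored neighbors.

    Only rows whose pm25 is missing are touched, so the operation is
    idempotent. Donors are same-day values from adjacent counties with at
    least one monitor; imputed values never cascade into later imputations.

    Raises
    ------
    ImputationError
        If an unmonitored county-day has no monitored neighbor reporting.
    """
    out = county_days.copy()
    need = out["pm25"].isna()
    if not need.any():
        return out
    neighbors = adjacency.groupby("county_id")["neighbor_id"].agg(list).to_dict()
    donors = out[out["n_monitors"] > 0].set_index(["county_id", "date"])["pm25"]
    for idx in out.index[need]:
        cid = out.at[idx, "county_id"]
        date = out.at[idx, "date"]
        vals = [
            donors[(nb, date)]
            for nb in neighbors.get(cid, [])
            if (nb, date) in donors.index
        ]
        if not vals:
            raise ImputationError(cid, date)
        out.at[idx, "pm25"] = float(np.mean(vals))
        out.at[idx, "provenance"] = "neighbor-imputed"
    return out


def compute_deltas(
    episode: pd.DataFrame,
    baseline: pd.DataFrame,
    threshold: float = SMOKE_DAY_THRESHOLD,
) -> pd.DataFrame:
    """Pair episode and baseline county-days by day index within each window.

    Both tables must cover the same counties with equally long windows; day k
    of the episode is matched with day k of the baseline (identical calendar
    dates one year apart in the standard configuration, so no weekday
    alignment is attempted). ``delta_c`` keeps its sign; flooring is an
    attribution-stage policy. ``smoke_day`` is classified on the episode
    concentration.
    """

    def _indexed(df, prefix):
        d = df.sort_values(["county_id", "date"]).copy()
        d["day_index"] = d.groupby("county_id").cumcount() + 1
        return d[["county_id", "day_index", "pm25"]].rename(columns={"pm25": prefix})

    e = _indexed(episode, "episode_pm25")
    b = _indexed(baseline, "baseline_pm25")
    e_len = e.groupby("county_id").size()
    b_len = b.groupby("county_id").size()
    mismatched = e_len.index.symmetric_difference(b_len.index)
    if len(mismatched):
        raise ValueError(f"county sets differ between periods: {list(mismatched)}")
    unequal = e_len[e_len != b_len]
    if len(unequal):
        raise ValueError(
            f"episode/baseline length mismatch for counties: {list(unequal.index)}"
        )
    out = e.merge(b, on=["county_id", "day_index"])
    out["delta_c"] = out["episode_pm25"] - out["baseline_pm25"]
    out["smoke_day"] = classify_smoke_day(out["episode_pm25"], threshold)
    return out[
        ["county_id", "day_index", "baseline_pm25", "episode_pm25", "delta_c", "smoke_day"]
    ]


def summarize_exposure(deltas: pd.DataFrame) -> pd.DataFrame:
    """Distribution of county-level period means: baseline, episode, increases.

    Each county contributes one value per row (its mean over the window), so
    the SD is the cross-county spread of county means. ``range`` is max-min.
    """
    if deltas.empty:
        raise ValueError("summarize_exposure requires a non-empty delta table")
    per_county = deltas.groupby("county_id").agg(
        baseline=("baseline_pm25", "mean"),
        episode=("episode_pm25", "mean"),
        increases=("delta_c", "mean"),
    )

    def _row(s: pd.Series) -> dict:
        sd = s.std(ddof=1) if len(s) > 1 else 0.0
        return {
            "mean": s.mean(),
            "sd": sd,
            "median": s.median(),
            "range": s.max() - s.min(),
            "min": s.min(),
            "max": s.max(),
        }

    rows = {name: _row(per_county[name]) for name in ("baseline", "episode", "increases")}
    out = pd.DataFrame(rows).T
    out.index.name = "period"
    return out
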