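import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smokehia import exposure
from smokehia.errors import ImputationError
from smokehia.exposure import (
    NephCalibration,
    aggregate_county_day,
    classify_smoke_day,
    compute_deltas,
    correct_nephelometers,
    impute_unmonitored,
    summarize_exposure,
)


def _readings(rows):
    return pd.DataFrame(
        rows, columns=["county_id", "monitor_id", "monitor_type", "date", "pm25"]
    )


class TestNephelometerCorrection:
    @pytest.mark.parametrize(
        "mtype,raw,expected",
        [
            ("nephelometer", 120.7, 100.0),  # divides by 1.207
            ("nephelometer", 15.0, 15.0),  # at/below threshold untouched
            ("nephelometer", 20.0, 20.0),  # boundary is strict
            ("frm", 120.7, 120.7),  # FRM never corrected
        ],
    )
    def test_correction_rule(self, mtype, raw, expected):
        r = _readings([("A", "A-M1", mtype, "2020-09-07", raw)])
        out = correct_nephelometers(r, NephCalibration())
        assert out["pm25"].iloc[0] == pytest.approx(expected)

    def test_correction_applied_per_reading_before_averaging(self):
        """The pipeline corrects instruments first, then averages counties."""
        from smokehia.pipeline import RunConfig, build_exposure

        rows = []
        for period, date in (("baseline", "2019-09-07"), ("episode", "2020-09-07")):
            rows.append(("A", "A-M1", "frm", pd.Timestamp(date), period, 100.0))
            rows.append(("A", "A-M2", "nephelometer", pd.Timestamp(date), period, 120.7))
        readings = pd.DataFrame(
            rows,
            columns=["county_id", "monitor_id", "monitor_type", "date", "period", "pm25"],
        )
        demo = pd.DataFrame({"county_id": ["A"], "population": [1000],
                             "poverty_population": [100], "rate_all_cause": [0.01],
                             "rate_respiratory": [0.001], "rate_cardiorespiratory": [0.003]})
        adjacency = pd.DataFrame(columns=["county_id", "neighbor_id"])
        cfg = RunConfig(episode_days=1)
        _, county_days, deltas, _ = build_exposure(cfg, readings, demo, adjacency)
        # mean of corrected readings (100, 100), not corrected mean of raw (110.35 -> 91.4)
        assert county_days["episode"]["pm25"].iloc[0] == pytest.approx(100.0)


class TestAggregation:
    def test_county_day_mean_and_monitor_count(self):
        r = _readings(
            [
                ("A", "A-M1", "frm", "2020-09-07", 90.0),
                ("A", "A-M2", "frm", "2020-09-07", 110.0),
                ("B", "B-M1", "frm", "2020-09-07", 42.0),
            ]
        )
        out = aggregate_county_day(r)
        a = out[out["county_id"] == "A"].iloc[0]
        assert a["pm25"] == pytest.approx(100.0) and a["n_monitors"] == 2
        b = out[out["county_id"] == "B"].iloc[0]
        assert b["pm25"] == pytest.approx(42.0) and b["n_monitors"] == 1
        assert (out["provenance"] == "monitored").all()

    def test_unmonitored_county_emitted_for_imputation(self):
        r = _readings([("A", "A-M1", "frm", "2020-09-07", 10.0)])
        out = aggregate_county_day(r, all_county_ids=["A", "Z"])
        z = out[out["county_id"] == "Z"].iloc[0]
        assert np.isnan(z["pm25"]) and z["n_monitors"] == 0 and z["provenance"] == "pending"

    def test_empty_input_gives_empty_output(self):
        out = aggregate_county_day(_readings([]))
        assert out.empty

    @settings(max_examples=60, derandomize=True)
    @given(
        values=st.lists(st.floats(0.0, 500.0), min_size=1, max_size=6),
        bump=st.floats(0.1, 100.0),
        idx=st.integers(0, 5),
    )
    def test_raising_one_monitor_never_lowers_the_county_mean(self, values, bump, idx):
        idx = idx % len(values)
        r = _readings(
            [("A", f"A-M{i}", "frm", "2020-09-07", v) for i, v in enumerate(values)]
        )
        base = aggregate_county_day(r)["pm25"].iloc[0]
        values2 = list(values)
        values2[idx] += bump
        r2 = _readings(
            [("A", f"A-M{i}", "frm", "2020-09-07", v) for i, v in enumerate(values2)]
        )
        assert aggregate_county_day(r2)["pm25"].iloc[0] >= base


class TestImputation:
    def _county_days(self):
        return pd.DataFrame(
            {
                "county_id": ["A", "B", "U"],
                "date": [pd.Timestamp("2020-09-07")] * 3,
                "pm25": [80.0, 120.0, np.nan],
                "n_monitors": [1, 2, 0],
                "provenance": ["monitored", "monitored", "pending"],
            }
        )

    def _adj(self, pairs):
        return pd.DataFrame(pairs, columns=["county_id", "neighbor_id"])

    def test_mean_of_monitored_neighbors(self):
        adj = self._adj([("U", "A"), ("A", "U"), ("U", "B"), ("B", "U")])
        out = impute_unmonitored(self._county_days(), adj)
        u = out[out["county_id"] == "U"].iloc[0]
        assert u["pm25"] == pytest.approx(100.0)
        assert u["provenance"] == "neighbor-imputed"

    def test_single_neighbor_identity(self):
        adj = self._adj([("U", "A"), ("A", "U")])
        out = impute_unmonitored(self._county_days(), adj)
        assert out[out["county_id"] == "U"]["pm25"].iloc[0] == pytest.approx(80.0)

    def test_isolated_unmonitored_county_errors_with_name_and_date(self):
        adj = self._adj([("A", "B"), ("B", "A")])
        with pytest.raises(ImputationError) as exc:
            impute_unmonitored(self._county_days(), adj)
        assert "U" in str(exc.value) and "2020-09-07" in str(exc.value)

    def test_imputation_is_idempotent(self):
        adj = self._adj([("U", "A"), ("A", "U"), ("U", "B"), ("B", "U")])
        once = impute_unmonitored(self._county_days(), adj)
        twice = impute_unmonitored(once, adj)
        pd.testing.assert_frame_equal(once, twice)


class TestDeltasAndSmokeDays:
    def _period(self, cid, dates, values):
        return pd.DataFrame(
            {
                "county_id": cid,
                "date": pd.to_datetime(dates),
                "pm25": values,
                "n_monitors": 1,
                "provenance": "monitored",
            }
        )

    def test_delta_pairs_by_day_index(self):
        episode = self._period("A", ["2020-09-07", "2020-09-08"], [100.1, 2.0])
        baseline = self._period("A", ["2019-09-07", "2019-09-08"], [3.1, 5.0])
        out = compute_deltas(episode, baseline)
        assert out["delta_c"].tolist() == pytest.approx([97.0, -3.0])
        assert out["smoke_day"].tolist() == [True, False]

    def test_identical_periods_give_zero_delta(self):
        episode = self._period("A", ["2020-09-07"], [5.0])
        baseline = self._period("A", ["2019-09-07"], [5.0])
        assert compute_deltas(episode, baseline)["delta_c"].iloc[0] == 0.0

    def test_length_mismatch_is_an_error(self):
        episode = self._period("A", ["2020-09-07", "2020-09-08"], [10.0, 12.0])
        baseline = self._period("A", ["2019-09-07"], [3.0])
        with pytest.raises(ValueError):
            compute_deltas(episode, baseline)

    @pytest.mark.parametrize(
        "pm25,expected", [(215.5, True), (20.4, False), (20.41, True), (0.0, False)]
    )
    def test_smoke_day_rule_is_strict(self, pm25, expected):
        assert bool(classify_smoke_day(pm25)) is expected


class TestSummary:
    def test_single_county_constant_series(self):
        deltas = pd.DataFrame(
            {
                "county_id": "A",
                "day_index": [1, 2, 3],
                "baseline_pm25": 3.0,
                "episode_pm25": 100.0,
                "delta_c": 97.0,
                "smoke_day": True,
            }
        )
        s = summarize_exposure(deltas)
        ep = s.loc["episode"]
        assert ep["mean"] == ep["median"] == 100.0
        assert ep["sd"] == 0.0 and ep["range"] == 0.0
        assert ep["min"] == ep["max"] == 100.0

    def test_increase_row_is_episode_minus_baseline(self, default_exposure):
        s = default_exposure["summary"]
        assert s.loc["increases", "mean"] == pytest.approx(
            s.loc["episode", "mean"] - s.loc["baseline", "mean"]
        )

    def test_default_synthetic_episode_mean_close_to_configured(
        self, default_exposure, default_cfg
    ):
        """Episode county-mean distribution centers near baseline + increase."""
        s = default_exposure["summary"]
        expected = default_cfg.baseline_mean + default_cfg.episode_increase_mean
        se = default_cfg.episode_increase_cross_county_sd / np.sqrt(default_cfg.n_counties)
        assert abs(s.loc["episode", "mean"] - expected) < 3 * se

    def test_empty_deltas_rejected(self):
        with pytest.raises(ValueError):
            summarize_exposure(pd.DataFrame(columns=["county_id"]))


def test_full_exposure_pipeline_covers_all_counties(default_exposure, default_region):
    """Aggregation + imputation yields one exposure per county-day, all filled."""
    for period, cd in default_exposure["county_days"].items():
        assert cd["pm25"].notna().all()
        assert set(cd["county_id"]) == set(default_region["counties"]["county_id"])
        imputed = cd[cd["provenance"] == "neighbor-imputed"]
        unmonitored = set(
            default_region["counties"].query("n_monitors == 0")["county_id"]
        )
        assert set(imputed["county_id"]) == unmonitored
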