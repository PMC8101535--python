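import pandas as pd
import pytest

from smokehia import exposure, pipeline, sensitivity
from smokehia.synthetic_data import SyntheticConfig, generate_counties, generate_series


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def default_region(default_cfg):
    """Full-size synthetic study region (39 counties) with ground truth."""
    counties, monitors, adjacency = generate_counties(default_cfg)
    readings, truth = generate_series(default_cfg, counties, monitors)
    return {
        "cfg": default_cfg,
        "counties": counties,
        "monitors": monitors,
        "adjacency": adjacency,
        "readings": readings,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(n_counties=10, monitors_per_county_range=(0, 4), seed=7)


@pytest.fixture(scope="session")
def small_region(small_cfg):
    counties, monitors, adjacency = generate_counties(small_cfg)
    readings, truth = generate_series(small_cfg, counties, monitors)
    return {
        "cfg": small_cfg,
        "counties": counties,
        "monitors": monitors,
        "adjacency": adjacency,
        "readings": readings,
        "truth": truth,
    }


def _exposure_tables(region, cfg):
    run_cfg = pipeline.RunConfig(
        synthetic=cfg, mc=sensitivity.MonteCarloSpec(n_draws=200)
    )
    corrected, county_days, deltas, summary = pipeline.build_exposure(
        run_cfg, region["readings"], region["counties"], region["adjacency"]
    )
    return {
        "corrected": corrected,
        "county_days": county_days,
        "deltas": deltas,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def default_exposure(default_region, default_cfg):
    """Exposure pipeline outputs (correction, aggregation, imputation, deltas)."""
    return _exposure_tables(default_region, default_cfg)


@pytest.fixture(scope="session")
def small_exposure(small_region, small_cfg):
    return _exposure_tables(small_region, small_cfg)


@pytest.fixture()
def toy_deltas():
    """Hand-built three-county delta table with known smoke-day structure."""
    rows = []
    for cid, episode in (("A", 100.0), ("B", 50.0), ("C", 10.0)):
        for k in range(1, 4):
            rows.append(
                {
                    "county_id": cid,
                    "day_index": k,
                    "baseline_pm25": 5.0,
                    "episode_pm25": episode,
                    "delta_c": episode - 5.0,
                    "smoke_day": episode > exposure.SMOKE_DAY_THRESHOLD,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_demo():
    return pd.DataFrame(
        {
            "county_id": ["A", "B", "C"],
            "population": [100_000, 50_000, 20_000],
            "poverty_population": [15_000, 5_000, 4_000],
            "rate_all_cause": [0.009, 0.008, 0.010],
            "rate_respiratory": [0.0009, 0.0008, 0.0010],
            "rate_cardiorespiratory": [0.003, 0.0028, 0.0035],
        }
    )
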