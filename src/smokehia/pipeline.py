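"""End-to-end orchestration: declarative config, run_all, table writers.

A run is fully described by a :class:`RunConfig` (loadable from YAML): where
the inputs come from (CSV paths or the synthetic generator), the study
windows, the response-function set, the scenario grid, the Monte Carlo spec
and the output directory. ``run_all`` executes the stages in order —
nephelometer correction, county aggregation, neighbor imputation, deltas,
acute and chronic attribution, intervention scenarios, Monte Carlo
sensitivity — and writes one CSV per output table plus a machine-readable
provenance record (config hash, seeds, library versions) sufficient to
reproduce every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import attribution, exposure, scenarios, sensitivity, synthetic_data
from .errors import ConfigurationError

log = logging.getLogger("smokehia")

ACUTE_RFS = {
    ("crf", "all_cause"): attribution.CRF_ACUTE_ALL_CAUSE,
    ("or", "all_cause"): attribution.OR_SMOKE_DAY_ALL_CAUSE,
    ("or", "respiratory"): attribution.OR_SMOKE_DAY_RESPIRATORY,
}
ANNUAL_RFS = {
    "all_cause": attribution.CRF_ANNUAL_ALL_CAUSE,
    "cardiorespiratory": attribution.CRF_ANNUAL_CARDIORESPIRATORY,
}


@dataclass
class RunConfig:
    """Declarative description of a full analysis run.

    ``inputs`` maps table names (readings, demographics, adjacency) to CSV
    paths; when omitted, the synthetic generator supplies the study region
    using ``synthetic`` parameters.
    """

    inputs: dict | None = None
    synthetic: synthetic_data.SyntheticConfig = field(
        default_factory=synthetic_data.SyntheticConfig
    )
    episode_start: str = "2020-09-07"
    baseline_start: str = "2019-09-07"
    episode_days: int = 13
    smoke_day_threshold: float = exposure.SMOKE_DAY_THRESHOLD
    apply_neph_correction: bool = True
    neph_overestimation_fraction: float = 0.207
    neph_apply_above: float = 20.0
    approaches: tuple = ("crf", "or")
    horizons: tuple = ("acute", "chronic")
    endpoints: tuple = ("all_cause", "respiratory", "cardiorespiratory")
    reductions: tuple = scenarios.STANDARD_REDUCTIONS + (1.0,)
    scenario_targets: tuple = ("total_population", "poverty_population")
    mc: sensitivity.MonteCarloSpec = field(default_factory=sensitivity.MonteCarloSpec)
    outdir: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            for key in (
                "monitors_per_county_range",
                "population_range",
                "poverty_fraction_range",
            ):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "annual_mortality_rate_range" in syn:
                syn["annual_mortality_rate_range"] = {
                    k: tuple(v) for k, v in syn["annual_mortality_rate_range"].items()
                }
            raw["synthetic"] = synthetic_data.SyntheticConfig(**syn)
        if "mc" in raw and raw["mc"] is not None:
            raw["mc"] = sensitivity.MonteCarloSpec(**dict(raw["mc"]))
        for key in ("approaches", "horizons", "endpoints", "reductions", "scenario_targets"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> dict:
        d = dataclasses.asdict(self)
        d["package_version"] = __version__
        return json.loads(json.dumps(d, sort_keys=True, default=str))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.canonical(), sort_keys=True).encode()
        ).hexdigest()


def _load_inputs(cfg: RunConfig):
    if cfg.inputs:
        readings = pd.read_csv(cfg.inputs["readings"], parse_dates=["date"])
        demo = pd.read_csv(cfg.inputs["demographics"])
        adjacency = pd.read_csv(cfg.inputs["adjacency"])
        return readings, demo, adjacency
    counties, monitors, adjacency = synthetic_data.generate_counties(cfg.synthetic)
    readings, _ = synthetic_data.generate_series(cfg.synthetic, counties, monitors)
    return readings, counties, adjacency


def _split_periods(readings: pd.DataFrame, cfg: RunConfig):
    dates = pd.to_datetime(readings["date"])
    windows = {
        "baseline": pd.date_range(cfg.baseline_start, periods=cfg.episode_days),
        "episode": pd.date_range(cfg.episode_start, periods=cfg.episode_days),
    }
    out = {}
    for period, window in windows.items():
        sel = readings[dates.isin(window)].copy()
        if sel.empty:
            raise ConfigurationError(f"no readings fall inside the {period} window")
        out[period] = sel
    return out


def build_exposure(cfg: RunConfig, readings, demo, adjacency):
    """Stages 1-5: correction, aggregation, imputation, deltas, summary."""
    if cfg.apply_neph_correction:
        calib = exposure.NephCalibration(
            cfg.neph_overestimation_fraction, cfg.neph_apply_above
        )
        readings = exposure.correct_nephelometers(readings, calib)
    periods = _split_periods(readings, cfg)
    county_ids = demo["county_id"].tolist()
    county_days = {}
    for period, rd in periods.items():
        agg = exposure.aggregate_county_day(rd, all_county_ids=county_ids)
        county_days[period] = exposure.impute_unmonitored(agg, adjacency)
    deltas = exposure.compute_deltas(
        county_days["episode"], county_days["baseline"], cfg.smoke_day_threshold
    )
    summary = exposure.summarize_exposure(deltas)
    return readings, county_days, deltas, summary


def rank_per_capita(burdens: pd.DataFrame) -> pd.DataFrame:
    """County burden rows ordered by per-100k burden, highest first.

    Ties break by county id (ascending); the sort is stable.
    """
    county = burdens[burdens["scope"] == "county"].copy()
    if county.empty:
        return county
    county = county.sort_values(
        ["per_100k", "county_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    county.insert(0, "rank", range(1, len(county) + 1))
    return county


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return (and optionally write) all outputs.

    Deterministic given the config (all randomness flows from the seeds it
    carries). Any stage failure is re-raised annotated with the stage name.
    """
    logging.basicConfig(level=cfg.log_level)
    outputs: dict = {}
    stage = "load-inputs"
    try:
        readings, demo, adjacency = _load_inputs(cfg)
        stage = "exposure"
        corrected, county_days, deltas, summary = build_exposure(
            cfg, readings, demo, adjacency
        )
        outputs["exposure_summary"] = summary.reset_index()
        outputs["county_day_episode"] = county_days["episode"]
        outputs["county_day_baseline"] = county_days["baseline"]
        outputs["deltas"] = deltas

        stage = "acute-attribution"
        acute = []
        for (approach, endpoint), rf in ACUTE_RFS.items():
            if approach in cfg.approaches and endpoint in cfg.endpoints:
                acute.append(attribution.run_acute(deltas, demo, rf))
        if acute and "acute" in cfg.horizons:
            outputs["burden_acute"] = pd.concat(acute, ignore_index=True)
            outputs["per_capita_ranking"] = rank_per_capita(acute[0])

        stage = "chronic-attribution"
        if "chronic" in cfg.horizons and "crf" in cfg.approaches:
            chronic = [
                attribution.run_chronic(deltas, demo, rf)
                for ep, rf in ANNUAL_RFS.items()
                if ep in cfg.endpoints
            ]
            if chronic:
                outputs["burden_chronic"] = pd.concat(chronic, ignore_index=True)

        stage = "scenarios"
        rfs = [
            rf
            for (approach, endpoint), rf in ACUTE_RFS.items()
            if approach in cfg.approaches and endpoint in cfg.endpoints
        ]
        tables = []
        for target in cfg.scenario_targets:
            t = scenarios.scenario_table(
                deltas, demo, rfs, reductions=cfg.reductions, target=target
            )
            t.insert(1, "target", target)
            tables.append(t)
        if tables:
            outputs["scenario_table"] = pd.concat(tables, ignore_index=True)

        stage = "monte-carlo"
        if cfg.mc.rsd_source == "fixed":
            mc_deltas = sensitivity.attach_rsd(deltas, fixed=cfg.mc.fixed_rsd)
        else:
            episode_readings = corrected[
                pd.to_datetime(corrected["date"]).isin(
                    pd.date_range(cfg.episode_start, periods=cfg.episode_days)
                )
            ]
            rsd_table, pooled = sensitivity.estimate_rsd(episode_readings)
            mc_deltas = sensitivity.attach_rsd(
                deltas,
                episode_days=county_days["episode"],
                rsd_table=rsd_table,
                pooled=pooled,
            )
        mc = sensitivity.mc_hia(
            mc_deltas,
            demo,
            ACUTE_RFS[("crf", "all_cause")],
            cfg.mc,
            threshold=cfg.smoke_day_threshold,
        )
        outputs["mc_interval"] = pd.DataFrame([mc])

        stage = "provenance"
        outputs["provenance"] = {
            "config": cfg.canonical(),
            "config_hash": cfg.config_hash(),
            "versions": {
                "smokehia": __version__,
                "numpy": __import__("numpy").__version__,
                "pandas": pd.__version__,
            },
        }
    except Exception as exc:
        exc.args = (f"[stage: {stage}] {exc}",)
        raise

    if cfg.outdir:
        write_outputs(outputs, cfg.outdir)
    return outputs


def write_outputs(outputs: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, obj in outputs.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.csv", index=False)
        else:
            (outdir / f"{name}.json").write_text(json.dumps(obj, indent=2, sort_keys=True))
    log.info("wrote %d output files to %s", len(outputs), outdir)
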