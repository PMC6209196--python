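"""End-to-end orchestration: simulate/read -> segment -> snow -> windows -> fit.

One :class:`RunConfig` drives the whole chain under a single seed; every
random stage (simulation, control sampling, bootstrap) derives its own seed
from it, so a rerun with the same config reproduces every output byte for
byte. Outputs: the two 10-row selection tables, coefficient tables with
bootstrap CIs for the selected models, per-category descriptive summaries
(raw means, the same arithmetic the original study reports), a log10-speed
histogram with the fitted mixture, and a manifest with a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, inference, snow, synthetic, telemetry, windows

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_all"]


@dataclass
class RunConfig:
    """Everything a full run needs; defaults reproduce the study conditions."""

    # inputs: either paths to CSVs, or simulate=True
    simulate: bool = True
    telemetry_path: str | None = None
    cameras_path: str | None = None
    snow_readings_path: str | None = None
    sim: synthetic.SimConfig | None = None

    out_dir: str = "wolfsnow_out"
    run_id: str = "run"
    seed: int = 0

    tz_offset_hours: float = telemetry.DEFAULT_TZ_OFFSET_HOURS
    target_interval_min: int = 30
    interval_band_min: tuple = telemetry.DEFAULT_INTERVAL_BAND_MIN
    event_threshold_cm: float = snow.DEFAULT_EVENT_THRESHOLD_CM
    n_controls: int = 3
    cutoff: str | float = "auto"     # 'auto' (fit + intersect) or a fixed m/min value
    n_boot: int = 5000
    boot_level: float = 0.95
    parsimony_window: float = 4.0
    make_plots: bool = True

    def resolved_sim(self) -> synthetic.SimConfig:
        if self.sim is not None:
            return self.sim
        return synthetic.SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a flat YAML file.

        Top-level keys map to :class:`RunConfig` fields; an optional ``sim``
        mapping holds :class:`~wolfsnow.synthetic.SimConfig` fields.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        sim_raw = raw.pop("sim", None)
        if sim_raw is not None:
            if "accumulation_range_cm" in sim_raw:
                sim_raw["accumulation_range_cm"] = tuple(sim_raw["accumulation_range_cm"])
            raw["sim"] = synthetic.SimConfig(**sim_raw)
        if "interval_band_min" in raw:
            raw["interval_band_min"] = tuple(raw["interval_band_min"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    return obj


@dataclass
class RunResult:
    """In-memory bundle of everything a run produced."""

    config: RunConfig
    mixture: behavior.SpeedMixture | None
    cutoff_m_per_min: float
    analysis: pd.DataFrame
    speed_selection: pd.DataFrame
    travel_selection: pd.DataFrame
    speed_best: pd.Series
    travel_best: pd.Series
    speed_coefficients: pd.DataFrame | None
    travel_coefficients: pd.DataFrame | None
    summaries: dict
    out_dir: Path


def _stage(name):
    logger.info("stage: %s", name)


def _load_inputs(config: RunConfig):
    if config.simulate:
        sim = config.resolved_sim()
        _stage("simulate")
        snow_sim = synthetic.simulate_snow_series(sim)
        tracks = synthetic.simulate_wolf_tracks(sim, snow_sim)
        return tracks.fixes, snow_sim.deployments, snow_sim.readings
    missing = [
        n for n, p in [
            ("telemetry", config.telemetry_path),
            ("cameras", config.cameras_path),
            ("snow_readings", config.snow_readings_path),
        ] if p is None
    ]
    if missing:
        raise ValueError(
            f"missing input path(s) {', '.join(missing)} and simulation not requested"
        )
    _stage("read inputs")
    fixes = telemetry.read_fixes(config.telemetry_path)
    deployments = snow.read_deployments(config.cameras_path)
    readings = snow.read_depth_readings(config.snow_readings_path)
    return fixes, deployments, readings


def category_summaries(analysis: pd.DataFrame) -> dict:
    """Raw descriptive statistics per snowfall category and time of day.

    Mean +/- sd of travel speed, travel proportions, and km/day (sum of step
    distances per wolf-day, averaged) — plain arithmetic on the analysis
    rows, independent of any model.
    """
    travel = analysis[analysis["behavior"] == "travel"]
    speed_by_tod = travel.groupby("time_of_day")["speed_m_min"].agg(["mean", "std", "size"])
    speed_table = (
        travel.groupby(["snowfall_category", "time_of_day"])["speed_m_min"]
        .agg(["mean", "std", "size"]).reset_index()
        .pivot(index="snowfall_category", columns="time_of_day")
    )
    travel_prop = (
        analysis.groupby(["snowfall_category", "time_of_day"])["travel"]
        .mean().unstack("time_of_day")
        .reindex(windows.CATEGORY_ORDER)
    )
    km_day = (
        analysis.assign(km=analysis["speed_m_min"] * 30.0 / 1000.0)
        .groupby(["wolf_id", "camera_day", "snowfall_category"])["km"].sum()
        .groupby("snowfall_category").agg(["mean", "std"])
    )
    return {
        "speed_by_time_of_day": speed_by_tod,
        "speed_by_category": speed_table,
        "travel_proportion": travel_prop,
        "km_per_day_by_category": km_day,
    }


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline; see the module docstring for the stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fixes, deployments, readings = _load_inputs(config)

    _stage("thin + steps")
    thinned = telemetry.thin_to_interval(fixes, config.target_interval_min)
    steps = telemetry.compute_steps(
        thinned, config.interval_band_min, config.tz_offset_hours
    )

    _stage("segment")
    log_speeds = np.log10(
        np.maximum(steps["speed_m_min"].to_numpy(dtype=float), behavior.DEFAULT_SPEED_FLOOR_M_PER_MIN)
    )
    mixture = None
    if config.cutoff == "auto":
        mixture = behavior.fit_mixture(log_speeds)
        cutoff = behavior.find_intersection(mixture).value_m_per_min
    else:
        cutoff = float(config.cutoff)
    labeled = behavior.classify_steps(steps, cutoff)

    _stage("snow")
    snow_daily = snow.build_snow_daily(deployments, readings, config.event_threshold_cm)
    cents = telemetry.daily_centroids(thinned, config.tz_offset_hours)
    wolf_day = snow.join_wolf_day(cents, snow_daily, deployments)

    _stage("windows")
    analysis = windows.build_analysis_dataset(
        labeled, wolf_day, n_controls=config.n_controls, seed=config.seed + 1,
    )
    # one common dataset for all candidate models: depth-complete cases
    n_all = len(analysis)
    analysis = analysis[analysis["depth_cm"].notna()].reset_index(drop=True)
    if len(analysis) < n_all:
        logger.info("dropped %d rows without snow depth for model comparability",
                    n_all - len(analysis))

    _stage("fit: travel speed (LMM)")
    speed_fits = [inference.fit_speed_model(analysis, s)
                  for s in inference.candidate_models("log10_speed")]
    speed_table = inference.selection_table(speed_fits)
    speed_best_row = inference.select_best(speed_table, config.parsimony_window)

    _stage("fit: time spent travelling (GLMM)")
    travel_fits = [inference.fit_travel_model(analysis, s)
                   for s in inference.candidate_models("behavior")]
    travel_table = inference.selection_table(travel_fits)
    travel_best_row = inference.select_best(travel_table, config.parsimony_window)

    speed_coefs = travel_coefs = None
    if config.n_boot > 0:
        _stage("bootstrap")
        speed_best_fit = next(f for f in speed_fits if f.spec.formula == speed_best_row["formula"])
        travel_best_fit = next(f for f in travel_fits if f.spec.formula == travel_best_row["formula"])
        speed_coefs = inference.parametric_bootstrap_ci(
            speed_best_fit, n_sim=config.n_boot, level=config.boot_level, seed=config.seed + 2,
        )
        travel_coefs = inference.parametric_bootstrap_ci(
            travel_best_fit, n_sim=config.n_boot, level=config.boot_level, seed=config.seed + 3,
        )

    _stage("report")
    summaries = category_summaries(analysis)
    speed_table.to_csv(out / f"{config.run_id}_speed_selection.csv", index=False)
    travel_table.to_csv(out / f"{config.run_id}_travel_selection.csv", index=False)
    if speed_coefs is not None:
        speed_coefs.to_csv(out / f"{config.run_id}_speed_coefficients.csv", index=False)
        travel_coefs.to_csv(out / f"{config.run_id}_travel_coefficients.csv", index=False)
    summaries["travel_proportion"].to_csv(out / f"{config.run_id}_travel_proportion.csv")
    analysis.to_csv(out / f"{config.run_id}_analysis_dataset.csv", index=False)

    if config.make_plots and mixture is not None:
        _plot_mixture(log_speeds, mixture, cutoff, out / f"{config.run_id}_speed_mixture.png")

    import statsmodels

    from . import __version__

    manifest = {
        "run_id": config.run_id,
        "config_hash": config.config_hash(),
        "versions": {
            "wolfsnow": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "seed": config.seed,
        "n_analysis_rows": int(len(analysis)),
        "cutoff_m_per_min": float(cutoff),
        "speed_best": str(speed_best_row["formula"]),
        "travel_best": str(travel_best_row["formula"]),
    }
    (out / f"{config.run_id}_manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunResult(
        config=config, mixture=mixture, cutoff_m_per_min=float(cutoff),
        analysis=analysis, speed_selection=speed_table, travel_selection=travel_table,
        speed_best=speed_best_row, travel_best=travel_best_row,
        speed_coefficients=speed_coefs, travel_coefficients=travel_coefs,
        summaries=summaries, out_dir=out,
    )


def _plot_mixture(log_speeds, mixture, cutoff_m_per_min, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.linspace(log_speeds.min(), log_speeds.max(), 400)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(log_speeds, bins=80, density=True, color="0.8", edgecolor="0.6")
    from scipy.stats import norm
    ax.plot(x, mixture.w1 * norm.pdf(x, mixture.mu1, mixture.sd1), label="rest component")
    ax.plot(x, mixture.w2 * norm.pdf(x, mixture.mu2, mixture.sd2), label="travel component")
    ax.axvline(np.log10(cutoff_m_per_min), color="k", ls="--",
               label=f"cutoff = {cutoff_m_per_min:.2f} m/min")
    ax.set_xlabel("log10 speed (m/min)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
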