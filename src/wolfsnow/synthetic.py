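"""Synthetic telemetry and snow-camera data with the structure the analysis assumes.

The generator emulates the study conditions: 17 wolves tracked at 10- or
30-minute fix rates over a ~60-day mid-winter window, and 13-14 remote
cameras whose daily noon depth readings contain localized snowfall events
(>= 5 cm / 24 h, the largest 16 cm). Movement is a two-state process: each
step is rest or travel with P(travel) from a logistic model in time of day
and snowfall category (with a by-wolf random intercept), travel speeds are
log10-normal around a linear model in the same covariates (by-wolf random
intercept and night slope), and rest speeds are log10-normal jitter. Pooled
log10 speeds are therefore a two-component normal mixture, which is exactly
what the segmentation stage assumes.

Ground truth (states, categories, random effects) is emitted alongside the
fix table so downstream stages can be tested for parameter recovery.

Coordinates use a local tangent-plane approximation at the study origin
(56.4 N, 111.1 W): adequate over the ~100 km study extent and trivially
invertible, so generated files round-trip through the readers exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar, telemetry, windows

__all__ = [
    "BehaviorModel",
    "SpeedModel",
    "SpeedMixtureParams",
    "SimConfig",
    "SnowSim",
    "TrackSim",
    "simulate_snow_series",
    "simulate_wolf_tracks",
    "simulate_speed_sample",
    "write_fixtures",
    "project",
    "unproject",
]

#: meters per degree latitude / per degree longitude at the study origin
_M_PER_DEG_LAT = 110_574.0
_M_PER_DEG_LON_FACTOR = 111_320.0

CATEGORY_OFFSET_KEYS = ["control", "two_before", "one_before", "one_after", "two_after", "three_after"]


@dataclass(frozen=True)
class BehaviorModel:
    """Logistic model for P(travel) per step, on the logit scale.

    Defaults follow the published travel-probability coefficients: wolves are
    a little *less* likely to travel at night on snowfall days, and the night
    deficit disappears (night-by-category interactions are positive) away
    from snowfall days. Reference levels: day, day_of_snowfall.
    """

    intercept: float = -0.467
    night: float = -0.542
    category: dict = field(default_factory=lambda: {
        "control": -0.243, "two_before": -0.201, "one_before": -0.026,
        "one_after": -0.025, "two_after": -0.169, "three_after": -0.095,
    })
    night_by_category: dict = field(default_factory=lambda: {
        "control": 0.563, "two_before": 0.456, "one_before": 0.365,
        "one_after": 0.268, "two_after": 0.621, "three_after": 0.546,
    })
    random_intercept_sd: float = 0.3

    def linear_predictor(self, night, category, b_wolf=0.0):
        lp = self.intercept + b_wolf + self.night * night
        lp += self.category.get(category, 0.0)
        lp += night * self.night_by_category.get(category, 0.0)
        return lp


@dataclass(frozen=True)
class SpeedModel:
    """Linear model for log10 travel speed (log10 m/min).

    The intercept is the day-time travel speed on a snowfall day; category
    offsets follow the published speed contrasts (slowest on the event day).
    The residual SD comes from the mixture's travel component.
    """

    intercept: float = 1.3
    night: float = 0.107
    category: dict = field(default_factory=lambda: {
        "control": 0.061, "two_before": 0.037, "one_before": 0.045,
        "one_after": 0.005, "two_after": 0.041, "three_after": -0.016,
    })
    random_intercept_sd: float = 0.10
    random_night_slope_sd: float = 0.05


@dataclass(frozen=True)
class SpeedMixtureParams:
    """Marginal two-component mixture of log10 speeds (rest slow, travel fast)."""

    w_rest: float = 0.67
    mu_rest_log10: float = -0.3
    sd_rest_log10: float = 0.45
    w_travel: float = 0.33
    mu_travel_log10: float = 1.3
    sd_travel_log10: float = 0.35


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with defaults set to the study conditions."""

    n_wolves: int = 17
    n_days: int = 60
    fix_interval_min: int = 30
    start_date: dt.date = dt.date(2014, 1, 5)
    origin_lat: float = 56.4
    origin_lon: float = -111.1
    origin_easting: float = 500_000.0
    origin_northing: float = 6_250_000.0
    tz_offset_hours: float = telemetry.DEFAULT_TZ_OFFSET_HOURS
    speed_mixture: SpeedMixtureParams = field(default_factory=SpeedMixtureParams)
    behavior_model: BehaviorModel = field(default_factory=BehaviorModel)
    speed_model: SpeedModel = field(default_factory=SpeedModel)
    n_cameras: int = 14
    event_rate: float = 4.0          # expected events per camera-winter
    shared_event_prob: float = 0.5   # fraction of events shared study-wide
    accumulation_range_cm: tuple = (5, 16)
    depth_noise_cm: float = 1.0      # depth resolution / settling noise scale
    initial_depth_mean_cm: float = 50.0
    initial_depth_sd_cm: float = 12.0
    study_extent_km: float = 80.0    # side of the square holding cameras and wolves
    home_radius_km: float = 6.0      # homing kicks in beyond this distance
    seed: int = 0

    def __post_init__(self):
        mix = self.speed_mixture
        if self.n_wolves < 1:
            raise ValueError(f"n_wolves must be >= 1, got {self.n_wolves}")
        if self.n_days < 7:
            raise ValueError(f"n_days must be >= 7, got {self.n_days}")
        if self.fix_interval_min not in (10, 30):
            raise ValueError(f"fix_interval_min must be 10 or 30, got {self.fix_interval_min}")
        if self.n_cameras < 1:
            raise ValueError(f"n_cameras must be >= 1, got {self.n_cameras}")
        if self.event_rate < 0:
            raise ValueError(f"event_rate must be >= 0, got {self.event_rate}")
        lo, hi = self.accumulation_range_cm
        if lo > hi:
            raise ValueError(f"accumulation_range_cm min > max: {self.accumulation_range_cm}")
        if lo < 5:
            raise ValueError(
                f"accumulation_range_cm minimum {lo} is below the 5 cm event threshold"
            )
        if not 0 <= self.shared_event_prob <= 1:
            raise ValueError(f"shared_event_prob must be in [0,1], got {self.shared_event_prob}")
        if abs(mix.w_rest + mix.w_travel - 1.0) > 1e-9:
            raise ValueError("speed_mixture weights must sum to 1")
        if mix.sd_rest_log10 <= 0 or mix.sd_travel_log10 <= 0:
            raise ValueError("speed_mixture SDs must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        """One independent RNG stream per module so regenerating cameras does
        not change tracks (stream 0: cameras/snow, 1: tracks, 2: speed pool)."""
        return np.random.default_rng([int(self.seed), int(stream)])


def project(lat, lon, config: SimConfig):
    """Geographic -> projected meters on the local tangent plane."""
    east = config.origin_easting + (np.asarray(lon) - config.origin_lon) * (
        _M_PER_DEG_LON_FACTOR * np.cos(np.radians(config.origin_lat))
    )
    north = config.origin_northing + (np.asarray(lat) - config.origin_lat) * _M_PER_DEG_LAT
    return east, north


def unproject(easting, northing, config: SimConfig):
    """Projected meters -> geographic degrees (inverse of :func:`project`)."""
    lon = config.origin_lon + (np.asarray(easting) - config.origin_easting) / (
        _M_PER_DEG_LON_FACTOR * np.cos(np.radians(config.origin_lat))
    )
    lat = config.origin_lat + (np.asarray(northing) - config.origin_northing) / _M_PER_DEG_LAT
    return lat, lon


@dataclass
class SnowSim:
    """Simulated camera network: deployments, daily readings, injected events."""

    deployments: pd.DataFrame   # snow.DEPLOYMENT_COLUMNS
    readings: pd.DataFrame      # snow.READING_COLUMNS
    events: pd.DataFrame        # camera_id, date, accumulation_cm (ground truth)


def simulate_snow_series(config: SimConfig) -> SnowSim:
    """Per-camera daily depth series with injected snowfall events.

    Cameras sit on a jittered grid across the study square, all deployed on
    the study start date with initial depths around the study's ~50 cm mean.
    Events are Poisson in number: a shared fraction (``shared_event_prob``)
    falls study-wide on one date, the rest are per-camera (localized), with
    24-h accumulations drawn as whole centimeters in ``accumulation_range_cm``.
    Non-event days drift by settling noise of scale ``depth_noise_cm``
    (0 disables it); depth is quantized to that resolution and never negative.
    """
    rng = config.rng(0)
    n = config.n_cameras
    extent_m = config.study_extent_km * 1000.0

    side = int(np.ceil(np.sqrt(n)))
    cell = extent_m / side
    positions = []
    for i in range(n):
        r, c = divmod(i, side)
        positions.append((
            config.origin_easting - extent_m / 2 + (c + 0.5) * cell + rng.uniform(-0.3, 0.3) * cell,
            config.origin_northing - extent_m / 2 + (r + 0.5) * cell + rng.uniform(-0.3, 0.3) * cell,
        ))
    east = np.array([p[0] for p in positions])
    north = np.array([p[1] for p in positions])
    lat, lon = unproject(east, north, config)
    cam_ids = [f"C{i + 1:02d}" for i in range(n)]
    init_depth = np.maximum(
        np.round(rng.normal(config.initial_depth_mean_cm, config.initial_depth_sd_cm, n)), 5.0
    )
    deployments = pd.DataFrame({
        "camera_id": cam_ids, "easting": east, "northing": north,
        "lat": lat, "lon": lon,
        "deploy_date": [config.start_date] * n,
        "initial_depth_cm": init_depth,
    })

    dates = [config.start_date + dt.timedelta(days=d) for d in range(config.n_days)]
    lo, hi = config.accumulation_range_cm
    # shared (study-wide) events: same date, per-camera accumulation
    n_shared = rng.poisson(config.event_rate * config.shared_event_prob)
    eligible_days = np.arange(1, config.n_days)  # day 0 has no 24-h difference
    shared_days = rng.choice(eligible_days, size=min(n_shared, len(eligible_days)), replace=False)

    readings, event_rows = [], []
    for ci, cam in enumerate(cam_ids):
        n_local = rng.poisson(config.event_rate * (1.0 - config.shared_event_prob))
        remaining = np.setdiff1d(eligible_days, shared_days)
        local_days = rng.choice(remaining, size=min(n_local, len(remaining)), replace=False)
        event_days = set(shared_days.tolist()) | set(local_days.tolist())

        depth = float(init_depth[ci])
        for d, date in enumerate(dates):
            if d > 0:
                if d in event_days:
                    accum = float(rng.integers(int(np.ceil(lo)), int(hi) + 1))
                    event_rows.append({"camera_id": cam, "date": date, "accumulation_cm": accum})
                elif config.depth_noise_cm > 0:
                    accum = config.depth_noise_cm * rng.choice([-1.0, 0.0, 1.0], p=[0.25, 0.55, 0.20])
                else:
                    accum = 0.0
                depth = max(depth + accum, 0.0)
            readings.append({"camera_id": cam, "date": date, "depth_cm": depth})

    return SnowSim(
        deployments=deployments,
        readings=pd.DataFrame(readings),
        events=pd.DataFrame(event_rows, columns=["camera_id", "date", "accumulation_cm"]),
    )


@dataclass
class TrackSim:
    """Simulated telemetry plus the ground truth that generated it."""

    fixes: pd.DataFrame         # telemetry.FIX_COLUMNS
    truth: pd.DataFrame         # per-step ground truth
    wolf_effects: pd.DataFrame  # per-wolf random effects and home centers


def _wolf_event_dates(home_e, home_n, snow: SnowSim):
    """Event dates of the camera nearest a wolf's home center."""
    dep = snow.deployments
    d2 = (dep["easting"] - home_e) ** 2 + (dep["northing"] - home_n) ** 2
    cam = dep["camera_id"].iloc[int(np.argmin(d2.to_numpy()))]
    ev = snow.events
    return cam, sorted(ev.loc[ev["camera_id"] == cam, "date"])


def simulate_wolf_tracks(config: SimConfig, snow: SnowSim) -> TrackSim:
    """Two-state (rest/travel) wolf trajectories on the camera landscape.

    Per wolf: a home center inside the study square; a per-step Bernoulli
    travel state whose probability follows ``behavior_model`` with the *true*
    covariates (night from the NOAA solar calculator at the home center,
    snowfall category from the nearest camera's injected events, control
    coefficients on all out-of-window days); travel-step speeds from
    ``speed_model`` (+ mixture travel SD), rest speeds from the mixture's
    rest component. Positions advance by speed x interval along a persistent
    random-walk heading with a homing bias beyond ``home_radius_km``.
    """
    rng = config.rng(1)
    mix = config.speed_mixture
    bm, sp = config.behavior_model, config.speed_model
    extent_m = config.study_extent_km * 1000.0
    interval = config.fix_interval_min
    n_fix = config.n_days * 24 * 60 // interval

    start_utc = dt.datetime.combine(config.start_date, dt.time(7, 0), tzinfo=dt.timezone.utc)
    times = pd.date_range(start_utc, periods=n_fix, freq=f"{interval}min")
    end_times = times[1:]

    # per-END-fix covariate scaffolding shared by all wolves except for sun
    # position, which is re-evaluated per wolf home (differences are seconds)
    cday = telemetry.camera_days(pd.Series(times), config.tz_offset_hours).to_numpy()

    fixes_frames, truth_frames, wolf_rows = [], [], []
    for wi in range(config.n_wolves):
        wolf = f"W{wi + 1:02d}"
        home_e = config.origin_easting + rng.uniform(-0.5, 0.5) * extent_m
        home_n = config.origin_northing + rng.uniform(-0.5, 0.5) * extent_m
        home_lat, home_lon = unproject(home_e, home_n, config)

        cam, event_dates = _wolf_event_dates(home_e, home_n, snow)
        all_days = sorted(set(cday))
        catmap = windows.assign_snowfall_categories(event_dates, all_days)
        cats = np.array([
            catmap[d] if catmap[d] != "unassigned" else "control" for d in cday
        ])

        sun_cache = {}
        night = np.empty(n_fix, dtype=float)
        for i, ts in enumerate(times):
            local_date = (ts + pd.Timedelta(hours=config.tz_offset_hours)).date()
            if local_date not in sun_cache:
                sun_cache[local_date] = solar.sun_times_utc(local_date, float(home_lat), float(home_lon))
            sunrise, sunset = sun_cache[local_date]
            night[i] = 0.0 if sunrise <= ts.to_pydatetime() < sunset else 1.0

        b_beh = rng.normal(0.0, bm.random_intercept_sd)
        b_spd = rng.normal(0.0, sp.random_intercept_sd)
        b_spd_night = rng.normal(0.0, sp.random_night_slope_sd)

        # state and speed per step (covariates at the step's END fix)
        night_s, cats_s = night[1:], cats[1:]
        lp = np.array([
            bm.linear_predictor(nv, cv, b_beh) for nv, cv in zip(night_s, cats_s)
        ])
        p_travel = 1.0 / (1.0 + np.exp(-lp))
        state = (rng.random(n_fix - 1) < p_travel).astype(int)

        mu_travel = (
            sp.intercept + b_spd + (sp.night + b_spd_night) * night_s
            + np.array([sp.category.get(c, 0.0) for c in cats_s])
        )
        log_speed = np.where(
            state == 1,
            rng.normal(mu_travel, mix.sd_travel_log10),
            rng.normal(mix.mu_rest_log10, mix.sd_rest_log10, size=n_fix - 1),
        )
        speed = 10.0 ** log_speed

        # persistent-heading walk with homing bias
        heading = rng.uniform(0, 2 * np.pi)
        e = np.empty(n_fix); n_ = np.empty(n_fix)
        e[0], n_[0] = home_e, home_n
        turn_sd = 0.6
        for i in range(n_fix - 1):
            heading += rng.normal(0.0, turn_sd)
            off_e, off_n = e[i] - home_e, n_[i] - home_n
            dist_home = np.hypot(off_e, off_n)
            if dist_home > config.home_radius_km * 1000.0:
                back = np.arctan2(-off_n, -off_e)
                # steer most of the way toward home
                delta = np.angle(np.exp(1j * (back - heading)))
                heading += 0.8 * delta
            d = speed[i] * interval
            e[i + 1] = e[i] + d * np.cos(heading)
            n_[i + 1] = n_[i] + d * np.sin(heading)
        lat, lon = unproject(e, n_, config)

        fixes_frames.append(pd.DataFrame({
            "wolf_id": wolf, "timestamp": times,
            "easting": e, "northing": n_, "lat": lat, "lon": lon,
        }))
        truth_frames.append(pd.DataFrame({
            "wolf_id": wolf, "end_time": end_times,
            "state": state, "speed_m_min": speed,
            "snowfall_category": cats_s,
            "time_of_day": np.where(night_s == 1, "night", "day"),
            "camera_day": cday[1:],
        }))
        wolf_rows.append({
            "wolf_id": wolf, "home_easting": home_e, "home_northing": home_n,
            "nearest_camera": cam,
            "b_behavior_intercept": b_beh, "b_speed_intercept": b_spd,
            "b_speed_night_slope": b_spd_night,
        })

    return TrackSim(
        fixes=pd.concat(fixes_frames, ignore_index=True),
        truth=pd.concat(truth_frames, ignore_index=True),
        wolf_effects=pd.DataFrame(wolf_rows),
    )


def simulate_speed_sample(config: SimConfig, n: int) -> np.ndarray:
    """Draw ``n`` pooled log10 speeds straight from the marginal mixture.

    Convenience sampler for testing the mixture fit in isolation from the
    movement process.
    """
    rng = config.rng(2)
    mix = config.speed_mixture
    is_travel = rng.random(n) < mix.w_travel
    out = np.where(
        is_travel,
        rng.normal(mix.mu_travel_log10, mix.sd_travel_log10, n),
        rng.normal(mix.mu_rest_log10, mix.sd_rest_log10, n),
    )
    return out


_FIXTURE_README = """\
Synthetic fixtures emulating a two-winter wolf/snow-camera study.

Files
-----
telemetry.csv      wolf_id,timestamp,easting,northing,lat,lon
                   One GPS fix per row; ISO-8601 UTC timestamps; projected
                   meters on a local tangent plane plus geographic degrees.
cameras.csv        camera_id,easting,northing,lat,lon,deploy_date,initial_depth_cm
                   One remote camera per row.
snow_readings.csv  camera_id,date,depth_cm
                   One daily noon snow-depth estimate per row.
truth_steps.csv    wolf_id,end_time,state,speed_m_min,snowfall_category,
                   time_of_day,camera_day
                   Ground-truth per-step states and covariates (state 1 =
                   travel), for recovery tests only.
truth_wolves.csv   Per-wolf home centers and random effects.
config.json        The generator configuration that produced the files.
"""


def write_fixtures(config: SimConfig, outdir) -> dict:
    """Write the full fixture set (telemetry, cameras, readings, truth, README).

    Identical config (including seed) yields byte-identical files. Returns
    the paths keyed by role.
    """
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snow_sim = simulate_snow_series(config)
    tracks = simulate_wolf_tracks(config, snow_sim)

    paths = {
        "telemetry": outdir / "telemetry.csv",
        "cameras": outdir / "cameras.csv",
        "snow_readings": outdir / "snow_readings.csv",
        "truth_steps": outdir / "truth_steps.csv",
        "truth_wolves": outdir / "truth_wolves.csv",
        "readme": outdir / "README.txt",
        "config": outdir / "config.json",
    }
    fixes = tracks.fixes.copy()
    fixes["timestamp"] = fixes["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    fixes.to_csv(paths["telemetry"], index=False, float_format="%.3f")
    snow_sim.deployments.to_csv(paths["cameras"], index=False, float_format="%.3f")
    snow_sim.readings.to_csv(paths["snow_readings"], index=False, float_format="%.1f")
    truth = tracks.truth.copy()
    truth["end_time"] = truth["end_time"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
    truth.to_csv(paths["truth_steps"], index=False, float_format="%.6f")
    tracks.wolf_effects.to_csv(paths["truth_wolves"], index=False, float_format="%.6f")
    paths["readme"].write_text(_FIXTURE_README)

    cfg = dataclasses.asdict(config)
    cfg["start_date"] = config.start_date.isoformat()
    cfg["accumulation_range_cm"] = list(config.accumulation_range_cm)
    paths["config"].write_text(json.dumps(cfg, indent=2, default=str))
    return paths
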