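"""GPS-fix ingestion, thinning, step metrics, centroids, and day/night labels.

The fix table is a pandas DataFrame with columns
``wolf_id, timestamp, easting, northing, lat, lon`` (timestamps UTC,
coordinates projected meters plus geographic degrees). Steps are the segments
between consecutive retained fixes of one wolf; their speed (m/min) is the
straight-line projected distance divided by the elapsed minutes.

Dates are handled on two clocks: the *camera day* (fixes after local noon
roll to the next date, aligning telemetry with the following noon camera
photo) and the real local date used for sunrise/sunset.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from . import solar

logger = logging.getLogger(__name__)

__all__ = [
    "FIX_COLUMNS",
    "DEFAULT_TZ_OFFSET_HOURS",
    "DEFAULT_INTERVAL_BAND_MIN",
    "read_fixes",
    "thin_to_interval",
    "assign_camera_day",
    "camera_days",
    "daily_centroids",
    "compute_steps",
]

FIX_COLUMNS = ["wolf_id", "timestamp", "easting", "northing", "lat", "lon"]

#: Study local time = UTC + this offset (Mountain Standard Time; the study
#: window is January-March, so no daylight-saving transition applies).
DEFAULT_TZ_OFFSET_HOURS = -7.0

#: Acceptance band (minutes) for step intervals after thinning to 30 min;
#: default matches the observed range of retained intervals in the original
#: study (19.75-40.92 min).
DEFAULT_INTERVAL_BAND_MIN = (19.75, 40.92)


def read_fixes(path) -> pd.DataFrame:
    """Read a telemetry CSV into a sorted, de-duplicated fix table.

    The file must carry the header ``wolf_id,timestamp,easting,northing,
    lat,lon`` with ISO-8601 zoned timestamps. Exact duplicate rows are dropped
    with a warning; output is sorted by (wolf_id, timestamp).
    """
    df = pd.read_csv(path)
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry file {path} is missing column(s): {', '.join(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # locate the first offending row for the error message
        parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="mixed")
        bad = parsed.isna()
        row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else -1
        raise ValueError(f"unparseable timestamp in {path} at data row {row}") from None
    for col in ("easting", "northing", "lat", "lon"):
        df[col] = pd.to_numeric(df[col])
    if not np.isfinite(df[["easting", "northing"]].to_numpy()).all():
        raise ValueError("non-finite easting/northing in telemetry input")
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise ValueError("lat/lon outside valid geographic range")

    n0 = len(df)
    df = df.drop_duplicates(subset=FIX_COLUMNS)
    if len(df) < n0:
        logger.warning("dropped %d duplicate fix rows", n0 - len(df))
    df = df.sort_values(["wolf_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    logger.info("read %d fixes for %d wolves", len(df), df["wolf_id"].nunique())
    return df[FIX_COLUMNS]


def thin_to_interval(fixes: pd.DataFrame, target_min: int = 30) -> pd.DataFrame:
    """Thin each wolf's fixes to one per ``target_min``-minute grid slot.

    The grid is anchored at the top of the hour (:00, :30 for the default).
    Each fix is assigned to its nearest grid time (exact midpoints go to the
    earlier slot); within a slot the fix nearest the grid time wins, ties
    resolved to the earlier fix. Data already on the grid pass through
    unchanged.
    """
    if fixes.empty:
        return fixes.copy()
    target_ns = int(target_min) * 60 * 1_000_000_000
    t = fixes["timestamp"].astype("int64")
    # nearest grid slot: floor((t + half) / target); an exact midpoint lands
    # on the boundary and floors to the earlier slot
    half = target_ns // 2
    slot = (t + half - 1) // target_ns  # -1 ns: exact midpoints floor to the earlier slot
    offset = (t - slot * target_ns).abs()
    work = fixes.assign(_slot=slot, _offset=offset)
    # within (wolf, slot): keep smallest offset, tie -> earliest timestamp
    work = work.sort_values(["wolf_id", "_slot", "_offset", "timestamp"], kind="mergesort")
    kept = work.groupby(["wolf_id", "_slot"], sort=False).head(1)
    kept = kept.sort_values(["wolf_id", "timestamp"], kind="mergesort")
    return kept.drop(columns=["_slot", "_offset"]).reset_index(drop=True)


def assign_camera_day(timestamp: dt.datetime | pd.Timestamp,
                      tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS) -> dt.date:
    """Camera-day date of a UTC timestamp.

    Snow cameras photograph at local noon, so telemetry after noon is only
    reflected in the next day's photo: fixes strictly after 12:00 local are
    assigned to the following calendar date. A fix at exactly noon keeps the
    real date (the noon photo is contemporaneous with it).
    """
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    local = ts.tz_convert(dt.timezone(dt.timedelta(hours=tz_offset_hours)))
    date = local.date()
    if (local.hour, local.minute, local.second, local.microsecond) > (12, 0, 0, 0):
        date = date + dt.timedelta(days=1)
    return date


def camera_days(timestamps: pd.Series, tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS) -> pd.Series:
    """Vectorized :func:`assign_camera_day` over a UTC timestamp Series."""
    local = timestamps.dt.tz_convert(dt.timezone(dt.timedelta(hours=tz_offset_hours)))
    after_noon = (
        (local.dt.hour > 12)
        | ((local.dt.hour == 12) & ((local.dt.minute > 0) | (local.dt.second > 0) | (local.dt.microsecond > 0)))
    )
    dates = local.dt.normalize() + pd.to_timedelta(after_noon.astype(int), unit="D")
    return pd.Series([d.date() for d in dates], index=timestamps.index, name="camera_day")


def daily_centroids(fixes: pd.DataFrame, tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS) -> pd.DataFrame:
    """Per-(wolf, camera_day) mean location.

    Centroids are arithmetic means of projected easting/northing; the
    geographic coordinates of the centroid are the means of lat/lon, which on
    the study's local tangent plane is the same projection applied in reverse.
    """
    work = fixes.copy()
    if "camera_day" not in work.columns:
        work["camera_day"] = camera_days(work["timestamp"], tz_offset_hours)
    out = (
        work.groupby(["wolf_id", "camera_day"], sort=True)
        .agg(
            easting=("easting", "mean"),
            northing=("northing", "mean"),
            lat=("lat", "mean"),
            lon=("lon", "mean"),
            n_fixes=("timestamp", "size"),
        )
        .reset_index()
    )
    return out


def compute_steps(
    fixes: pd.DataFrame,
    interval_band_min: tuple[float, float] = DEFAULT_INTERVAL_BAND_MIN,
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
    classify_day_night: bool = True,
) -> pd.DataFrame:
    """Build the step table from (thinned) fixes.

    One step per consecutive fix pair within a wolf; Euclidean distance on
    projected coordinates; speed in m/min. Steps whose interval falls outside
    ``interval_band_min`` (gaps, irregular fixes) are excluded and counted in
    the log. Each step carries the camera day and the day/night label of its
    ending fix; sunrise/sunset are evaluated at the wolf's daily-centroid
    coordinates for that camera day.
    """
    lo, hi = interval_band_min
    frames = []
    for wolf, grp in fixes.groupby("wolf_id", sort=True):
        if len(grp) < 2:
            logger.warning("wolf %s has %d fix(es); no steps", wolf, len(grp))
            continue
        g = grp.sort_values("timestamp")
        t = g["timestamp"].reset_index(drop=True)
        t_ns = t.astype("int64").to_numpy()
        interval = (t_ns[1:] - t_ns[:-1]) / 60e9
        dx = np.diff(g["easting"].to_numpy())
        dy = np.diff(g["northing"].to_numpy())
        dist = np.hypot(dx, dy)
        frames.append(
            pd.DataFrame(
                {
                    "wolf_id": wolf,
                    "start_time": t.iloc[:-1].to_numpy(),
                    "end_time": t.iloc[1:].to_numpy(),
                    "interval_min": interval,
                    "distance_m": dist,
                    "speed_m_min": dist / interval,
                    "end_lat": g["lat"].to_numpy()[1:],
                    "end_lon": g["lon"].to_numpy()[1:],
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "wolf_id", "start_time", "end_time", "interval_min", "distance_m",
                "speed_m_min", "end_lat", "end_lon", "camera_day", "time_of_day",
            ]
        )
    steps = pd.concat(frames, ignore_index=True)
    in_band = (steps["interval_min"] >= lo) & (steps["interval_min"] <= hi)
    n_out = int((~in_band).sum())
    if n_out:
        logger.info("excluded %d steps with interval outside [%.2f, %.2f] min", n_out, lo, hi)
    steps = steps[in_band].reset_index(drop=True)

    end_ts = pd.Series(steps["end_time"])
    if end_ts.dt.tz is None:
        end_ts = end_ts.dt.tz_localize("UTC")
    steps["camera_day"] = camera_days(end_ts, tz_offset_hours)

    if classify_day_night:
        cents = daily_centroids(
            fixes.assign(camera_day=camera_days(
                fixes["timestamp"] if fixes["timestamp"].dt.tz is not None
                else fixes["timestamp"].dt.tz_localize("UTC"), tz_offset_hours)),
            tz_offset_hours,
        ).set_index(["wolf_id", "camera_day"])
        # sun-time cache: one sunrise/sunset pair per (local date, rounded coords)
        cache: dict[tuple, tuple] = {}
        labels = []
        for wolf, ts, cday, lat, lon in zip(
            steps["wolf_id"], end_ts, steps["camera_day"], steps["end_lat"], steps["end_lon"]
        ):
            key = (wolf, cday)
            if key in cents.index:
                lat = cents.loc[key, "lat"]
                lon = cents.loc[key, "lon"]
            local_date = (ts + pd.Timedelta(hours=tz_offset_hours)).date()
            ckey = (local_date, round(lat, 3), round(lon, 3))
            if ckey not in cache:
                cache[ckey] = solar.sun_times_utc(local_date, lat, lon)
            sunrise, sunset = cache[ckey]
            labels.append("day" if sunrise <= ts.to_pydatetime() < sunset else "night")
        steps["time_of_day"] = labels
    return steps
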