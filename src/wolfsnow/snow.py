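"""Snow-camera depth series, snowfall-event detection, and wolf-day joins.

Each remote camera photographs a depth pole daily at local noon. Daily snow
accumulation is the first difference of the depth series (change over 24 h;
negative under settling or melt), and a *snowfall event* is an accumulation of
at least the event threshold (default 5 cm) in 24 h. Wolves are matched to
cameras through their daily centroid: for every (wolf, camera day) the nearest
deployed camera supplies that day's depth and accumulation, giving exactly one
snow record per wolf-day.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_EVENT_THRESHOLD_CM",
    "read_deployments",
    "read_depth_readings",
    "build_snow_daily",
    "nearest_camera",
    "join_wolf_day",
]

#: A snowfall event is >= this much accumulation (cm) in 24 hours.
DEFAULT_EVENT_THRESHOLD_CM = 5.0

DEPLOYMENT_COLUMNS = ["camera_id", "easting", "northing", "lat", "lon",
                      "deploy_date", "initial_depth_cm"]
READING_COLUMNS = ["camera_id", "date", "depth_cm"]


def read_deployments(path) -> pd.DataFrame:
    """Read the camera-deployment CSV (one row per camera)."""
    df = pd.read_csv(path)
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"deployment file {path} missing column(s): {', '.join(missing)}")
    df["deploy_date"] = pd.to_datetime(df["deploy_date"]).dt.date
    if (df["initial_depth_cm"] < 0).any():
        raise ValueError("initial_depth_cm must be >= 0")
    return df[DEPLOYMENT_COLUMNS]


def read_depth_readings(path) -> pd.DataFrame:
    """Read the per-camera daily depth CSV (one row per camera-date)."""
    df = pd.read_csv(path)
    missing = [c for c in READING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"depth readings file {path} missing column(s): {', '.join(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df[READING_COLUMNS]


def build_snow_daily(
    deployments: pd.DataFrame,
    depth_readings: pd.DataFrame,
    event_threshold_cm: float = DEFAULT_EVENT_THRESHOLD_CM,
) -> pd.DataFrame:
    """Per-camera daily depth, 24-h accumulation, and event flags.

    Accumulation on date t is ``depth(t) - depth(t-1)`` and is only defined
    when the previous calendar date has a reading: a camera's first day, and
    any day following a gap, get missing accumulation (a multi-day depth
    change is never spread across the gap). ``is_event`` is True iff the
    accumulation is defined and >= ``event_threshold_cm``.

    Raises
    ------
    ValueError
        On duplicate (camera, date) readings or readings dated before the
        camera's deployment.
    """
    dep = deployments.set_index("camera_id")
    if depth_readings.duplicated(subset=["camera_id", "date"]).any():
        dup = depth_readings[depth_readings.duplicated(subset=["camera_id", "date"], keep=False)]
        raise ValueError(
            "duplicate (camera_id, date) depth readings: "
            f"{sorted(set(map(tuple, dup[['camera_id', 'date']].to_numpy())))[:5]}"
        )
    frames = []
    for cam, grp in depth_readings.groupby("camera_id", sort=True):
        if cam not in dep.index:
            raise ValueError(f"depth readings reference unknown camera {cam!r}")
        deploy_date = dep.loc[cam, "deploy_date"]
        g = grp.sort_values("date").reset_index(drop=True)
        if (g["date"] < deploy_date).any():
            raise ValueError(f"camera {cam!r} has readings before its deployment date {deploy_date}")
        dates = pd.to_datetime(g["date"])
        depth = g["depth_cm"].to_numpy(dtype=float)
        if (depth < 0).any():
            raise ValueError(f"camera {cam!r} has negative depth readings")
        gap_days = dates.diff().dt.days.to_numpy()
        accum = np.full(len(g), np.nan)
        consecutive = np.flatnonzero(gap_days == 1)
        accum[consecutive] = depth[consecutive] - depth[consecutive - 1]
        frames.append(g.assign(accumulation_cm=accum))
    out = pd.concat(frames, ignore_index=True)
    out["is_event"] = out["accumulation_cm"].ge(event_threshold_cm).fillna(False)
    n_events = int(out["is_event"].sum())
    logger.info("snow daily: %d camera-days, %d event days (threshold %.1f cm)",
                len(out), n_events, event_threshold_cm)
    return out[["camera_id", "date", "depth_cm", "accumulation_cm", "is_event"]]


def nearest_camera(centroid_row, deployments: pd.DataFrame, date=None):
    """Nearest deployed camera to a daily centroid.

    Euclidean distance on projected coordinates; ties broken by
    lexicographically smallest camera_id. Only cameras deployed on or before
    ``date`` (if given) are eligible.

    Returns ``(camera_id, distance_km)``.
    """
    cams = deployments
    if date is not None:
        cams = cams[cams["deploy_date"] <= date]
    if cams.empty:
        raise ValueError(f"no camera deployed on or before {date}")
    dx = cams["easting"].to_numpy() - float(centroid_row["easting"])
    dy = cams["northing"].to_numpy() - float(centroid_row["northing"])
    dist_km = np.hypot(dx, dy) / 1000.0
    order = np.lexsort((cams["camera_id"].to_numpy(), dist_km))
    i = order[0]
    return cams["camera_id"].iloc[i], float(dist_km[i])


def join_wolf_day(
    centroids: pd.DataFrame,
    snow_daily: pd.DataFrame,
    deployments: pd.DataFrame,
) -> pd.DataFrame:
    """One snow record per (wolf, camera day) via the nearest camera.

    Days whose nearest camera lacks a reading for that date keep their row
    with missing depth/accumulation and ``is_event=False``. Centroid-to-camera
    distances are returned (and summarized in the log) as a data-quality
    check.
    """
    snow_idx = snow_daily.set_index(["camera_id", "date"])
    rows = []
    for _, c in centroids.iterrows():
        cam, dist_km = nearest_camera(c, deployments, date=c["camera_day"])
        key = (cam, c["camera_day"])
        if key in snow_idx.index:
            rec = snow_idx.loc[key]
            depth, accum, ev = rec["depth_cm"], rec["accumulation_cm"], bool(rec["is_event"])
        else:
            depth, accum, ev = np.nan, np.nan, False
        rows.append(
            {
                "wolf_id": c["wolf_id"],
                "camera_day": c["camera_day"],
                "camera_id": cam,
                "distance_to_camera_km": dist_km,
                "depth_cm": depth,
                "accumulation_cm": accum,
                "is_event": ev,
            }
        )
    out = pd.DataFrame(rows)
    if out.duplicated(subset=["wolf_id", "camera_day"]).any():
        raise AssertionError("internal error: multiple snow records for one wolf-day")
    logger.info(
        "wolf-day snow join: %d rows, camera distance %.1f ± %.1f km",
        len(out), out["distance_to_camera_km"].mean(), out["distance_to_camera_km"].std(),
    )
    return out
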