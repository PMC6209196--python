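"""NOAA solar position calculations: sunrise, sunset, and day/night labels.

Implements the standard NOAA Solar Calculator equations (Meeus-based low
precision algorithm) for official sunrise/sunset, i.e. the times at which the
solar zenith angle crosses 90.833 degrees (solar elevation -0.833 degrees,
accounting for atmospheric refraction and the solar disc radius). Accuracy is
on the order of one minute at mid latitudes, which is far finer than the
30-minute telemetry grid it serves.
"""

from __future__ import annotations

import datetime as dt
import math

__all__ = [
    "sun_times_utc",
    "classify_time_of_day",
    "UnsupportedLatitudeError",
]

#: Official sunrise/sunset zenith (degrees): refraction + solar semidiameter.
OFFICIAL_ZENITH_DEG = 90.833

#: Latitude band supported: beyond this, winter polar night breaks the
#: sunrise/sunset dichotomy the day/night labels rely on.
MAX_ABS_LATITUDE_DEG = 66.5


class UnsupportedLatitudeError(ValueError):
    """Raised for latitudes where polar day or night can occur."""


def _julian_day(date: dt.date) -> float:
    """Julian day number at 0h UT for a calendar date."""
    y, m, d = date.year, date.month, date.day
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_params(jc: float) -> tuple[float, float]:
    """Sun declination (degrees) and equation of time (minutes) at a Julian century."""
    geom_mean_long = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    geom_mean_anom = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    m_rad = math.radians(geom_mean_anom)
    eq_center = (
        math.sin(m_rad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * m_rad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * m_rad) * 0.000289
    )
    true_long = geom_mean_long + eq_center
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(math.radians(omega))

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq_corr = mean_obliq + 0.00256 * math.cos(math.radians(omega))

    decl = math.degrees(
        math.asin(math.sin(math.radians(obliq_corr)) * math.sin(math.radians(app_long)))
    )

    var_y = math.tan(math.radians(obliq_corr / 2.0)) ** 2
    l_rad = math.radians(geom_mean_long)
    eq_time = 4.0 * math.degrees(
        var_y * math.sin(2 * l_rad)
        - 2.0 * ecc * math.sin(m_rad)
        + 4.0 * ecc * var_y * math.sin(m_rad) * math.cos(2 * l_rad)
        - 0.5 * var_y * var_y * math.sin(4 * l_rad)
        - 1.25 * ecc * ecc * math.sin(2 * m_rad)
    )
    return decl, eq_time


def sun_times_utc(date: dt.date, lat: float, lon: float) -> tuple[dt.datetime, dt.datetime]:
    """Official sunrise and sunset as UTC datetimes for a calendar date.

    Parameters
    ----------
    date:
        Calendar date (the local civil date for which sun times are wanted).
    lat, lon:
        Geographic coordinates in decimal degrees; west longitudes negative.

    Returns
    -------
    (sunrise_utc, sunset_utc), timezone-aware UTC datetimes.

    Raises
    ------
    UnsupportedLatitudeError
        If ``abs(lat) >= 66.5`` where the official crossing may not exist.
    """
    if abs(lat) >= MAX_ABS_LATITUDE_DEG:
        raise UnsupportedLatitudeError(
            f"latitude {lat:.2f} is in the polar band (|lat| >= {MAX_ABS_LATITUDE_DEG}); "
            "day/night classification by sunrise/sunset is undefined there"
        )
    jd = _julian_day(date)
    # Two-pass refinement: evaluate solar parameters at approximate solar noon.
    jc = (jd + 0.5 - lon / 360.0 - 2451545.0) / 36525.0
    decl, eq_time = _solar_params(jc)

    lat_rad = math.radians(lat)
    decl_rad = math.radians(decl)
    cos_ha = (
        math.cos(math.radians(OFFICIAL_ZENITH_DEG)) / (math.cos(lat_rad) * math.cos(decl_rad))
        - math.tan(lat_rad) * math.tan(decl_rad)
    )
    if not -1.0 <= cos_ha <= 1.0:  # pragma: no cover - excluded by the latitude guard
        raise UnsupportedLatitudeError(
            f"sun does not cross the horizon at lat={lat:.2f} on {date}"
        )
    ha_deg = math.degrees(math.acos(cos_ha))

    solar_noon_min = 720.0 - 4.0 * lon - eq_time  # minutes UTC
    sunrise_min = solar_noon_min - 4.0 * ha_deg
    sunset_min = solar_noon_min + 4.0 * ha_deg

    base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    return (
        base + dt.timedelta(minutes=sunrise_min),
        base + dt.timedelta(minutes=sunset_min),
    )


def classify_time_of_day(
    timestamp_utc: dt.datetime,
    lat: float,
    lon: float,
    tz_offset_hours: float,
) -> str:
    """Label a UTC timestamp ``"day"`` or ``"night"`` at a location.

    "Day" means sunrise <= t < sunset for the local calendar date of the
    timestamp; everything else is "night". The local date is derived from the
    fixed study offset ``tz_offset_hours`` (no daylight-saving logic: the
    study window is mid-winter).
    """
    if timestamp_utc.tzinfo is None:
        timestamp_utc = timestamp_utc.replace(tzinfo=dt.timezone.utc)
    local = timestamp_utc + dt.timedelta(hours=tz_offset_hours)
    sunrise, sunset = sun_times_utc(local.date(), lat, lon)
    return "day" if sunrise <= timestamp_utc < sunset else "night"
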