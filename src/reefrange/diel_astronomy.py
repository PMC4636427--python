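"""Sunrise/sunset, day/night assignment, hourly detection profiles, and
moon illumination.

Sun times come from the NOAA solar position algorithm (the equations
behind the NOAA solar calculator): Julian-century solar coordinates, the
equation of time, and the hour angle at which the solar altitude crosses
-0.833 degrees (civil sunrise/sunset with standard refraction and solar
semi-diameter).  Accuracy is within about two minutes of standard
ephemerides for non-polar latitudes, ample for binning detections by diel
phase.  The study clock is one fixed UTC offset with no daylight-saving
transitions, so hour-of-day bins are stable year-round.

Moon illumination uses the mean synodic cycle: the illuminated fraction is
(1 - cos(2 pi age / 29.530588)) / 2 where age is days since a reference
new moon (2000-01-06 18:14 UT).  True phase can lead or lag the mean
cycle by several hours, so values are accurate to about 0.05 away from
the quarter-phase inflections; an externally supplied almanac table can
be substituted where exact values matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .detections_core import DEFAULT_UTC_OFFSET_HOURS, utc_offset_tz

SUNRISE_SUNSET_ZENITH_DEG = 90.833  # civil: refraction + solar semi-diameter
SYNODIC_MONTH_DAYS = 29.530588853
#: Julian date of the reference new moon, 2000-01-06 18:14 UT.
NEW_MOON_EPOCH_JD = 2451550.26


@dataclass
class SolarDay:
    date: date
    sunrise: datetime
    sunset: datetime

    @property
    def day_length_h(self) -> float:
        return (self.sunset - self.sunrise).total_seconds() / 3600.0


def _julian_day(dt_utc: datetime) -> float:
    frac = (dt_utc.hour + dt_utc.minute / 60.0 + dt_utc.second / 3600.0) / 24.0
    return dt_utc.toordinal() + 1721424.5 + frac


def _solar_params(jc: float) -> tuple[float, float, float]:
    """(declination deg, equation of time minutes, _) at Julian century jc."""
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = math.radians(m)
    c = (math.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
         + math.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
         + math.sin(3 * mrad) * 0.000289)
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(omega)
    decl = math.degrees(math.asin(math.sin(math.radians(eps))
                                  * math.sin(math.radians(app_long))))
    y = math.tan(math.radians(eps / 2.0)) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r) - 2 * e * math.sin(mrad)
        + 4 * e * y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r) - 1.25 * e * e * math.sin(2 * mrad))
    return decl, eot, eps


def sun_times(d: date, lat: float, lon: float,
              utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS) -> SolarDay:
    """Civil sunrise and sunset (solar altitude -0.833 deg) for one date.

    Raises for latitudes poleward of 66 degrees, where the algorithm's
    no-polar-day assumption breaks down.
    """
    if abs(lat) >= 66.0:
        raise ValueError("unsupported latitude (polar day/night not handled)")
    tz = utc_offset_tz(utc_offset_hours)
    # evaluate solar coordinates at local solar noon (one pass is ample)
    approx_noon_utc = datetime(d.year, d.month, d.day, 12, tzinfo=tz).astimezone(timezone.utc)
    jc = (_julian_day(approx_noon_utc) - 2451545.0) / 36525.0
    decl, eot, _ = _solar_params(jc)
    latr, declr = math.radians(lat), math.radians(decl)
    cos_ha = (math.cos(math.radians(SUNRISE_SUNSET_ZENITH_DEG))
              / (math.cos(latr) * math.cos(declr))
              - math.tan(latr) * math.tan(declr))
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha = math.degrees(math.acos(cos_ha))
    noon_min = 720.0 - 4.0 * lon - eot + utc_offset_hours * 60.0
    midnight = datetime(d.year, d.month, d.day, tzinfo=tz)
    sunrise = midnight + timedelta(minutes=noon_min - 4.0 * ha)
    sunset = midnight + timedelta(minutes=noon_min + 4.0 * ha)
    return SolarDay(d, sunrise, sunset)


def solar_days_for(dates: Iterable[date], lat: float, lon: float,
                   utc_offset_hours: float = DEFAULT_UTC_OFFSET_HOURS
                   ) -> dict[date, SolarDay]:
    return {d: sun_times(d, lat, lon, utc_offset_hours) for d in sorted(set(dates))}


def assign_phase(timestamp: datetime, solar: SolarDay) -> str:
    """'day' iff sunrise <= t < sunset of the timestamp's date, else 'night'."""
    return "day" if solar.sunrise <= timestamp < solar.sunset else "night"


def assign_phases(dets: pd.DataFrame, solar_days: Mapping[date, SolarDay]) -> pd.Series:
    """Vectorised phase per detection row."""
    out = []
    for t in dets["timestamp"]:
        sd = solar_days.get(t.date())
        if sd is None:
            raise KeyError(f"no solar day for {t.date()}")
        out.append(assign_phase(t, sd))
    return pd.Series(out, index=dets.index, name="phase")


def day_night_proportions(dets: pd.DataFrame,
                          solar_days: Mapping[date, SolarDay]) -> tuple[float, float]:
    """Per-fish proportions of detections by phase; they sum to one."""
    if dets.empty:
        raise ValueError("no detections")
    ph = assign_phases(dets, solar_days)
    p_day = float((ph == "day").mean())
    return p_day, 1.0 - p_day


def hourly_profile(dets: pd.DataFrame, n_days: int | None = None) -> np.ndarray:
    """Mean detections per clock hour (24-vector) across study days.

    *n_days* defaults to the number of distinct local dates with data; the
    vector then sums to the mean detections per day.
    """
    if dets.empty:
        raise ValueError("no detections")
    if n_days is None:
        n_days = dets["timestamp"].dt.date.nunique()
    counts = dets.groupby(dets["timestamp"].dt.hour).size()
    return counts.reindex(range(24), fill_value=0).to_numpy(dtype=float) / n_days


def moon_illumination(d: date | datetime) -> float:
    """Illuminated fraction of the moon's disc (0 new, 1 full) for a date,
    from the mean synodic cycle."""
    if isinstance(d, datetime):
        dt_utc = d.astimezone(timezone.utc) if d.tzinfo else d.replace(tzinfo=timezone.utc)
    else:
        dt_utc = datetime(d.year, d.month, d.day, 12, tzinfo=timezone.utc)
    age = (_julian_day(dt_utc) - NEW_MOON_EPOCH_JD) % SYNODIC_MONTH_DAYS
    return (1.0 - math.cos(2.0 * math.pi * age / SYNODIC_MONTH_DAYS)) / 2.0
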