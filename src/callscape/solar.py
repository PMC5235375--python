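"""Sun and moon timing utilities.

Sunrise/sunset follow the standard NOAA solar-position algorithm; lunar
phases use a linear synodic approximation anchored at the first new moon
of 2000.  Both are adequate for minute-scale day/night partitioning and
night-grouping by moonlight; an exact user-supplied phase table can be
used instead wherever these defaults feed an analysis.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

__all__ = [
    "SolarContext",
    "sun_times",
    "moon_age_days",
    "moon_phase",
    "nearest_phase_date",
    "SYNODIC_MONTH_DAYS",
]

SYNODIC_MONTH_DAYS = 29.530588853
#: New moon of 2000-01-06 18:14 UTC (Meeus), as a datetime.
_NEW_MOON_EPOCH = dt.datetime(2000, 1, 6, 18, 14, tzinfo=dt.timezone.utc)

_ZENITH_OFFICIAL = math.radians(90.833)  # refraction + solar radius


def _solar_minutes(date: dt.date, latitude: float, longitude: float) -> tuple[float, float]:
    """Sunrise/sunset in minutes after UTC midnight (NOAA algorithm)."""
    doy = date.timetuple().tm_yday
    year_len = 366 if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0) else 365
    gamma = 2.0 * math.pi / year_len * (doy - 1 + 0.5)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    lat = math.radians(latitude)
    cos_ha = (math.cos(_ZENITH_OFFICIAL) - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError(f"sun does not rise/set on {date} at latitude {latitude}")
    ha_deg = math.degrees(math.acos(cos_ha))
    sunrise = 720.0 - 4.0 * (longitude + ha_deg) - eqtime
    sunset = 720.0 - 4.0 * (longitude - ha_deg) - eqtime
    return sunrise, sunset


def sun_times(
    date: dt.date, latitude: float, longitude: float, tz_offset_hours: float
) -> tuple[dt.datetime, dt.datetime]:
    """Local sunrise and sunset (naive datetimes at the given UTC offset)."""
    rise_min, set_min = _solar_minutes(date, latitude, longitude)
    midnight = dt.datetime.combine(date, dt.time())
    offset = dt.timedelta(hours=tz_offset_hours)
    sunrise = midnight + dt.timedelta(minutes=rise_min) + offset
    sunset = midnight + dt.timedelta(minutes=set_min) + offset
    return sunrise, sunset


@dataclass
class SolarContext:
    """Per-site solar geometry used to partition events into day/night."""

    latitude: float
    longitude: float
    tz_offset_hours: float

    def sun_times(self, date: dt.date) -> tuple[dt.datetime, dt.datetime]:
        sunrise, sunset = sun_times(date, self.latitude, self.longitude, self.tz_offset_hours)
        if not sunrise < sunset:
            raise ValueError("sunrise must precede sunset")
        return sunrise, sunset


def moon_age_days(when: dt.date | dt.datetime) -> float:
    """Days elapsed since the last new moon (0 <= age < synodic month)."""
    if isinstance(when, dt.date) and not isinstance(when, dt.datetime):
        when = dt.datetime.combine(when, dt.time(12))
    if when.tzinfo is None:
        when = when.replace(tzinfo=dt.timezone.utc)
    days = (when - _NEW_MOON_EPOCH).total_seconds() / 86400.0
    return days % SYNODIC_MONTH_DAYS


def moon_phase(when: dt.date | dt.datetime) -> str:
    """Coarse phase label: new, first_quarter, full, or last_quarter."""
    age = moon_age_days(when)
    q = SYNODIC_MONTH_DAYS / 4.0
    if age < q / 2 or age >= SYNODIC_MONTH_DAYS - q / 2:
        return "new"
    if age < 1.5 * q:
        return "first_quarter"
    if age < 2.5 * q:
        return "full"
    return "last_quarter"


def nearest_phase_date(date: dt.date, phase: str) -> dt.date:
    """Calendar date of the new/full moon nearest to ``date``."""
    if phase not in ("new", "full"):
        raise ValueError("phase must be 'new' or 'full'")
    target_age = 0.0 if phase == "new" else SYNODIC_MONTH_DAYS / 2.0
    age = moon_age_days(date)
    delta = age - target_age
    # wrap to [-half, +half] synodic month
    half = SYNODIC_MONTH_DAYS / 2.0
    if delta > half:
        delta -= SYNODIC_MONTH_DAYS
    elif delta < -half:
        delta += SYNODIC_MONTH_DAYS
    return date - dt.timedelta(days=round(delta))
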