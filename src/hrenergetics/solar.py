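"""Sunrise/sunset computation (NOAA solar geometry).

Day-phases of a bat-day are anchored to local sunrise and sunset, so the
budget stage needs solar event times for the roost coordinates.  The NOAA
Solar Calculator equations are implemented directly; they are accurate to
well under two minutes at temperate latitudes, which is ample for phase
boundaries defined at minute resolution.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import NamedTuple

__all__ = ["SolarTimes", "solar_times"]

# official sunrise/sunset zenith: solar centre 50 arcmin below horizon
_ZENITH_DEG = 90.833


class SolarTimes(NamedTuple):
    """Sunrise and sunset as timezone-aware UTC datetimes.

    Either field is ``None`` when the event does not occur on that date
    (polar day or polar night).
    """

    sunrise: dt.datetime | None
    sunset: dt.datetime | None


def _solar_position(gamma: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians).

    ``gamma`` is the fractional year in radians.
    """
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
    return eqtime, decl


def solar_times(latitude: float, longitude: float, date: dt.date) -> SolarTimes:
    """Compute sunrise and sunset (UTC) for one civil date.

    Parameters
    ----------
    latitude, longitude
        Decimal degrees; east and north positive.
    date
        Civil date for which the events are computed.

    Returns
    -------
    SolarTimes
        UTC sunrise and sunset; a field is ``None`` for polar day/night.

    Raises
    ------
    ValueError
        If the coordinates are outside their valid ranges.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude!r} outside [-90, 90]")
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude {longitude!r} outside [-180, 180]")

    doy = date.timetuple().tm_yday
    year_len = 366 if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0) else 365
    gamma = 2.0 * math.pi / year_len * (doy - 1 + (12 - 12) / 24)
    eqtime, decl = _solar_position(gamma)

    lat_rad = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(_ZENITH_DEG)) / (math.cos(lat_rad) * math.cos(decl))
        - math.tan(lat_rad) * math.tan(decl)
    )
    if cos_ha > 1.0:  # sun never rises
        return SolarTimes(None, None)
    if cos_ha < -1.0:  # sun never sets
        return SolarTimes(None, None)

    ha_deg = math.degrees(math.acos(cos_ha))
    # minutes past UTC midnight
    sunrise_min = 720.0 - 4.0 * (longitude + ha_deg) - eqtime
    sunset_min = 720.0 - 4.0 * (longitude - ha_deg) - eqtime

    midnight = dt.datetime.combine(date, dt.time(0), tzinfo=dt.timezone.utc)
    return SolarTimes(
        midnight + dt.timedelta(minutes=sunrise_min),
        midnight + dt.timedelta(minutes=sunset_min),
    )
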