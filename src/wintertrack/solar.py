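"""Solar geometry for light-level geolocation.

Twilight times are controlled by two angles that depend only on the day of
year — the solar declination delta and the equation of time — plus the
observer's position.  With h0 the sun-elevation angle defining twilight,
the half day length H (degrees of hour angle) satisfies

    cos H = (sin h0 - sin phi sin delta) / (cos phi cos delta)

and local apparent noon in UTC hours is 12 - lon/15 - EoT/60.  Dawn/dusk
are noon -/+ H/15.  Everything here is vectorized over numpy arrays.

Declination and equation of time use the Spencer Fourier expansions,
accurate to ~0.1 degrees / ~0.6 min, which is ample for geolocation whose
intrinsic errors are tens of km.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: default twilight sun elevation (degrees); a common archival-tag convention
DEFAULT_TWILIGHT_ELEVATION = -3.44


def _gamma(doy):
    return 2.0 * np.pi * (np.asarray(doy, dtype=float) - 1.0) / 365.0


def solar_declination_deg(doy):
    """Solar declination (degrees) for day-of-year (1..366)."""
    g = _gamma(doy)
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    return np.degrees(decl)

def equation_of_time_minutes(doy):
    """Equation of time (minutes, true solar minus mean solar) for day-of-year."""
    g = _gamma(doy)
    return 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                     - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))


def half_daylength_hours(doy, lat, elevation_deg=DEFAULT_TWILIGHT_ELEVATION):
    """Half day length in hours, NaN under polar day/night at this elevation."""
    decl = np.radians(solar_declination_deg(doy))
    phi = np.radians(np.asarray(lat, dtype=float))
    h0 = np.radians(elevation_deg)
    cos_h = (np.sin(h0) - np.sin(phi) * np.sin(decl)) / (np.cos(phi) * np.cos(decl))
    with np.errstate(invalid="ignore"):
        h = np.degrees(np.arccos(np.where(np.abs(cos_h) <= 1.0, cos_h, np.nan)))
    return h / 15.0


def solar_noon_utc_hours(doy, lon):
    """UTC hour of local apparent noon."""
    return 12.0 - np.asarray(lon, dtype=float) / 15.0 - equation_of_time_minutes(doy) / 60.0


def twilight_hours_utc(doy, lon, lat, elevation_deg=DEFAULT_TWILIGHT_ELEVATION):
    """(dawn, dusk) in UTC hours relative to the date's midnight.

    Values may fall outside [0, 24) for far-western longitudes; they are
    hours *since that date's 00:00 UTC*, not clock times, so that the
    forward model and its inversion share one frame.  NaN pairs mark polar
    day or night.
    """
    half = half_daylength_hours(doy, lat, elevation_deg)
    noon = solar_noon_utc_hours(doy, lon)
    return noon - half, noon + half


def day_of_year(times) -> np.ndarray:
    """Day-of-year for datetime-like scalars/arrays."""
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]")))
    return idx.dayofyear.to_numpy()
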