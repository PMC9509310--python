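"""Solar geometry: declination, equation of time, zenith angle, day length.

Uses the Spencer (1971) Fourier series for declination and equation of
time as popularized by the NOAA solar calculator.  Accurate to a small
fraction of a degree, which is ample for canopy radiative transfer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _fractional_year(doy, hour_utc):
    return 2.0 * np.pi / 365.0 * (doy - 1 + (hour_utc - 12.0) / 24.0)


def declination(doy, hour_utc=12.0):
    """Solar declination (radians)."""
    g = _fractional_year(np.asarray(doy, dtype=float), hour_utc)
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def equation_of_time(doy, hour_utc=12.0):
    """Equation of time (minutes)."""
    g = _fractional_year(np.asarray(doy, dtype=float), hour_utc)
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )


def sun_zenith(times, lat_deg, lon_deg):
    """Solar zenith angle (radians) for tz-aware timestamps.

    Parameters
    ----------
    times : DatetimeIndex or Series (timezone-aware)
    lat_deg, lon_deg : site coordinates, east-positive longitude.

    Returns
    -------
    ndarray of zenith angles in radians (can exceed pi/2 at night).
    """
    idx = pd.DatetimeIndex(times)
    if idx.tz is None:
        raise ValueError("timestamps must be timezone-aware")
    utc = idx.tz_convert("UTC")
    doy = utc.dayofyear.to_numpy(dtype=float)
    hour = (
        utc.hour.to_numpy(dtype=float)
        + utc.minute.to_numpy(dtype=float) / 60.0
        + utc.second.to_numpy(dtype=float) / 3600.0
    )
    decl = declination(doy, hour)
    eqt = equation_of_time(doy, hour)
    # true solar time in minutes
    tst = hour * 60.0 + eqt + 4.0 * lon_deg
    ha = np.deg2rad(tst / 4.0 - 180.0)
    lat = np.deg2rad(lat_deg)
    cos_z = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(ha)
    return np.arccos(np.clip(cos_z, -1.0, 1.0))


def sunrise_sunset_hours(doy, lat_deg, lon_deg):
    """Sunrise and sunset, in fractional hours UTC, plus solar noon.

    Returns (rise_utc, set_utc, noon_utc) arrays; polar cases clipped.
    """
    doy = np.asarray(doy, dtype=float)
    decl = declination(doy)
    lat = np.deg2rad(lat_deg)
    cos_h0 = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    h0 = np.arccos(cos_h0)  # half day length in radians
    half_day_h = np.rad2deg(h0) / 15.0
    noon_utc = 12.0 - (4.0 * lon_deg + equation_of_time(doy)) / 60.0
    return noon_utc - half_day_h, noon_utc + half_day_h, noon_utc


def extraterrestrial_normal(doy):
    """Extraterrestrial normal irradiance (W m-2) with eccentricity."""
    doy = np.asarray(doy, dtype=float)
    return 1367.0 * (1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0))
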