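"""Daily solar geometry on a 365-day calendar.

Standard FAO-56 style formulas for extraterrestrial radiation and
astronomical daylength.  All angles are handled in radians internally;
latitudes are signed degrees (southern hemisphere negative) and ``doy``
is the day of year in 1..365 (no leap days anywhere in the package).
"""

from __future__ import annotations

import numpy as np

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
#: Default sun elevation at sunrise/sunset (deg); -0.833 accounts for
#: atmospheric refraction plus the solar radius.
DEFAULT_HORIZON_ANGLE = -0.833


def _declination(doy):
    return 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)


def _inv_rel_distance(doy):
    return 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)


def extraterrestrial_radiation(latitude: float, doy) -> float | np.ndarray:
    """Daily extraterrestrial radiation Ra in MJ m-2 day-1.

    Parameters
    ----------
    latitude : float
        Signed latitude in degrees, in [-90, 90].
    doy : int or array-like
        Day of year, 1..365.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    doy = np.asarray(doy, dtype=float)
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("doy must be in 1..366")
    phi = np.deg2rad(latitude)
    delta = _declination(doy)
    dr = _inv_rel_distance(doy)
    cos_ws = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta)
        + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    out = np.maximum(ra, 0.0)
    return float(out) if out.ndim == 0 else out


def daylength(latitude: float, doy, horizon_angle: float = DEFAULT_HORIZON_ANGLE):
    """Daylength in hours between sun crossings of ``horizon_angle``.

    With the default horizon angle this matches NOAA-style sunrise/sunset
    daylength; set ``horizon_angle=0`` for the purely geometric value.
    Always in [0, 24].
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(latitude)
    delta = _declination(doy)
    h0 = np.deg2rad(horizon_angle)
    cos_ws = (np.sin(h0) - np.sin(phi) * np.sin(delta)) / (
        np.cos(phi) * np.cos(delta)
    )
    ws = np.arccos(np.clip(cos_ws, -1.0, 1.0))
    out = 24.0 / np.pi * ws
    return float(out) if out.ndim == 0 else out
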