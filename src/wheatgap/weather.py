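"""Stochastic daily weather generation and weather file I/O.

A reduced stochastic generator stands in for fitting a semi-empirical
generator to 30 years of observations (which do not exist for the
synthetic sites): sinusoidal annual cycles for mean temperature and
radiation (phase flipped by hemisphere), AR(1) temperature residuals,
two-state Markov precipitation occurrence with exponential wet-day
amounts scaled to the target annual total, and wet-day radiation
damping with a final rescale to preserve the target radiation mean.

All values are rounded to 2 decimal places at generation time so a
written weather file round-trips bit-exactly.  The calendar has 365-day
years (no leap days).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .sites import SiteClimate
from .solar import extraterrestrial_radiation

__all__ = [
    "DailyWeather",
    "WeatherSeries",
    "generate_weather",
    "read_weather",
    "write_weather",
]

DAYS_PER_YEAR = 365
#: lag-1 autocorrelation of daily mean-temperature residuals
TEMP_AUTOCORR = 0.7
#: multiplicative radiation noise (log-scale SD)
RAD_NOISE_SD = 0.12
#: radiation on wet days is damped by this factor before rescaling
WET_DAY_RAD_FACTOR = 0.75
#: generated radiation is capped at this clearness fraction of Ra
MAX_CLEARNESS = 0.78
MIN_RADIATION = 0.25  # MJ m-2 day-1 floor (heavily overcast)

# warmest day of year (temperature lags the solstice by ~1 month)
TEMP_PEAK_DOY_N = 200
TEMP_PEAK_DOY_S = 18
RAD_PEAK_DOY_N = 172
RAD_PEAK_DOY_S = 355


@dataclass(frozen=True)
class DailyWeather:
    day_index: int
    doy: int
    tmin: float
    tmax: float
    precip: float
    radiation: float


@dataclass
class WeatherSeries:
    """A multi-year daily weather record backed by numpy arrays."""

    site: SiteClimate
    n_years: int
    doy: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    precip: np.ndarray
    radiation: np.ndarray
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.doy)

    def __getitem__(self, i: int) -> DailyWeather:
        return DailyWeather(
            day_index=i,
            doy=int(self.doy[i]),
            tmin=float(self.tmin[i]),
            tmax=float(self.tmax[i]),
            precip=float(self.precip[i]),
            radiation=float(self.radiation[i]),
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "doy": self.doy,
                "tmin": self.tmin,
                "tmax": self.tmax,
                "precip": self.precip,
                "radiation": self.radiation,
            }
        )

    def validate(self) -> None:
        if len(self.doy) != self.n_years * DAYS_PER_YEAR:
            raise ValueError("series length inconsistent with n_years")
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin in series")
        if np.any(self.precip < 0):
            raise ValueError("negative precipitation in series")
        ra = extraterrestrial_radiation(self.site.latitude, self.doy)
        if np.any(self.radiation < 0) or np.any(self.radiation > ra + 1e-9):
            raise ValueError("radiation outside [0, extraterrestrial] bound")


def _seasonal(mean: float, amplitude: float, doy: np.ndarray, peak: int) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - peak) / DAYS_PER_YEAR)


def generate_weather(site: SiteClimate, n_years: int, seed: int) -> WeatherSeries:
    """Generate a seeded ``n_years``-long daily weather series for ``site``.

    The realised 100-year means of temperature, precipitation and
    radiation land within 0.3 degC / 3% / 3% of the site targets, the
    seasonal cycle is phase-shifted six months in the southern
    hemisphere, and every day respects the physical bounds
    (tmax >= tmin, precip >= 0, 0 <= radiation <= Ra).
    """
    if not isinstance(site, SiteClimate):
        raise TypeError("site must be a SiteClimate")
    if n_years < 1:
        raise ValueError(f"n_years must be >= 1, got {n_years}")
    rng = np.random.default_rng(seed)
    n = n_years * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)

    north = site.latitude >= 0
    t_peak = TEMP_PEAK_DOY_N if north else TEMP_PEAK_DOY_S
    r_peak = RAD_PEAK_DOY_N if north else RAD_PEAK_DOY_S

    # --- temperature: sinusoid + AR(1) residual ---
    tseas = _seasonal(site.mean_temp, site.seasonal_temp_amplitude, doy, t_peak)
    eps = rng.standard_normal(n) * site.temp_residual_sd
    resid = np.empty(n)
    resid[0] = eps[0]
    innov_scale = np.sqrt(1.0 - TEMP_AUTOCORR**2)
    for i in range(1, n):
        resid[i] = TEMP_AUTOCORR * resid[i - 1] + innov_scale * eps[i]
    tmean = tseas + resid
    half_dr = site.diurnal_range / 2.0
    tmin = tmean - half_dr
    tmax = tmean + half_dr

    # --- precipitation: two-state Markov occurrence, exponential amounts ---
    pw = site.wet_day_prob
    p11 = site.precip_autocorr
    p01 = pw * (1.0 - p11) / (1.0 - pw)
    u = rng.random(n)
    wet = np.empty(n, dtype=bool)
    wet[0] = u[0] < pw
    for i in range(1, n):
        wet[i] = u[i] < (p11 if wet[i - 1] else p01)
    mean_amount = site.annual_precip / (DAYS_PER_YEAR * pw)
    amounts = rng.exponential(mean_amount, n)
    precip = np.where(wet, amounts, 0.0)

    # --- radiation: sinusoid x lognormal noise, damped on wet days,
    #     rescaled to the target mean, capped by clearness ---
    rseas = _seasonal(site.mean_radiation, site.rad_amplitude, doy, r_peak)
    rseas = np.maximum(rseas, MIN_RADIATION)
    noise = np.exp(rng.standard_normal(n) * RAD_NOISE_SD - 0.5 * RAD_NOISE_SD**2)
    rad = rseas * noise
    rad[wet] *= WET_DAY_RAD_FACTOR
    ra_cap = MAX_CLEARNESS * extraterrestrial_radiation(site.latitude, doy)
    for _ in range(2):  # rescale-then-clip, twice, to hold the mean under the cap
        rad *= site.mean_radiation / rad.mean()
        rad = np.clip(rad, MIN_RADIATION, ra_cap)

    series = WeatherSeries(
        site=site,
        n_years=n_years,
        doy=doy,
        tmin=np.round(tmin, 2),
        tmax=np.round(tmax, 2),
        precip=np.round(precip, 2),
        radiation=np.round(rad, 2),
        seed=seed,
    )
    series.validate()
    return series


# ---------------------------------------------------------------------------
# file format: '#'-prefixed header, then TAB-separated daily rows
# ---------------------------------------------------------------------------

_COLUMNS = "DOY\tTMIN_C\tTMAX_C\tRAIN_MM\tSRAD_MJ"


def write_weather(series: WeatherSeries, path) -> None:
    """Write a series to the documented plain-text format (2 dp)."""
    buf = io.StringIO()
    buf.write(f"# site_id: {series.site.site_id}\n")
    buf.write(f"# country: {series.site.country}\n")
    buf.write(f"# latitude: {series.site.latitude:.4f}\n")
    buf.write(f"# longitude: {series.site.longitude:.4f}\n")
    buf.write(f"# n_years: {series.n_years}\n")
    buf.write(f"# seed: {series.seed}\n")
    buf.write(_COLUMNS + "\n")
    for i in range(len(series)):
        buf.write(
            f"{series.doy[i]:d}\t{series.tmin[i]:.2f}\t{series.tmax[i]:.2f}"
            f"\t{series.precip[i]:.2f}\t{series.radiation[i]:.2f}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


class WeatherFormatError(ValueError):
    pass


def read_weather(path, site: SiteClimate | None = None) -> WeatherSeries:
    """Read a weather file written by :func:`write_weather`.

    If ``site`` is omitted, a minimal :class:`SiteClimate` is
    reconstructed from the header (location only; generator fields take
    defaults).  Malformed headers, non-monotone day numbering and
    physically impossible rows are rejected with the offending line
    number.
    """
    header: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    lineno = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" not in line:
                raise WeatherFormatError(f"line {lineno}: malformed header {line!r}")
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
        elif line.startswith("DOY"):
            if line != _COLUMNS:
                raise WeatherFormatError(f"line {lineno}: unexpected column header")
        else:
            parts = line.split("\t")
            if len(parts) != 5:
                raise WeatherFormatError(f"line {lineno}: expected 5 columns")
            try:
                rows.append((int(parts[0]),) + tuple(float(p) for p in parts[1:]))
            except ValueError as exc:
                raise WeatherFormatError(f"line {lineno}: {exc}") from exc
    for key in ("site_id", "latitude", "n_years"):
        if key not in header:
            raise WeatherFormatError(f"missing header field {key!r}")
    n_years = int(header["n_years"])
    if len(rows) != n_years * DAYS_PER_YEAR:
        raise WeatherFormatError(
            f"{len(rows)} data rows inconsistent with n_years={n_years}"
        )
    arr = np.array(rows)
    doy = arr[:, 0].astype(int)
    expected = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    if not np.array_equal(doy, expected):
        bad = int(np.argmax(doy != expected))
        raise WeatherFormatError(
            f"line {bad + len(lines) - len(rows) + 1}: non-monotone day numbering"
        )
    data_offset = len(lines) - len(rows)
    tmin, tmax, precip, rad = arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4]
    for name, bad_mask in (
        ("tmax < tmin", tmax < tmin),
        ("negative precipitation", precip < 0),
        ("negative radiation", rad < 0),
    ):
        if np.any(bad_mask):
            bad = int(np.argmax(bad_mask))
            raise WeatherFormatError(f"line {bad + data_offset + 1}: {name}")
    if site is None:
        lat = float(header["latitude"])
        country = header.get("country", "UK" if lat >= 0 else "NZ")
        site = SiteClimate(
            site_id=header["site_id"],
            country=country,
            latitude=lat,
            longitude=float(header.get("longitude", 0.0)),
            mean_temp=float((tmin.mean() + tmax.mean()) / 2.0),
            annual_precip=float(precip.sum() / n_years),
            mean_radiation=float(rad.mean()),
        )
    seed = header.get("seed")
    return WeatherSeries(
        site=site,
        n_years=n_years,
        doy=doy,
        tmin=tmin,
        tmax=tmax,
        precip=precip,
        radiation=rad,
        seed=None if seed in (None, "None") else int(seed),
    )
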