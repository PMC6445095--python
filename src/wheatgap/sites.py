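"""Study sites and their climate parameterisation.

Six sites span the major wheat-growing regions of two high-yielding
countries: Edinburgh (ED), Leeds (LE) and Rothamsted (RR) in the UK, and
Gore (GO), Lincoln (LI) and Pukekohe (PU) in New Zealand.  Each site
carries the long-run climate statistics the synthetic weather generator
must reproduce (annual mean temperature, annual precipitation, mean
daily global radiation) plus generator-only parameters (seasonal
amplitudes, wet-day statistics, residual noise) with documented
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SiteClimate",
    "ClimateSummary",
    "builtin_sites",
    "get_site",
    "summarize_climate",
    "SITE_IDS",
]

SITE_IDS = ("ED", "LE", "RR", "GO", "LI", "PU")


@dataclass(frozen=True)
class SiteClimate:
    """A site's location and target climate statistics.

    ``mean_temp`` (deg C), ``annual_precip`` (mm/yr) and
    ``mean_radiation`` (MJ m-2 day-1) are long-run targets the weather
    generator must hit; the remaining fields parameterise how it gets
    there (seasonality, day-to-day persistence, noise).
    """

    site_id: str
    country: str  # "UK" or "NZ"
    latitude: float  # degrees, south negative
    longitude: float  # degrees
    mean_temp: float  # deg C, annual mean
    annual_precip: float  # mm per year
    mean_radiation: float  # MJ m-2 day-1, daily mean
    seasonal_temp_amplitude: float = 6.5  # deg C, half peak-to-trough
    wet_day_prob: float = 0.45  # stationary fraction of wet days
    precip_autocorr: float = 0.65  # P(wet | wet yesterday)
    temp_residual_sd: float = 2.0  # deg C, AR(1) residual SD
    diurnal_range: float = 8.0  # deg C, tmax - tmin
    rad_amplitude: float = 7.0  # MJ m-2 day-1, seasonal half-amplitude

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.mean_radiation <= 0:
            raise ValueError("mean_radiation must be positive")
        if self.annual_precip < 0:
            raise ValueError("annual_precip must be non-negative")
        if not 0.0 < self.wet_day_prob < 1.0:
            raise ValueError("wet_day_prob must be in (0, 1)")
        if self.country == "NZ" and self.latitude >= 0:
            raise ValueError("NZ sites lie in the southern hemisphere")
        if self.country == "UK" and self.latitude <= 0:
            raise ValueError("UK sites lie in the northern hemisphere")

    @property
    def hemisphere(self) -> str:
        return "N" if self.latitude >= 0 else "S"


def _mk(site_id, country, lat, lon, temp, precip, rad, amp, rad_amp):
    return SiteClimate(
        site_id=site_id,
        country=country,
        latitude=lat,
        longitude=lon,
        mean_temp=temp,
        annual_precip=precip,
        mean_radiation=rad,
        seasonal_temp_amplitude=amp,
        rad_amplitude=rad_amp,
    )


# Long-run 1981-2010 climate statistics per site; seasonal amplitudes are
# generator defaults (UK 6.5 degC, NZ 5.0 degC; radiation amplitude about
# 72% of the mean in the UK and 62% in NZ, consistent with the stronger
# relative seasonality of radiation at high northern latitudes).
_BUILTIN = (
    _mk("ED", "UK", 55.94, -3.31, 8.6, 717.0, 8.7, 6.5, 6.3),
    _mk("LE", "UK", 54.30, -1.53, 9.5, 626.0, 8.6, 6.5, 6.2),
    _mk("RR", "UK", 51.80, -0.35, 9.8, 700.0, 9.8, 6.5, 7.1),
    _mk("GO", "NZ", -46.12, 168.89, 9.8, 976.0, 12.4, 5.0, 7.7),
    _mk("LI", "NZ", -43.70, 172.00, 11.6, 596.0, 13.6, 5.0, 8.4),
    _mk("PU", "NZ", -37.21, 174.86, 14.5, 1296.0, 14.0, 5.0, 8.7),
)


def builtin_sites() -> list[SiteClimate]:
    """The six built-in study sites (3 UK, 3 NZ)."""
    return list(_BUILTIN)


def get_site(site_id: str) -> SiteClimate:
    for s in _BUILTIN:
        if s.site_id == site_id:
            return s
    raise KeyError(f"unknown site {site_id!r}; expected one of {SITE_IDS}")


@dataclass(frozen=True)
class ClimateSummary:
    mean_temp: float
    annual_precip: float
    mean_radiation: float


def summarize_climate(arg) -> ClimateSummary:
    """Arithmetic climate means across sites or across a generated series.

    Accepts either an iterable of :class:`SiteClimate` (cross-site means
    of the stated statistics) or a generated ``WeatherSeries`` (means of
    the realised daily weather).
    """
    # duck-type: a WeatherSeries has tmin/tmax/precip arrays
    if hasattr(arg, "tmin") and hasattr(arg, "precip"):
        series = arg
        if len(series.tmin) == 0:
            raise ValueError("empty weather series")
        tmean = (series.tmin + series.tmax) / 2.0
        return ClimateSummary(
            mean_temp=float(tmean.mean()),
            annual_precip=float(series.precip.sum() / series.n_years),
            mean_radiation=float(series.radiation.mean()),
        )
    sites = list(arg)
    if not sites:
        raise ValueError("no sites given")
    n = len(sites)
    return ClimateSummary(
        mean_temp=sum(s.mean_temp for s in sites) / n,
        annual_precip=sum(s.annual_precip for s in sites) / n,
        mean_radiation=sum(s.mean_radiation for s in sites) / n,
    )
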