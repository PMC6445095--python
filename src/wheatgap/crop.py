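"""A Sirius-like daily winter wheat simulator.

Daily biomass is intercepted photosynthetically active radiation (PAR =
0.5 x global radiation, Beer's-law canopy with extinction k) times
radiation-use efficiency, limited by piecewise-linear temperature and
(in rainfed mode) water-stress factors.  Phenology runs on thermal time:
leaves appear every phyllochron ``P_h``; the final leaf number responds
to daylength shortfall via ``P_p`` and to vernalisation; anthesis
follows flag-leaf appearance by a fixed phyllochron interval; grain
filling consumes ``G_f`` degC days or stops when the canopy's green area
is exhausted.  The canopy is a set of leaf cohorts whose green duration
scales with ``(1 + S_G)`` and whose senescence accelerates up to
``W_ss``-fold under full water stress.  Soil water is a 5-cm layer
cascade with uptake governed by ``R_u`` (see :mod:`wheatgap.soil`).

Yields are grams dry matter per m2 internally and reported as t/ha
(x 0.01), grain at dry-matter basis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .cultivar import CultivarParams
from .sites import SiteClimate
from .soil import SoilProfile, lincoln_270, rothamsted_210
from .weather import DAYS_PER_YEAR, WeatherSeries

__all__ = [
    "ModelConstants",
    "Management",
    "SeasonResult",
    "YieldSeries",
    "SeasonError",
    "thermal_time",
    "intercepted_par",
    "water_stress_factor",
    "vernalisation_increment",
    "final_leaf_number",
    "flowering_stress_multiplier",
    "default_sowing_doy",
    "default_soil",
    "simulate_season",
    "simulate_years",
]

#: typical local sowing dates: 20 October (UK), 20 April (NZ)
SOWING_DOY = {"UK": 293, "NZ": 110}


@dataclass(frozen=True)
class ModelConstants:
    """Fixed physiological and numerical constants of the simulator.

    These are cultivar-independent.  The ensemble is pinned by the
    reference-cultivar calibration bands (see docs/methods.md) rather
    than by any single literature value.
    """

    t_base: float = 0.0           # degC, thermal-time base
    rue: float = 3.70             # g DM per MJ intercepted PAR
    par_fraction: float = 0.5     # PAR / global radiation
    k_ext: float = 0.45           # canopy extinction coefficient
    base_fln: float = 8.0         # leaves, minimum mainstem final leaf number
    min_fln: float = 6.0
    max_fln: float = 22.0
    dl_cap: float = 20.0          # h; daylength above this adds no leaves
    vern_tmin: float = -1.0       # degC, vernalisation window
    vern_tmax: float = 7.5
    vern_days: float = 33.0       # effective days to full vernalisation
    vern_penalty: float = 8.0     # extra leaves per unfulfilled vern fraction
    anthesis_phyllochrons: float = 2.0  # flag-leaf ligule -> anthesis
    emergence_tt: float = 150.0   # degC day, sowing -> emergence
    expand_phyllochrons: float = 1.2    # leaf expansion duration
    life_base: float = 2.0        # phyllochrons, green duration intercept
    life_slope: float = 3.5       # phyllochrons, extra duration for top leaves
    sen_span_phyllochrons: float = 1.5  # linear senescence span
    shoot_density: float = 250.0  # effective shoots m-2 (canopy scale)
    rank_decay: float = 0.19      # lower leaves smaller by exp(-decay*rank gap)
    ag_frac: float = 0.90         # above-ground share of pre-anthesis growth
    stem_frac: float = 0.60       # stem share of above-ground at anthesis
    reserve_frac: float = 0.25    # labile share of stem biomass
    transloc_rate: float = 0.025  # reserve pool fraction translocated per day
    pt_alpha: float = 1.26        # Priestley-Taylor coefficient
    rn_frac: float = 0.63         # net/global radiation for PET
    soil_evap_coef: float = 0.5
    root_growth: float = 1.2      # cm per day
    green_lai_min: float = 0.15   # grain fill stops below this green LAI
    tf_opt_lo: float = 10.0       # degC, growth temperature response
    tf_opt_hi: float = 20.0
    tf_max: float = 37.0
    flower_window_tt: float = 100.0  # degC day around anthesis
    heat_threshold: float = 27.0  # degC tmax
    heat_sens: float = 0.02       # fertility loss per degC above threshold
    drought_threshold: float = 0.4
    drought_sens: float = 0.10
    fert_floor: float = 0.3
    max_season_days: int = 450
    #: weight on tmax in the daytime-mean temperature driving the
    #: grain-fill clock (grain growth tracks daytime canopy temperature)
    fill_day_weight: float = 0.75
    #: grain sink capacity as a multiple of above-ground biomass at
    #: anthesis (kernel number is set around anthesis)
    grain_sink_ratio: float = 0.95
    #: flag-leaf area / tillering trade-off: canopy scale follows
    #: (A_max / amax_ref) ** amax_exponent
    amax_ref: float = 0.007
    amax_exponent: float = 0.5
    #: determinate kernel growth: past this post-anthesis thermal time
    #: the assimilate-to-grain conversion declines linearly ...
    fill_decline_start: float = 500.0  # degC day
    fill_decline_rate: float = 0.00125  # per degC day
    fill_conv_floor: float = 0.5

    def to_vector(self) -> np.ndarray:
        v = np.zeros(K.N_CONSTANTS)
        v[K.C_T_BASE] = self.t_base
        v[K.C_RUE] = self.rue
        v[K.C_PAR_FRAC] = self.par_fraction
        v[K.C_K_EXT] = self.k_ext
        v[K.C_BASE_FLN] = self.base_fln
        v[K.C_MIN_FLN] = self.min_fln
        v[K.C_MAX_FLN] = self.max_fln
        v[K.C_DL_CAP] = self.dl_cap
        v[K.C_VERN_TMIN] = self.vern_tmin
        v[K.C_VERN_TMAX] = self.vern_tmax
        v[K.C_VERN_DAYS] = self.vern_days
        v[K.C_VERN_PENALTY] = self.vern_penalty
        v[K.C_ANTH_PHYLL] = self.anthesis_phyllochrons
        v[K.C_EMERGENCE_TT] = self.emergence_tt
        v[K.C_EXPAND_PHYLL] = self.expand_phyllochrons
        v[K.C_LIFE_BASE] = self.life_base
        v[K.C_LIFE_SLOPE] = self.life_slope
        v[K.C_SEN_SPAN_PHYLL] = self.sen_span_phyllochrons
        v[K.C_SHOOT_DENSITY] = self.shoot_density
        v[K.C_RANK_DECAY] = self.rank_decay
        v[K.C_AG_FRAC] = self.ag_frac
        v[K.C_STEM_FRAC] = self.stem_frac
        v[K.C_RESERVE_FRAC] = self.reserve_frac
        v[K.C_TRANSLOC_RATE] = self.transloc_rate
        v[K.C_PT_ALPHA] = self.pt_alpha
        v[K.C_RN_FRAC] = self.rn_frac
        v[K.C_SOIL_EVAP_COEF] = self.soil_evap_coef
        v[K.C_ROOT_GROWTH] = self.root_growth
        v[K.C_GREEN_LAI_MIN] = self.green_lai_min
        v[K.C_TF_OPT_LO] = self.tf_opt_lo
        v[K.C_TF_OPT_HI] = self.tf_opt_hi
        v[K.C_TF_MAX] = self.tf_max
        v[K.C_FLOWER_WINDOW_TT] = self.flower_window_tt
        v[K.C_HEAT_THRESHOLD] = self.heat_threshold
        v[K.C_HEAT_SENS] = self.heat_sens
        v[K.C_DROUGHT_THRESHOLD] = self.drought_threshold
        v[K.C_DROUGHT_SENS] = self.drought_sens
        v[K.C_FERT_FLOOR] = self.fert_floor
        v[K.C_MAX_SEASON_DAYS] = float(self.max_season_days)
        v[K.C_FILL_DAY_WEIGHT] = self.fill_day_weight
        v[K.C_GRAIN_SINK_RATIO] = self.grain_sink_ratio
        v[K.C_AMAX_REF] = self.amax_ref
        v[K.C_AMAX_EXPONENT] = self.amax_exponent
        v[K.C_FILL_DECLINE_START] = self.fill_decline_start
        v[K.C_FILL_DECLINE_RATE] = self.fill_decline_rate
        v[K.C_FILL_CONV_FLOOR] = self.fill_conv_floor
        return v

    def replace(self, **kw) -> "ModelConstants":
        return dataclasses.replace(self, **kw)


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class Management:
    sowing_doy: int | None = None  # None -> country default
    mode: str = "water_limited"  # or "potential"
    lue_multiplier: float = 1.00  # 1.10 for ideotype design runs
    flowering_stress_enabled: bool = True

    def __post_init__(self):
        if self.mode not in ("water_limited", "potential"):
            raise ValueError(f"mode must be water_limited|potential, got {self.mode!r}")
        if self.lue_multiplier <= 0:
            raise ValueError("lue_multiplier must be positive")


@dataclass(frozen=True)
class SeasonResult:
    grain_yield: float  # t/ha, dry matter
    total_biomass: float  # t/ha above-ground
    HI: float
    anthesis_doy: int
    maturity_doy: int
    anthesis_das: int  # days after sowing
    maturity_das: int
    grainfill_days: int
    cum_intercepted_radiation: float  # MJ m-2, global
    cum_incident_radiation: float  # MJ m-2 over emergence..maturity
    max_LAI: float
    water_stress_days: int
    final_leaf_number: float
    grainfill_tt: float  # degC day consumed, min(G_f, available)
    anthesis_biomass: float  # t/ha above-ground at anthesis
    season_tt: float  # diagnostic: sum of daily thermal time
    ag_increment_sum: float  # diagnostic: mass-balance check, g m-2
    water_balance_residual: float  # diagnostic, mm


@dataclass
class YieldSeries:
    results: list
    mean_yield: float
    cv_yield: float  # sample SD / mean
    mean_HI: float

    @classmethod
    def from_results(cls, results) -> "YieldSeries":
        if not results:
            raise ValueError("empty season list")
        y = np.array([r.grain_yield for r in results])
        mean = float(y.mean())
        sd = float(y.std(ddof=1)) if len(y) > 1 else 0.0
        cv = sd / mean if mean > 0 else np.inf
        return cls(
            results=list(results),
            mean_yield=mean,
            cv_yield=cv,
            mean_HI=float(np.mean([r.HI for r in results])),
        )

    @property
    def yields(self) -> np.ndarray:
        return np.array([r.grain_yield for r in self.results])

    @property
    def mean_grainfill_days(self) -> float:
        return float(np.mean([r.grainfill_days for r in self.results]))


class SeasonError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# elementary operations (validated wrappers over the kernel formulas)
# ---------------------------------------------------------------------------

def thermal_time(tmin: float, tmax: float, t_base: float = 0.0) -> float:
    """Daily thermal time max(0, (tmin+tmax)/2 - t_base) in degC day."""
    if tmax < tmin:
        raise ValueError(f"tmax {tmax} < tmin {tmin}")
    return K.thermal_time_day(float(tmin), float(tmax), float(t_base))


def intercepted_par(lai: float, global_radiation: float, k: float = 0.45,
                    par_fraction: float = 0.5) -> float:
    """Intercepted PAR (MJ m-2 day-1): 0.5*Rs*(1 - exp(-k*LAI))."""
    if lai < 0:
        raise ValueError("LAI must be >= 0")
    return par_fraction * global_radiation * K.intercepted_fraction(float(lai), float(k))


def water_stress_factor(actual_transpiration: float, demand: float,
                        mode: str = "water_limited") -> float:
    """Supply/demand ratio in [0, 1]; 1 when demand is zero or irrigated."""
    if demand < 0:
        raise ValueError("demand must be >= 0")
    if mode == "potential" or demand == 0:
        return 1.0
    return float(min(1.0, max(0.0, actual_transpiration / demand)))


def vernalisation_increment(tmin: float, tmax: float,
                            consts: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Daily vernalisation progress: 1/vern_days inside the window, else 0."""
    tmean = 0.5 * (tmin + tmax)
    if consts.vern_tmin <= tmean <= consts.vern_tmax:
        return 1.0 / consts.vern_days
    return 0.0


def final_leaf_number(P_p: float, vern_progress: float, daylength: float,
                      consts: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Final leaf number from daylength shortfall and vernalisation state.

    FLN = base + P_p * max(0, dl_cap - daylength)
         + vern_penalty * (1 - vern_progress), clamped to [min, max];
    monotone non-increasing in daylength.
    """
    shortfall = max(0.0, consts.dl_cap - daylength)
    fln = (consts.base_fln + P_p * shortfall
           + consts.vern_penalty * (1.0 - min(1.0, vern_progress)))
    return float(min(consts.max_fln, max(consts.min_fln, fln)))


def flowering_stress_multiplier(tmax: float, water_stress_factor: float = 1.0,
                                mode: str = "water_limited",
                                consts: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Daily grain-number/size multiplier for heat or drought at flowering.

    Applied multiplicatively on days falling inside the thermal window
    around anthesis; 1 on benign days, < 1 under extreme heat
    (tmax above the threshold) or severe drought.  Defaults are chosen
    so baseline UK/NZ weather shows a < 1% mean yield effect.
    """
    f = 1.0
    if tmax > consts.heat_threshold:
        f *= max(0.0, 1.0 - consts.heat_sens * (tmax - consts.heat_threshold))
    if mode == "water_limited" and water_stress_factor < consts.drought_threshold:
        f *= 1.0 - consts.drought_sens * (
            (consts.drought_threshold - water_stress_factor)
            / consts.drought_threshold
        )
    return max(consts.fert_floor, f)


def default_sowing_doy(site: SiteClimate) -> int:
    return SOWING_DOY[site.country]


def default_soil(site: SiteClimate) -> SoilProfile:
    return rothamsted_210() if site.country == "UK" else lincoln_270()


# ---------------------------------------------------------------------------
# season / multi-year drivers
# ---------------------------------------------------------------------------

def _traits_vector(cv: CultivarParams) -> np.ndarray:
    return np.array([cv.P_h, cv.P_p, cv.G_f, cv.A_max, cv.S_G, cv.R_u, cv.W_ss])


def simulate_season(
    cultivar: CultivarParams,
    series: WeatherSeries,
    soil: SoilProfile | None = None,
    management: Management | None = None,
    start_year: int = 0,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> SeasonResult:
    """Run one season sown in calendar year ``start_year`` of the series.

    Deterministic for fixed inputs.  Raises :class:`SeasonError` if the
    weather runs out before maturity (a season needs up to ~450 days
    past sowing, so the series must extend into the following year).
    """
    management = management or Management()
    soil = soil if soil is not None else default_soil(series.site)
    sow_doy = management.sowing_doy or default_sowing_doy(series.site)
    sow_idx = start_year * DAYS_PER_YEAR + (sow_doy - 1)
    if sow_idx >= len(series):
        raise SeasonError(f"sowing day (year {start_year}) beyond series end")
    if len(series) - sow_idx < 400:
        raise SeasonError(
            f"season incomplete: only {len(series) - sow_idx} days of weather "
            f"after sowing in year {start_year} (need ~400)"
        )
    out = K.simulate_season_kernel(
        series.tmin, series.tmax, series.precip, series.radiation,
        series.doy.astype(np.float64),
        sow_idx,
        float(series.site.latitude),
        _traits_vector(cultivar),
        float(management.lue_multiplier),
        1 if management.mode == "water_limited" else 0,
        1 if management.flowering_stress_enabled else 0,
        constants.to_vector(),
        soil.awc_per_layer, soil.lambda_rel,
    )
    if out[0] == K.STATUS_INCOMPLETE:
        raise SeasonError(f"season incomplete: crop did not mature "
                          f"(sown year {start_year}, {cultivar.name})")
    sow_doy0 = sow_doy
    anth_doy = (sow_doy0 - 1 + int(out[4])) % DAYS_PER_YEAR + 1
    mat_doy = (sow_doy0 - 1 + int(out[5])) % DAYS_PER_YEAR + 1
    return SeasonResult(
        grain_yield=float(out[1]) * 0.01,
        total_biomass=float(out[2]) * 0.01,
        HI=float(out[3]),
        anthesis_doy=anth_doy,
        maturity_doy=mat_doy,
        anthesis_das=int(out[4]),
        maturity_das=int(out[5]),
        grainfill_days=int(out[6]),
        cum_intercepted_radiation=float(out[7]),
        cum_incident_radiation=float(out[15]),
        max_LAI=float(out[8]),
        water_stress_days=int(out[9]),
        final_leaf_number=float(out[13]),
        grainfill_tt=float(out[14]),
        anthesis_biomass=float(out[16]) * 0.01,
        season_tt=float(out[10]),
        ag_increment_sum=float(out[11]),
        water_balance_residual=float(out[12]),
    )


def simulate_years(
    cultivar: CultivarParams,
    series: WeatherSeries,
    soil: SoilProfile | None = None,
    management: Management | None = None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> YieldSeries:
    """One season per sowing year of the series.

    Both hemispheres' seasons cross a calendar-year boundary (UK sown
    late October, NZ sown late April maturing in January), so an
    ``n``-year series yields ``n - 1`` complete seasons.
    """
    if series.n_years < 2:
        raise ValueError("need a series of at least 2 years")
    results = []
    for year in range(series.n_years - 1):
        try:
            results.append(
                simulate_season(cultivar, series, soil, management,
                                start_year=year, constants=constants)
            )
        except SeasonError as exc:
            raise SeasonError(f"year {year}: {exc}") from exc
    return YieldSeries.from_results(results)
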