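"""Yield-gap estimation: ideotype potential vs. reference cultivar.

The yield gap at a site is Y_G = Y_GP - Y_M, where Y_GP is the
'genetic' yield potential of an ideotype optimized for the local
climate (simulated with a 10% light-use-efficiency uplift) and Y_M is
the management-optimal yield of the locally adapted reference cultivar
(no uplift).  Gaps are also expressed as a percentage of Y_GP.  Sites
aggregate to unweighted country means with a between-site sample
variance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crop import Management, ModelConstants, DEFAULT_CONSTANTS, YieldSeries, simulate_years
from .cultivar import CLAIRE, TRAIT_NAMES, CultivarParams
from .easa import EASAConfig, design_ideotype
from .sites import SiteClimate, builtin_sites, summarize_climate
from .weather import generate_weather

__all__ = [
    "YieldGapReport",
    "CountryAggregate",
    "yield_gap",
    "gap_percent",
    "simulate_reference",
    "country_aggregate",
    "climate_contrasts",
    "run_full_analysis",
    "reports_to_frame",
]


def yield_gap(y_gp: float, y_m: float) -> tuple[float, float]:
    """(Y_G, Y_G as % of Y_GP) from potential and reference yields.

    Exact arithmetic; rounding (1 decimal t/ha, integer %) happens only
    at the report layer.
    """
    if y_gp <= 0:
        raise ValueError(f"yield potential must be positive, got {y_gp}")
    y_g = y_gp - y_m
    return y_g, 100.0 * y_g / y_gp


def gap_percent(y_g: float, y_gp: float) -> float:
    """Gap as % of potential, directly from a gap and a potential yield."""
    if y_gp <= 0:
        raise ValueError("yield potential must be positive")
    return 100.0 * y_g / y_gp


@dataclass(frozen=True)
class YieldGapReport:
    site_id: str
    country: str
    mode: str
    y_m: float   # t/ha, reference cultivar mean
    y_gp: float  # t/ha, ideotype mean
    y_g: float   # t/ha
    y_g_pct: float  # % of y_gp
    ideotype: CultivarParams
    reference_cv: float  # inter-annual CV of the reference run
    ideotype_cv: float
    ideotype_hi: float
    seed: int

    @classmethod
    def build(cls, site, mode, y_m, y_gp, ideotype, reference_cv,
              ideotype_cv, ideotype_hi, seed) -> "YieldGapReport":
        y_g, pct = yield_gap(y_gp, y_m)
        return cls(site.site_id, site.country, mode, y_m, y_gp, y_g, pct,
                   ideotype, reference_cv, ideotype_cv, ideotype_hi, seed)


@dataclass(frozen=True)
class CountryAggregate:
    country: str
    mode: str
    n_sites: int
    y_m: float
    y_gp: float
    y_g: float
    y_g_pct: float  # 100 * mean gap / mean potential
    between_site_variance: float  # sample variance of site y_gp means


def simulate_reference(
    site: SiteClimate,
    mode: str = "potential",
    seed: int = 0,
    n_years: int = 100,
    cultivar: CultivarParams = CLAIRE,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    weather=None,
) -> YieldSeries:
    """Y_M: the reference cultivar under optimal management (LUE x1.00)."""
    if weather is None:
        weather = generate_weather(site, n_years + 1, seed)
    management = Management(mode=mode, lue_multiplier=1.00)
    return simulate_years(cultivar, weather, management=management,
                          constants=constants)


def country_aggregate(reports: list[YieldGapReport]) -> CountryAggregate:
    """Unweighted country means and between-site sample variance."""
    if len(reports) < 2:
        raise ValueError("need at least 2 site reports to aggregate")
    countries = {r.country for r in reports}
    modes = {r.mode for r in reports}
    if len(countries) != 1 or len(modes) != 1:
        raise ValueError(f"mixed countries/modes in aggregate: {countries}, {modes}")
    y_m = float(np.mean([r.y_m for r in reports]))
    y_gp = float(np.mean([r.y_gp for r in reports]))
    y_g = y_gp - y_m
    return CountryAggregate(
        country=countries.pop(),
        mode=modes.pop(),
        n_sites=len(reports),
        y_m=y_m,
        y_gp=y_gp,
        y_g=y_g,
        y_g_pct=100.0 * y_g / y_gp,
        between_site_variance=float(np.var([r.y_gp for r in reports], ddof=1)),
    )


def climate_contrasts(sites=None) -> dict:
    """Country climate contrasts from the site table.

    Reports the NZ-UK temperature difference, NZ/UK precipitation and
    radiation ratios (as % excess) and the photothermal quotient
    (radiation/temperature) contrast computed both as the ratio of
    country means and as the mean of site-level quotients (the two
    orders of averaging differ; both are reported).
    """
    sites = list(sites) if sites is not None else builtin_sites()
    uk = [s for s in sites if s.country == "UK"]
    nz = [s for s in sites if s.country == "NZ"]
    if not uk or not nz:
        raise ValueError("need sites from both countries")
    uk_sum = summarize_climate(uk)
    nz_sum = summarize_climate(nz)
    ptq_uk_sites = float(np.mean([s.mean_radiation / s.mean_temp for s in uk]))
    ptq_nz_sites = float(np.mean([s.mean_radiation / s.mean_temp for s in nz]))
    return {
        "uk_mean_temp": uk_sum.mean_temp,
        "uk_precip": uk_sum.annual_precip,
        "uk_radiation": uk_sum.mean_radiation,
        "nz_mean_temp": nz_sum.mean_temp,
        "nz_precip": nz_sum.annual_precip,
        "nz_radiation": nz_sum.mean_radiation,
        "delta_temp": nz_sum.mean_temp - uk_sum.mean_temp,
        "precip_excess_pct": 100.0 * (nz_sum.annual_precip / uk_sum.annual_precip - 1.0),
        "radiation_excess_pct": 100.0 * (nz_sum.mean_radiation / uk_sum.mean_radiation - 1.0),
        "ptq_excess_pct_of_means": 100.0 * (
            (nz_sum.mean_radiation / nz_sum.mean_temp)
            / (uk_sum.mean_radiation / uk_sum.mean_temp) - 1.0
        ),
        "ptq_excess_pct_of_sites": 100.0 * (ptq_nz_sites / ptq_uk_sites - 1.0),
    }


def reports_to_frame(reports: list[YieldGapReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "site": r.site_id, "country": r.country, "mode": r.mode,
            "y_m": round(r.y_m, 1), "y_gp": round(r.y_gp, 1),
            "y_g": round(r.y_g, 1), "y_g_pct": round(r.y_g_pct),
        }
        for t in TRAIT_NAMES:
            row[t] = getattr(r.ideotype, t)
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(
    seed: int = 0,
    n_years: int = 100,
    max_generations: int = 200,
    stall_generations: int = 15,
    n_parents: int = 8,
    sites=None,
    modes=("water_limited", "potential"),
    constants: ModelConstants = DEFAULT_CONSTANTS,
    progress=None,
):
    """All sites x modes: reference runs, ideotype design, gap reports.

    Returns ``(reports, aggregates, manifest)``.  Fully deterministic
    for a fixed seed: per-stage seeds derive from ``seed`` via a
    SeedSequence, and weather is shared between the reference and the
    ideotype candidates at each site/mode.
    """
    sites = list(sites) if sites is not None else builtin_sites()
    reports = []
    manifest_runs = []
    for site in sites:
        # one weather realisation per site, shared across modes and candidates
        site_tag = int.from_bytes(
            hashlib.sha256(site.site_id.encode()).digest()[:4], "little"
        )
        wseed = int(np.random.SeedSequence([seed, site_tag])
                    .generate_state(1)[0] % (2**31))
        weather = generate_weather(site, n_years + 1, wseed)
        for mode in modes:
            if progress:
                progress(f"{site.site_id} {mode}")
            ref = simulate_reference(site, mode=mode, weather=weather,
                                     constants=constants)
            cfg = EASAConfig(
                mode=mode, seed=wseed + 1, n_years=n_years,
                max_generations=max_generations,
                stall_generations=stall_generations, n_parents=n_parents,
            )
            opt = design_ideotype(site, mode, cfg, weather=weather,
                                  constants=constants)
            ideotype = opt.best_genome.as_cultivar(
                CLAIRE, name=f"I_{'W' if mode == 'water_limited' else 'P'}_{site.site_id}"
            )
            rep = YieldGapReport.build(
                site, mode, ref.mean_yield, opt.best_fitness.mean_yield,
                ideotype, ref.cv_yield, opt.best_fitness.cv_yield,
                opt.best_fitness.mean_HI, wseed,
            )
            reports.append(rep)
            manifest_runs.append({
                "site": site.site_id, "mode": mode, "weather_seed": wseed,
                "easa_seed": cfg.seed, "n_years": n_years,
                "y_m": rep.y_m, "y_gp": rep.y_gp,
                "n_evaluations": opt.n_evaluations,
            })
    aggregates = []
    for country in ("UK", "NZ"):
        for mode in modes:
            group = [r for r in reports
                     if r.country == country and r.mode == mode]
            if len(group) >= 2:
                aggregates.append(country_aggregate(group))
    table = reports_to_frame(reports)
    digest = hashlib.sha256(
        table.to_csv(index=False).encode()
    ).hexdigest()
    manifest = {
        "seed": seed,
        "n_years": n_years,
        "max_generations": max_generations,
        "n_parents": n_parents,
        "runs": manifest_runs,
        "table_sha256": digest,
    }
    return reports, aggregates, manifest
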