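"""The daily winter-wheat simulator: elementary operations, phenology,
canopy, growth, grain fill, and whole-season invariants."""

import numpy as np
import pytest

import wheatgap as wg
from wheatgap.crop import (DEFAULT_CONSTANTS, Management, SeasonError,
                           final_leaf_number, flowering_stress_multiplier,
                           intercepted_par, simulate_season, simulate_years,
                           thermal_time, vernalisation_increment,
                           water_stress_factor)
from wheatgap.weather import WeatherSeries
from conftest import random_cultivar


def constant_weather(site, n_years, tmin, tmax, precip=2.0, rad=12.0):
    n = n_years * 365
    return WeatherSeries(
        site=site, n_years=n_years,
        doy=np.tile(np.arange(1, 366), n_years),
        tmin=np.full(n, float(tmin)), tmax=np.full(n, float(tmax)),
        precip=np.full(n, float(precip)), radiation=np.full(n, float(rad)),
        seed=None,
    )


class TestElementaryOps:
    @pytest.mark.parametrize("tmin,tmax,base,want", [
        (10, 20, 0, 15.0),
        (-5, 1, 0, 0.0),
        (4, 12, 2, 6.0),
    ])
    def test_thermal_time(self, tmin, tmax, base, want):
        assert thermal_time(tmin, tmax, base) == pytest.approx(want)

    def test_thermal_time_rejects_inverted_range(self):
        with pytest.raises(ValueError):
            thermal_time(10, 5)

    def test_season_thermal_time_matches_bruteforce(self, rr_weather):
        r = simulate_season(wg.CLAIRE, rr_weather,
                            management=Management(mode="potential"))
        sow = 292  # doy 293, year 0
        oracle = sum(
            thermal_time(rr_weather.tmin[t], rr_weather.tmax[t])
            for t in range(sow, sow + r.maturity_das + 1)
        )
        assert r.season_tt == pytest.approx(oracle, abs=1e-9)

    def test_intercepted_par(self):
        assert intercepted_par(0.0, 20.0) == 0.0
        # asymptote: half the global radiation
        assert intercepted_par(50.0, 20.0) == pytest.approx(10.0, abs=1e-6)
        assert intercepted_par(6.0, 20.0, k=0.45) == pytest.approx(9.328, abs=1e-3)

    def test_water_stress_factor(self):
        assert water_stress_factor(0.0, 0.0) == 1.0
        assert water_stress_factor(3.0, 3.0) == 1.0
        assert water_stress_factor(0.0, 5.0) == 0.0
        assert water_stress_factor(1.0, 4.0) == pytest.approx(0.25)
        assert water_stress_factor(0.0, 5.0, mode="potential") == 1.0

    def test_vernalisation_window(self):
        # 50 effective days saturate the default 33-day requirement
        prog = min(1.0, sum(vernalisation_increment(2.0, 8.0) for _ in range(50)))
        assert prog == 1.0
        # hot days contribute nothing
        assert vernalisation_increment(25.0, 35.0) == 0.0
        mixed = [(2, 8), (25, 35), (0, 6), (15, 25), (-4, 2)]
        oracle = sum(1.0 / DEFAULT_CONSTANTS.vern_days
                     for lo, hi in mixed
                     if DEFAULT_CONSTANTS.vern_tmin
                     <= (lo + hi) / 2 <= DEFAULT_CONSTANTS.vern_tmax)
        assert sum(vernalisation_increment(lo, hi) for lo, hi in mixed) \
            == pytest.approx(oracle)

    def test_final_leaf_number_daylength_response(self):
        base = DEFAULT_CONSTANTS.base_fln
        cap = DEFAULT_CONSTANTS.dl_cap
        # at the daylength cap with full vernalisation: base leaves only
        assert final_leaf_number(0.565, 1.0, cap) == pytest.approx(base)
        # P_p = 0: independent of daylength
        assert final_leaf_number(0.0, 1.0, 9.0) == final_leaf_number(0.0, 1.0, 16.0)
        # monotone non-increasing in daylength
        lengths = np.linspace(8.0, 20.0, 25)
        flns = [final_leaf_number(0.565, 1.0, d) for d in lengths]
        assert all(a >= b - 1e-12 for a, b in zip(flns, flns[1:]))
        # unfulfilled vernalisation adds leaves
        assert final_leaf_number(0.565, 0.5, 12.0) > final_leaf_number(0.565, 1.0, 12.0)

    def test_flowering_stress_multiplier(self):
        assert flowering_stress_multiplier(22.0, 1.0) == 1.0
        assert flowering_stress_multiplier(38.0, 1.0) < 1.0
        assert flowering_stress_multiplier(24.0, 0.1) < 1.0
        assert flowering_stress_multiplier(45.0, 0.0) \
            >= DEFAULT_CONSTANTS.fert_floor


class TestSeason:
    def test_deterministic(self, rr_weather):
        a = simulate_season(wg.CLAIRE, rr_weather)
        b = simulate_season(wg.CLAIRE, rr_weather)
        assert a == b

    def test_phenology_ordering_and_invariants(self, claire_rr_potential):
        for r in claire_rr_potential.results:
            assert 0 < r.anthesis_das < r.maturity_das
            assert r.grainfill_days == r.maturity_das - r.anthesis_das
            assert r.HI == pytest.approx(r.grain_yield / r.total_biomass, rel=1e-9)
            assert r.grain_yield <= r.total_biomass
            assert r.cum_intercepted_radiation <= r.cum_incident_radiation
            assert r.max_LAI >= 0
            assert r.grainfill_tt <= wg.CLAIRE.G_f + 1e-9

    def test_mass_balance(self, claire_rr_potential):
        for r in claire_rr_potential.results:
            assert r.ag_increment_sum == pytest.approx(
                r.total_biomass * 100.0, rel=1e-9)

    def test_water_balance_closure(self, rr_weather):
        for year in range(5):
            r = simulate_season(wg.CLAIRE, rr_weather, start_year=year,
                                management=Management(mode="water_limited"))
            assert abs(r.water_balance_residual) < 1e-6

    def test_potential_at_least_water_limited(self, rr_weather):
        for year in range(5):
            p = simulate_season(wg.CLAIRE, rr_weather, start_year=year,
                                management=Management(mode="potential"))
            w = simulate_season(wg.CLAIRE, rr_weather, start_year=year,
                                management=Management(mode="water_limited"))
            assert p.grain_yield >= w.grain_yield - 1e-12

    def test_zero_radiation_gives_no_yield(self):
        site = wg.get_site("RR")
        series = wg.generate_weather(site, 3, 4)
        dark = WeatherSeries(site=site, n_years=3, doy=series.doy,
                             tmin=series.tmin, tmax=series.tmax,
                             precip=series.precip,
                             radiation=np.full(len(series), 0.01))
        r = simulate_season(wg.CLAIRE, dark, management=Management(mode="potential"))
        assert r.grain_yield < 0.05

    def test_lue_multiplier_bounded_biomass_response(self, rr_weather):
        base = simulate_season(wg.CLAIRE, rr_weather,
                               management=Management(mode="potential"))
        up = simulate_season(wg.CLAIRE, rr_weather,
                             management=Management(mode="potential",
                                                   lue_multiplier=1.10))
        ratio = up.total_biomass / base.total_biomass
        assert 1.0 < ratio <= 1.10 + 1e-9

    def test_grainfill_duration_at_constant_temperature(self):
        """G_f = 650 degC day at a constant 17.1 degC consumes ~38 days."""
        site = wg.get_site("RR")
        w = constant_weather(site, 3, 17.1, 17.1, rad=14.0)
        r = simulate_season(wg.CLAIRE, w, management=Management(mode="potential"))
        assert r.grainfill_days == pytest.approx(650.0 / 17.1, abs=1.0)

    def test_longer_grainfill_never_reduces_yield(self, rr_weather):
        yields = []
        for gf in (500.0, 650.0, 800.0, 900.0):
            cv = wg.CLAIRE.replace(G_f=gf)
            r = simulate_season(cv, rr_weather,
                                management=Management(mode="potential"))
            yields.append(r.grain_yield)
        assert all(a <= b + 1e-9 for a, b in zip(yields, yields[1:]))

    def test_stay_green_extends_interception(self, rr_weather):
        lo = simulate_season(wg.CLAIRE.replace(S_G=0.5), rr_weather,
                             management=Management(mode="potential"))
        hi = simulate_season(wg.CLAIRE.replace(S_G=1.13), rr_weather,
                             management=Management(mode="potential"))
        assert hi.cum_intercepted_radiation > lo.cum_intercepted_radiation

    def test_wss_inert_without_water_stress(self, rr_weather):
        a = simulate_season(wg.CLAIRE.replace(W_ss=1.0), rr_weather,
                            management=Management(mode="potential"))
        b = simulate_season(wg.CLAIRE.replace(W_ss=1.7), rr_weather,
                            management=Management(mode="potential"))
        assert a.grain_yield == b.grain_yield

    def test_flowering_stress_toggle_negligible_on_baseline(self, rr_weather):
        on = simulate_years(wg.CLAIRE, rr_weather,
                            management=Management(mode="water_limited",
                                                  flowering_stress_enabled=True))
        off = simulate_years(wg.CLAIRE, rr_weather,
                             management=Management(mode="water_limited",
                                                   flowering_stress_enabled=False))
        assert abs(on.mean_yield - off.mean_yield) / off.mean_yield < 0.01

    def test_extreme_flowering_heat_reduces_yield(self, rr_weather):
        hot = WeatherSeries(
            site=rr_weather.site, n_years=rr_weather.n_years, doy=rr_weather.doy,
            tmin=rr_weather.tmin,
            tmax=np.where((rr_weather.doy > 160) & (rr_weather.doy < 195),
                          38.0, rr_weather.tmax),
            precip=rr_weather.precip, radiation=rr_weather.radiation)
        base = simulate_season(wg.CLAIRE, rr_weather,
                               management=Management(mode="potential"))
        heat = simulate_season(wg.CLAIRE, hot,
                               management=Management(mode="potential"))
        assert heat.grain_yield < base.grain_yield

    def test_season_incomplete_raises(self):
        short = wg.generate_weather(wg.get_site("RR"), 1, 3)
        with pytest.raises(SeasonError, match="incomplete"):
            simulate_season(wg.CLAIRE, short)


class TestYears:
    def test_mean_and_cv(self, claire_rr_potential):
        ys = claire_rr_potential
        assert len(ys.results) == 10  # 11 calendar years -> 10 seasons
        assert ys.mean_yield == pytest.approx(float(ys.yields.mean()))
        assert ys.cv_yield == pytest.approx(
            float(ys.yields.std(ddof=1) / ys.yields.mean()))
        assert ys.cv_yield < 0.10  # reference cultivar is stable

    def test_identical_years_have_zero_cv(self):
        site = wg.get_site("RR")
        w = constant_weather(site, 4, 6.0, 14.0, rad=10.0)
        ys = simulate_years(wg.CLAIRE, w, management=Management(mode="potential"))
        assert ys.cv_yield == pytest.approx(0.0, abs=1e-12)

    def test_reference_yield_in_calibration_range(self, claire_rr_potential):
        assert 9.0 < claire_rr_potential.mean_yield < 12.5

    def test_needs_two_years(self):
        w = wg.generate_weather(wg.get_site("RR"), 1, 3)
        with pytest.raises(ValueError):
            simulate_years(wg.CLAIRE, w)

    def test_failure_reports_year_index(self):
        site = wg.get_site("RR")
        # 2 years is enough for year 0 only; asking implicitly for more fails
        w = constant_weather(site, 2, -10.0, -2.0, rad=5.0)  # never grows
        with pytest.raises(SeasonError, match="year 0"):
            simulate_years(wg.CLAIRE, w)


class TestRandomCultivars:
    def test_ordering_and_hi_cap_over_random_draws(self, weather):
        """potential >= water-limited and HI <= 0.64 across 200 draws."""
        rng = np.random.default_rng(7)
        series = {"RR": weather("RR", 9, 21), "LI": weather("LI", 9, 22)}
        for i in range(200):
            cv = random_cultivar(rng)
            site_id = "RR" if i % 2 == 0 else "LI"
            year = int(rng.integers(0, 7))
            try:
                p = simulate_season(cv, series[site_id], start_year=year,
                                    management=Management(mode="potential"))
                w = simulate_season(cv, series[site_id], start_year=year,
                                    management=Management(mode="water_limited"))
            except SeasonError:
                continue
            assert p.grain_yield >= w.grain_yield - 1e-12
            assert p.HI <= 0.64 and w.HI <= 0.64
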