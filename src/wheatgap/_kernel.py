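"""Numba-compiled daily loop of the wheat simulator.

Everything here is plain numeric code over scalars and 1-D arrays so it
can be jit-compiled; the public, validated API lives in ``crop.py``.
If numba is unavailable the same functions run as pure Python (slower,
identical results).

Model constants are passed in a flat float64 vector; the ``C_*`` index
constants below name its slots.  ``wheatgap.crop.ModelConstants`` owns
the default values and documentation.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


# --- constant-vector slots -------------------------------------------------
C_T_BASE = 0
C_RUE = 1
C_PAR_FRAC = 2
C_K_EXT = 3
C_BASE_FLN = 4
C_MIN_FLN = 5
C_MAX_FLN = 6
C_DL_CAP = 7
C_VERN_TMIN = 8
C_VERN_TMAX = 9
C_VERN_DAYS = 10
C_VERN_PENALTY = 11
C_ANTH_PHYLL = 12
C_EMERGENCE_TT = 13
C_EXPAND_PHYLL = 14
C_LIFE_BASE = 15
C_LIFE_SLOPE = 16
C_SEN_SPAN_PHYLL = 17
C_SHOOT_DENSITY = 18
C_RANK_DECAY = 19
C_AG_FRAC = 20
C_STEM_FRAC = 21
C_RESERVE_FRAC = 22
C_TRANSLOC_RATE = 23
C_PT_ALPHA = 24
C_RN_FRAC = 25
C_SOIL_EVAP_COEF = 26
C_ROOT_GROWTH = 27
C_GREEN_LAI_MIN = 28
C_TF_OPT_LO = 29
C_TF_OPT_HI = 30
C_TF_MAX = 31
C_FLOWER_WINDOW_TT = 32
C_HEAT_THRESHOLD = 33
C_HEAT_SENS = 34
C_DROUGHT_THRESHOLD = 35
C_DROUGHT_SENS = 36
C_FERT_FLOOR = 37
C_MAX_SEASON_DAYS = 38
C_FILL_DAY_WEIGHT = 39
C_GRAIN_SINK_RATIO = 40
C_AMAX_REF = 41
C_AMAX_EXPONENT = 42
C_FILL_DECLINE_START = 43
C_FILL_DECLINE_RATE = 44
C_FILL_CONV_FLOOR = 45
N_CONSTANTS = 46

MAX_COHORTS = 26
LAYER_CM = 5.0

# season-kernel status codes
STATUS_OK = 0
STATUS_INCOMPLETE = 1


@njit(cache=True)
def thermal_time_day(tmin: float, tmax: float, t_base: float) -> float:
    """Daily thermal time: mean temperature above base, clamped at 0."""
    tt = 0.5 * (tmin + tmax) - t_base
    return tt if tt > 0.0 else 0.0


@njit(cache=True)
def temp_factor(tmean: float, lo: float, hi: float, tmax_lim: float) -> float:
    """Piecewise-linear temperature limitation on growth in [0, 1]."""
    if tmean <= 0.0:
        return 0.0
    if tmean < lo:
        return tmean / lo
    if tmean <= hi:
        return 1.0
    if tmean >= tmax_lim:
        return 0.0
    return (tmax_lim - tmean) / (tmax_lim - hi)


@njit(cache=True)
def intercepted_fraction(lai: float, k: float) -> float:
    return 1.0 - math.exp(-k * lai)


@njit(cache=True)
def daylength_h(latitude: float, doy: float) -> float:
    """Daylength in hours with the standard -0.833 deg horizon offset."""
    phi = latitude * math.pi / 180.0
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    h0 = -0.833 * math.pi / 180.0
    cos_ws = (math.sin(h0) - math.sin(phi) * math.sin(delta)) / (
        math.cos(phi) * math.cos(delta)
    )
    if cos_ws < -1.0:
        cos_ws = -1.0
    elif cos_ws > 1.0:
        cos_ws = 1.0
    return 24.0 / math.pi * math.acos(cos_ws)


@njit(cache=True)
def priestley_taylor_pet(tmean: float, rad: float, alpha: float, rn_frac: float) -> float:
    """Potential evapotranspiration (mm/day) from temperature and radiation."""
    es = 0.6108 * math.exp(17.27 * tmean / (tmean + 237.3))
    slope = 4098.0 * es / ((tmean + 237.3) ** 2)
    gamma = 0.066
    pet = alpha * slope / (slope + gamma) * rn_frac * rad / 2.45
    return pet if pet > 0.0 else 0.0


@njit(cache=True)
def soil_step(water, awc, lam_rel, rain, evap_demand, transp_demand, ru, n_rooted):
    """One day of the layer-cascade soil water balance (in place).

    Returns (transpiration, drainage, evaporation) in mm.
    """
    n = water.shape[0]
    # infiltration cascade
    excess = rain
    for i in range(n):
        if excess <= 0.0:
            break
        room = awc[i] - water[i]
        add = excess if excess < room else room
        water[i] += add
        excess -= add
    drainage = excess if excess > 0.0 else 0.0

    # soil evaporation from the top two layers
    evap = 0.0
    remaining = evap_demand
    for i in range(min(2, n)):
        if remaining <= 0.0:
            break
        take = water[i] if water[i] < remaining else remaining
        water[i] -= take
        evap += take
        remaining -= take

    # root extraction, limited per layer by R_u and the lambda profile
    transp = 0.0
    remaining = transp_demand
    frac = ru / 100.0
    for i in range(n_rooted):
        if remaining <= 0.0:
            break
        supply = frac * lam_rel[i] * water[i]
        take = supply if supply < remaining else remaining
        water[i] -= take
        transp += take
        remaining -= take
    return transp, drainage, evap


@njit(cache=True)
def simulate_season_kernel(
    tmin, tmax, precip, rad, doy,  # full series arrays
    sow_idx,  # index of sowing day in the series
    latitude,
    traits,  # [P_h, P_p, G_f, A_max, S_G, R_u, W_ss]
    lue_multiplier,
    water_limited,  # 0/1
    flowering_on,  # 0/1
    consts,  # float64[N_CONSTANTS]
    soil_awc, soil_lam_rel,  # per-layer arrays (profile starts full)
):
    """Simulate one season from sowing to maturity.

    Returns a float64 vector:
      [0] status (0 ok, 1 season incomplete)
      [1] grain biomass (g DM m-2)
      [2] above-ground biomass (g DM m-2)
      [3] harvest index
      [4] anthesis day (days after sowing)
      [5] maturity day (days after sowing)
      [6] grain-fill days (calendar)
      [7] cumulative intercepted global radiation (MJ m-2)
      [8] maximum LAI
      [9] water-stress days (stress factor < 0.95)
      [10] sum of daily thermal time, sowing..maturity (diagnostic)
      [11] sum of daily above-ground increments (mass-balance diagnostic)
      [12] water-balance residual, mm (diagnostic; 0 in potential mode)
      [13] final leaf number
      [14] post-anthesis thermal time consumed by grain fill
      [15] cumulative incident global radiation, emergence..maturity
      [16] above-ground biomass at anthesis (g DM m-2)
    """
    out = np.zeros(17)
    ph = traits[0]
    pp = traits[1]
    gf = traits[2]
    # leaf size trades off against tillering: effective canopy scale
    # rises sub-linearly with flag-leaf area
    amax = (consts[C_AMAX_REF]
            * (traits[3] / consts[C_AMAX_REF]) ** consts[C_AMAX_EXPONENT])
    sg = traits[4]
    # stay-green delays senescence with diminishing returns at high S_G
    sg_factor = 1.0 + sg - sg * sg / 6.0
    ru = traits[5]
    wss = traits[6]

    n = tmin.shape[0]
    max_days = int(consts[C_MAX_SEASON_DAYS])
    end = sow_idx + max_days
    if end > n:
        end = n

    n_layers = soil_awc.shape[0]
    water = soil_awc.copy()  # start at field capacity
    storage0 = 0.0
    for i in range(n_layers):
        storage0 += water[i]

    # state
    emerged = False
    fln_fixed = False
    flag_reached = False
    anthesis = False
    mature = False
    tt_sow = 0.0
    tt_em = 0.0
    tt_flag = 0.0
    tt_post = 0.0
    vern = 0.0
    leaf_number = 0.0
    fln = consts[C_MAX_FLN]
    biomass_ag = 0.0
    b_anth = 0.0
    grain = 0.0
    pool = 0.0
    pool0 = 0.0
    fert = 1.0
    root_cm = 0.0
    lai = 0.0
    max_lai = 0.0
    cum_int = 0.0
    cum_inc = 0.0
    stress_days = 0.0
    tt_total = 0.0
    ag_increments = 0.0
    cum_rain = 0.0
    cum_drain = 0.0
    cum_transp = 0.0
    cum_evap = 0.0
    anthesis_das = -1.0
    maturity_das = -1.0
    fill_days = 0.0
    wsf = 1.0

    app_tt = np.zeros(MAX_COHORTS)
    area_pot = np.zeros(MAX_COHORTS)
    sen_age = np.zeros(MAX_COHORTS)
    n_cohorts = 0

    expand_tt = consts[C_EXPAND_PHYLL] * ph
    sen_span_tt = consts[C_SEN_SPAN_PHYLL] * ph

    for t in range(sow_idx, end):
        das = t - sow_idx
        dtt = thermal_time_day(tmin[t], tmax[t], consts[C_T_BASE])
        tmean = 0.5 * (tmin[t] + tmax[t])
        tt_total += dtt

        if not emerged:
            tt_sow += dtt
            if tt_sow >= consts[C_EMERGENCE_TT]:
                emerged = True
            # bare soil: rain in, some evaporation
            if water_limited == 1:
                pet = priestley_taylor_pet(tmean, rad[t], consts[C_PT_ALPHA],
                                           consts[C_RN_FRAC])
                es_dem = consts[C_SOIL_EVAP_COEF] * pet
                tr, dr, ev = soil_step(water, soil_awc, soil_lam_rel,
                                       precip[t], es_dem, 0.0, ru, 0)
                cum_rain += precip[t]
                cum_drain += dr
                cum_evap += ev
            continue

        # --- emerged crop ---
        tt_em += dtt
        root_cm += consts[C_ROOT_GROWTH]

        # vernalisation
        if vern < 1.0 and consts[C_VERN_TMIN] <= tmean <= consts[C_VERN_TMAX]:
            vern += 1.0 / consts[C_VERN_DAYS]
            if vern > 1.0:
                vern = 1.0

        # final leaf number
        if not fln_fixed:
            dl = daylength_h(latitude, float(doy[t]))
            shortfall = consts[C_DL_CAP] - dl
            if shortfall < 0.0:
                shortfall = 0.0
            provisional = (consts[C_BASE_FLN] + pp * shortfall
                           + consts[C_VERN_PENALTY] * (1.0 - vern))
            if provisional < consts[C_MIN_FLN]:
                provisional = consts[C_MIN_FLN]
            elif provisional > consts[C_MAX_FLN]:
                provisional = consts[C_MAX_FLN]
            if vern >= 1.0 or leaf_number >= provisional - 0.5:
                fln = provisional
                fln_fixed = True
            else:
                fln = provisional

        # leaf appearance
        if not flag_reached:
            leaf_number += dtt / ph
            if leaf_number > fln:
                leaf_number = fln
            while n_cohorts < MAX_COHORTS and leaf_number >= n_cohorts + 1:
                i = n_cohorts
                app_tt[i] = tt_em
                rank_gap = fln - (i + 1.0)
                if rank_gap < 0.0:
                    rank_gap = 0.0
                area_pot[i] = (amax * consts[C_SHOOT_DENSITY]
                               * math.exp(-consts[C_RANK_DECAY] * rank_gap))
                n_cohorts += 1
            if fln_fixed and leaf_number >= fln - 1e-9:
                flag_reached = True
                tt_flag = tt_em

        # senescence acceleration under water stress (previous day's stress)
        accel = 1.0
        if water_limited == 1:
            accel = 1.0 + (wss - 1.0) * (1.0 - wsf)

        # canopy: cohort areas
        lai = 0.0
        for i in range(n_cohorts):
            age = tt_em - app_tt[i]
            if age < expand_tt:
                g = age / expand_tt
            else:
                sen_age[i] += dtt * accel
                rel_rank = (i + 1.0) / fln
                if rel_rank > 1.0:
                    rel_rank = 1.0
                dur = ((consts[C_LIFE_BASE] + consts[C_LIFE_SLOPE] * rel_rank)
                       * ph * sg_factor)
                if sen_age[i] <= dur:
                    g = 1.0
                else:
                    g = 1.0 - (sen_age[i] - dur) / sen_span_tt
                    if g < 0.0:
                        g = 0.0
            lai += area_pot[i] * g
        if lai > max_lai:
            max_lai = lai

        cover = intercepted_fraction(lai, consts[C_K_EXT])

        # --- water ---
        pet = priestley_taylor_pet(tmean, rad[t], consts[C_PT_ALPHA],
                                   consts[C_RN_FRAC])
        demand = pet * cover
        if water_limited == 1:
            es_dem = consts[C_SOIL_EVAP_COEF] * pet * math.exp(-consts[C_K_EXT] * lai)
            n_rooted = int(root_cm / LAYER_CM)
            if n_rooted > n_layers:
                n_rooted = n_layers
            tr, drn, ev = soil_step(water, soil_awc, soil_lam_rel,
                                    precip[t], es_dem, demand, ru, n_rooted)
            cum_rain += precip[t]
            cum_drain += drn
            cum_evap += ev
            cum_transp += tr
            if demand > 1e-12:
                wsf = tr / demand
                if wsf > 1.0:
                    wsf = 1.0
            else:
                wsf = 1.0
        else:
            wsf = 1.0

        if not mature and wsf < 0.95:
            stress_days += 1.0

        # --- growth ---
        tf = temp_factor(tmean, consts[C_TF_OPT_LO], consts[C_TF_OPT_HI],
                         consts[C_TF_MAX])
        ipar = consts[C_PAR_FRAC] * rad[t] * cover
        growth = ipar * consts[C_RUE] * lue_multiplier * tf * wsf
        cum_int += rad[t] * cover
        cum_inc += rad[t]

        if not anthesis:
            ag = consts[C_AG_FRAC] * growth
            biomass_ag += ag
            ag_increments += ag
            # anthesis trigger
            if flag_reached and tt_em >= tt_flag + consts[C_ANTH_PHYLL] * ph:
                anthesis = True
                anthesis_das = float(das)
                b_anth = biomass_ag
                pool0 = consts[C_RESERVE_FRAC] * consts[C_STEM_FRAC] * biomass_ag
                pool = pool0
        else:
            # grain-fill clock runs on daytime-weighted temperature
            w = consts[C_FILL_DAY_WEIGHT]
            fill_dtt = w * tmax[t] + (1.0 - w) * tmin[t] - consts[C_T_BASE]
            if fill_dtt < 0.0:
                fill_dtt = 0.0
            tt_post += fill_dtt
            ag = growth
            biomass_ag += ag
            ag_increments += ag
            tr_res = consts[C_TRANSLOC_RATE] * pool0
            if tr_res > pool:
                tr_res = pool
            # grain sink set at anthesis: kernel number scales with
            # biomass at anthesis and caps total grain growth
            sink_cap = consts[C_GRAIN_SINK_RATIO] * b_anth * fert
            allowed = sink_cap - grain
            if allowed < 0.0:
                allowed = 0.0
            # determinate kernel growth: conversion of assimilate to
            # grain declines through late grain fill
            conv = 1.0
            if tt_post > consts[C_FILL_DECLINE_START]:
                conv = 1.0 - consts[C_FILL_DECLINE_RATE] * (
                    tt_post - consts[C_FILL_DECLINE_START])
                if conv < consts[C_FILL_CONV_FLOOR]:
                    conv = consts[C_FILL_CONV_FLOOR]
            inc = (ag + tr_res) * fert * conv
            if inc <= allowed:
                grain += inc
                pool -= tr_res
            else:
                scale = allowed / inc if inc > 0.0 else 0.0
                grain += allowed
                pool -= tr_res * scale
            fill_days += 1.0
            if tt_post >= gf or lai < consts[C_GREEN_LAI_MIN]:
                mature = True
                maturity_das = float(das)
                break

        # flowering-window heat/drought effects on grain set
        if flowering_on == 1 and flag_reached:
            anth_tt = tt_flag + consts[C_ANTH_PHYLL] * ph
            if abs(tt_em - anth_tt) <= consts[C_FLOWER_WINDOW_TT]:
                if tmax[t] > consts[C_HEAT_THRESHOLD]:
                    f = 1.0 - consts[C_HEAT_SENS] * (tmax[t] - consts[C_HEAT_THRESHOLD])
                    if f < 0.0:
                        f = 0.0
                    fert *= f
                if water_limited == 1 and wsf < consts[C_DROUGHT_THRESHOLD]:
                    f = 1.0 - consts[C_DROUGHT_SENS] * (
                        (consts[C_DROUGHT_THRESHOLD] - wsf) / consts[C_DROUGHT_THRESHOLD]
                    )
                    fert *= f
                if fert < consts[C_FERT_FLOOR]:
                    fert = consts[C_FERT_FLOOR]

    if not mature:
        out[0] = STATUS_INCOMPLETE
        return out

    storage1 = 0.0
    for i in range(n_layers):
        storage1 += water[i]
    residual = 0.0
    if water_limited == 1:
        residual = cum_rain - ((storage1 - storage0) + cum_drain
                               + cum_transp + cum_evap)

    out[0] = STATUS_OK
    out[1] = grain
    out[2] = biomass_ag
    out[3] = grain / biomass_ag if biomass_ag > 0.0 else 0.0
    out[4] = anthesis_das
    out[5] = maturity_das
    out[6] = fill_days
    out[7] = cum_int
    out[8] = max_lai
    out[9] = stress_days
    out[10] = tt_total
    out[11] = ag_increments
    out[12] = residual
    out[13] = fln
    out[14] = tt_post if tt_post < gf else gf
    out[15] = cum_inc
    out[16] = b_anth
    return out
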