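# Methods

This note describes the models inside `wheatgap`: what they compute,
the assumptions they make, which parameters matter, how the ensemble
was calibrated, and what the synthetic-data setting does and does not
tell you about real field data.

## Synthetic weather

Each site is summarised by its long-run climate statistics (annual mean
temperature, annual precipitation, mean daily global radiation) plus
generator parameters (`SiteClimate`). The generator is deliberately
reduced — it reproduces the statistics that define the baseline
climate, with minimal machinery:

- **Temperature**: a sinusoidal annual cycle (half-amplitude 6.5 °C for
  UK sites, 5.0 °C for NZ; warmest day ≈ 19 July / 18 January by
  hemisphere) plus an AR(1) residual (lag-1 autocorrelation 0.7,
  innovation SD 2.0 °C). Daily min/max are the mean ∓ half the 8 °C
  diurnal range.
- **Precipitation**: two-state Markov occurrence (stationary wet-day
  probability 0.45, wet→wet persistence 0.65) with exponential wet-day
  amounts whose mean is scaled so the expected annual total equals the
  site target exactly.
- **Radiation**: a sinusoidal cycle phased to the solstices
  (half-amplitude ≈ 72% of the mean for UK sites, 62% for NZ,
  reflecting the stronger relative seasonality at high northern
  latitudes), log-normal multiplicative noise (σ = 0.12), a 25%
  reduction on wet days, then a rescale to the target mean and a clip
  to ≤ 0.78 × extraterrestrial radiation (FAO-56 Ra) and ≥ 0.25
  MJ m⁻² day⁻¹.

The calendar has 365-day years (no leap days); all outputs are rounded
to 2 decimals so a written weather file round-trips bit-exactly. Over
100 years the realised means land within 0.3 °C / 3% / 3% of the
targets. The generator does **not** reproduce spell-length
distributions, inter-annual variance structure (e.g. blocking, ENSO),
temperature–radiation cross-correlation beyond the wet-day coupling,
or extremes; conclusions about year-to-year yield variability therefore
reflect this simplified weather, not observed series.

## The crop simulator

A daily-timestep winter-wheat model in the Sirius tradition: radiation
capture × conversion efficiency, thermal-time phenology, a leaf-cohort
canopy, and a layer-cascade soil water balance. States are per unit
ground area (g DM m⁻², LAI in m² m⁻²); yields are dry matter, reported
as t ha⁻¹.

### Phenology

- Thermal time: `max(0, (tmin+tmax)/2 − T_base)` with `T_base = 0 °C`.
- Emergence after 150 °C day from sowing (20 October UK, 20 April NZ).
- Vernalisation: progress accrues at 1/33 per day when the daily mean
  lies in [−1, 7.5] °C. The narrow ceiling makes the mild Pukekohe
  winter vernalise slowly, which (via the unfulfilled-vernalisation
  penalty of 8 leaves × remaining fraction) delays flowering there into
  November — the behaviour expected of autumn-sown wheat in northern
  New Zealand. Colder sites saturate in midwinter and take no penalty.
- Final leaf number (FLN) = 8 base leaves + `P_p` × (daylength
  shortfall below 20 h) + penalty, clamped to [6, 22]; fixed when
  vernalisation completes, or when leaf appearance catches the
  provisional value. Leaves appear every `P_h` °C day; anthesis follows
  the flag-leaf ligule by 2 phyllochrons.
- Grain filling consumes `G_f` °C day on a **daytime-weighted**
  temperature (0.75·tmax + 0.25·tmin ≈ daily mean + 2 °C): kernels
  track daytime canopy temperature. This choice makes a 650 °C day
  grain-fill last ≈ 38 calendar days at the study sites, consistent
  with the reference cultivar's behaviour; the senescence and
  development clocks stay on the daily mean.

### Canopy

Leaf cohorts appear with the mainstem leaf number. Cohort area is
`A_max_eff × shoot_density × exp(−0.19 × (FLN − rank))`; big flag
leaves trade off against tillering, so the effective flag area follows
`A_max_eff = 0.007 × (A_max/0.007)^0.5`. A cohort expands over 1.2
phyllochrons, stays green for `(2 + 3.5·rank/FLN) × P_h ×
(1 + S_G − S_G²/6)` °C day (stay-green delays senescence with
diminishing returns), then declines linearly over 1.5 phyllochrons.
Under water stress the senescence clock runs up to `W_ss`-fold faster,
interpolating with (1 − stress factor).

### Growth and grain

Daily biomass = intercepted PAR (0.5 × global radiation ×
(1 − e^(−0.45·LAI))) × RUE (3.70 g DM MJ⁻¹, ×1.10 for ideotype design
runs) × a piecewise-linear temperature factor (0 at ≤ 0 °C, 1 between
10 and 20 °C, 0 at 37 °C) × the water-stress factor. Pre-anthesis, 90%
is above-ground; post-anthesis assimilate goes to grain together with
a stem-reserve translocation (pool = 25% of the stem fraction (60%) of
anthesis biomass; ≤ 2.5% of the pool per day, only while filling is
active). Three sink-side constraints shape the harvest index:

- grain is capped at 0.95 × above-ground biomass at anthesis (kernel
  number is set around anthesis);
- the assimilate→grain conversion declines linearly after 500 °C day
  of grain fill to a floor of 0.5 (determinate, sigmoid kernel growth);
- filling ends at `G_f` or when green LAI falls below 0.15, whichever
  comes first.

Heat (tmax > 27 °C) or severe drought (stress factor < 0.4) inside a
±100 °C day window around anthesis multiplies grain set down (2% per
°C, floor 0.3); at the study sites' baseline climate this changes mean
yield by < 1% and it can be toggled off.

### Soil water

The profile is a cascade of 5-cm layers at uniform available water
capacity (UK "Rothamsted": 210 mm over 28 layers; NZ "Lincoln": 270 mm
over 36). Rain infiltrates top-down; overflow past the bottom layer is
drainage. Potential evapotranspiration is Priestley–Taylor (α = 1.26,
net radiation 0.63 × global); crop demand is PET × green cover, soil
evaporation 0.5 × PET × e^(−k·LAI) from the top two layers. Daily
uptake from layer *i* is limited to `(R_u/100) × (λᵢ/λ̄) × availableᵢ`
with λ falling linearly from 0.10 (surface) to 0.04 (bottom): `R_u` is
the percentage of extractable root-zone water usable per day and λ
weights it toward shallow layers. Roots deepen at 1.2 cm day⁻¹. The
water-stress factor is supply/demand clamped to [0, 1]; irrigated
("potential") runs fix it at 1. Both the water and the above-ground
mass balances close to better than 10⁻⁶ over arbitrary simulations
and are asserted by the test suite.

Each season starts from a profile at field capacity — adequate for
autumn sowing into recharged soils, but it removes any carry-over of
summer depletion between years.

## Trait optimisation (EASA)

A seven-trait genome (`P_h`, `P_p`, `G_f`, `A_max`, `S_G`, `R_u`,
`W_ss`; six traits in irrigated mode, where `W_ss` has no effect) is
searched inside the bounds of observed genetic variation. The search is
an elitist (1+16) evolution strategy with standard log-normal step-size
self-adaptation (τ' = 1/√(2n) global, τ = 1/√(2√n) per-coordinate),
offspring clipped to bounds, run independently from 8 parents — parent
0 is the reference cultivar Claire, the rest are uniform in the box.
Candidates are scored by mean yield over a fixed multi-year weather
realisation (common random numbers, so selection compares like with
like) and are removed from selection when the inter-annual CV of yield
exceeds 0.10 or the mean harvest index exceeds 0.64 (thresholds
inclusive). A lineage stops after 15 generations without a relative
improvement above 10⁻³ (200 generations maximum); the best feasible
candidate over all lineages is returned.

Design choices worth flagging: plus-selection (the parent remains
eligible) guarantees per-lineage monotone improvement and that the
returned ideotype can never fall below the seeded reference under the
same evaluation settings; the harvest-index filter is applied to the
mean HI over years; ties are broken deterministically by trait values.
On concave analytic fitness surfaces the search recovers the optimum
within 2% of each trait's range from all 8 parents (tested at three
seeds).

## Yield-gap pipeline

For each site × {water-limited, potential}: simulate Claire
(LUE × 1.00) for `Y_M`, design the ideotype (candidates at LUE × 1.10)
for `Y_GP`, and report `Y_G = Y_GP − Y_M` and `100·Y_G/Y_GP`. Because
the 10% light-use-efficiency uplift is attached to ideotype design,
part of the reported gap is that uplift itself — the gap mixes "better
trait combination" with "better photosynthetic efficiency", as the
study design intends. Country aggregates are unweighted means over the
three sites with a sample (ddof = 1) between-site variance. Report
tables round yields and gaps to 1 decimal and percentages to integers;
identities hold exactly pre-rounding. The photothermal-quotient
contrast between countries is computed both as a ratio of country
means and as a mean of site-level quotients; the two differ and both
are reported, neither privileged.

All randomness descends from a single seed through named
`SeedSequence` spawns (per-site weather, per-lineage search), so a full
analysis replays bit-identically from its manifest.

## Calibration

The published surface of the original study is numbers, not equations,
so the constant ensemble (RUE, shoot density, cohort lifetimes,
vernalisation window, sink ratios) was calibrated jointly against the
reference-cultivar anchors: Claire's 100-year mean yield ≈ 10.8 t ha⁻¹
(UK) and 13.2 t ha⁻¹ (NZ) in irrigated mode, a ≈ 38-day mean
grain-fill, inter-annual CV < 10%, HI ≈ 0.45–0.50, and ideotype gains
in the 25–40% range. Within-package consistency, not parameter-level
agreement with any particular Sirius release, is the goal; absolute
optimized trait values are therefore only qualitatively comparable
(e.g. `P_h` and `G_f` move to their upper bounds, `P_p` collapses to
keep anthesis dates roughly fixed, stay-green strengthens — the same
directions the original optimisation reports).

## Problem sizes

The default configuration evaluates candidates over 100 years with up
to 200 generations per lineage. The test suite and worked examples use
a scaled-down setting — 25 evaluation years and 30 generations — which
completes the full 6-site × 2-mode analysis in about two minutes on one
CPU; at that size the qualitative results (NZ > UK yield potential,
gaps of ~25–40% of potential at every site) are already stable across
seeds, while absolute `Y_GP` values are within a few percent of the
full-size run.

## Known limitations

- No nitrogen cycle (the study assumes non-limiting N), no pests,
  diseases, lodging, or CO₂ response.
- The canopy model tracks mainstem-like cohorts with an effective
  shoot density; tillering dynamics, ear photosynthesis and stem area
  are folded into calibrated constants.
- Grain number is a biomass proxy (sink cap ∝ anthesis biomass), not a
  floret-level model; the HI ceiling emerges from three aggregate
  constraints rather than organ physiology.
- The weather generator's simplifications (above) make inter-annual
  CV estimates indicative only.
- Claire's phenology at the warmest site depends on the
  vernalisation-window calibration; outside autumn-sown temperate
  wheat systems the phenology defaults would need re-fitting.
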