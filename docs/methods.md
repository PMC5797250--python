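# Methods

`cropskill` quantifies, at desk scale, the economic value of skill in
probabilistic seasonal rainfall forecasts for designing dryland sorghum
crops. Everything runs on synthetic inputs with known properties, so every
claim the pipeline makes about forecast skill and forecast value can be
checked against the world that generated the data. This note documents the
models, the tunable parameters, the numerical choices, and what the
synthetic world does and does not establish.

## 1. Synthetic station weather

Daily weather (rain, maxt, mint, radn) is generated per calendar year:

* **Rain occurrence** — a first-order two-state Markov chain with monthly
  stationary wet-day probabilities `pi_m` and a persistence parameter `c`
  (lag-1 occurrence correlation, default 0.35): `p(wet|wet) = pi_m +
  c(1-pi_m)`, `p(wet|dry) = pi_m(1-c)`. The chain restarts from the
  stationary probability each 1 January (a deliberate simplification; the
  discontinuity is one transition per year).
* **Rain amounts** — gamma with shape 0.55 and monthly scales derived from
  the target annual mean (default 650 mm) and summer share (default 0.65
  falling Sep–Feb), using fixed within-season month weights. A lognormal
  year-level multiplier (CV 0.15) adds the low-frequency variability a
  daily chain alone cannot produce; the defaults give annual-total CV of
  about 0.25–0.34, matching the 0.25–0.40 range typical of the northern
  Australian grains belt.
* **Temperature and radiation** — annual harmonics (peak in mid-January,
  southern hemisphere) plus iid daily noise; the diurnal range is drawn
  positive so `maxt > mint` always holds, and radiation is floored at
  1 MJ m⁻² day⁻¹.

## 2. ENSO-like index and teleconnection

The index is a stationary AR(1) in months (default persistence 0.8),
standardized to mean 0 and sd 10 — the familiar scale of pressure-based
ENSO indices. The teleconnection multiplies each month's gamma scale by
`max(0.05, 1 + k z_m)` with `z_m` the unit-variance index. `k` is
calibrated so that the correlation between Sep–Feb rainfall totals and the
seasonal-mean index equals the configured `teleconnection_strength`:
the AR(1) covariances give the signal terms in closed form, and the
unmodulated seasonal-total variance is estimated by a seeded 400-year
pilot simulation (the pilot sees the Markov persistence and the
interannual multiplier, which closed-form daily accounting would miss).
A Monte Carlo check at 500 years recovers a target of 0.6 to within 0.03.
Strengths approaching the correlation between a single season's mean index
and its monthly values (about 0.95 at persistence 0.8) are infeasible and
rejected with a parameter error.

## 3. Tunable-skill ensemble hindcasts

Forecasts are issued on the 1st of each month at lead 0 for the 3-month
rainfall total. Skill is one parameter `rho` in [0, 1].

Window totals are mapped to Gaussian scores by a normal-scores (empirical
quantile) transform: year `y`'s total gets
`z_y = Phi^-1((rank_y - 0.5)/n)`, and scores map back to totals by linear
interpolation of the empirical quantile function (tails clamp to the
observed extremes). This makes `z` exactly standard-normal-ranked whatever
the rainfall distribution looks like, and makes the transform invertible
at the observed years.

For each issue, with `z_obs` the realized score:

    s   = rho^2 z_obs + rho sqrt(1-rho^2) eta      (one eta per issue)
    z_i = s + sqrt(1-rho^2) eps_i                  (one eps per member)

Members are draws from the true conditional distribution of the outcome
given the signal `s`, so the system is **reliable by construction** at
every skill level — the reliability slope of issued above-median
probabilities is ~1 (checked at ~2000 issues). Other identities that
follow: at `rho = 0` the members reproduce climatology (mean variance
ratio 1); at `rho = 1` the conditional noise vanishes, `z_i = z_obs`, and
every member equals the realized observation exactly (the generator then
returns the observed daily trace itself, giving the perfect-knowledge
limit without interpolation error); the correlation between the
ensemble-mean total and the realized total is `rho`; the per-issue
variance ratio is `1 - rho^2` in expectation, so dispersion (VR) falls
and shift (AMD) grows with skill.

Member daily traces are fresh synthetic sequences rescaled so each
member's window rain equals its drawn total; temperature and radiation are
synthetic (rainfall is the only skill-bearing variable).

**Crop-driving member seasons.** The crop proxy needs ~6 months of daily
weather from sowing, and simulated yields depend on when rain falls
(grain fill), not only on how much. The pipeline therefore builds member
seasons from six consecutive 1-month segments, each conditioned on its own
observed total at the same `rho` — the daily analogue of a long-range model
run downscaled to station weather. A single 3-month-total draw transmits
no sub-seasonal information and leaves yield-event skill near zero even at
high `rho`; monthly conditioning gives mean yield BSS ≈ 0.2 at `rho = 0.5`
and 0.35 at 0.75 on the reduced factorial. The issued 3-month product used
for rainfall verification is unchanged.

## 4. SOI-phase analogue system

Consecutive monthly index pairs are classified to the nearest of five
centroids in the (previous, current) plane — consistently negative
(-10, -10), consistently positive (+10, +10), rapidly falling (+8, -8),
rapidly rising (-8, +8), near zero (0, 0) — Euclidean distance, ties
broken in that fixed label order. The original cluster geometry behind the
five named phases was never published; these defaults reproduce the named
behaviours and are fully configurable.

An analogue forecast for an issue collects the window totals of all years
sharing the issue month's phase, always excluding the forecast year
(leave-one-out), and converts them to category probabilities against the
climatological median and terciles. Empty or single-member analogue sets
raise; the pipeline falls back to the leave-one-out climatology and flags
the substitution. With teleconnection 0 the system's BSS over 300
cross-validated issues is statistically indistinguishable from (slightly
below) zero, as cross-validated analogue systems must be.

## 5. Crop proxy

A transparent water-bucket stand-in for a process-based sorghum model,
run on a fixed 180-day horizon from sowing (the 1st of the window month):

    runoff  = runoff_curve * max(rain - 25 mm, 0)
    SW     += rain - runoff, overflow above PAWC drains
    evap    = evap_coeff * SW/PAWC
    demand  = demand_coeff * radn * f(density) * f(tillering) * f(row)
    transp  = min(demand, kl * SW)        while cumulative tt < target

Phenology is thermal time above 11 °C with maturity targets
{1500, 1700, 1900} °Cd (early/medium/late) and anthesis at 0.55 of the
target. Two structural choices matter:

* **Grain-fill water share.** Effective water use is
  `W = min(T_total, T_post/0.35)` where `T_post` is post-anthesis
  transpiration. Designs that exhaust the bucket before anthesis (high
  density, high tillering, long maturity, solid rows) are penalised when
  the season finishes dry, while conservative designs (skip rows, low
  density, early hybrids) are not. Without this term one maximal-demand
  design dominates every year and no forecast can have value; with it the
  per-year optimal design switches between 7–9 designs over 35 years.
  Because `W` is the minimum of two functionals that are each monotone in
  any added water, yield remains exactly non-decreasing in rainfall, PAWC
  and initial soil water.
* **Smooth nitrogen ceiling.** Biomass is
  `c (1 - exp(-TE·W/c))` with `c = 14.4·n/(n+40)`-style Michaelis ceiling
  (defaults `biomass_max` 20 t/ha, `K` 40 kg N/ha). A hard
  `min(biomass, c)` puts an atom at the cap; when most years sit there the
  in-sample yield median equals the cap and the above/below-median event
  degenerates (every outcome "below", spuriously perfect skill scores).
  The smooth ceiling keeps yields continuous while preserving the
  saturating, concave N response (`y(150)-y(100) <= y(100)-y(50)`).

Yield is `harvest_index (0.45) × biomass`, bounded by 12 t/ha; a crop
below 0.2 t/ha is flagged failed, which switches the economics to the
failed-crop cost. Defaults (TE 0.028 t/ha per mm of effective water,
kl 0.08 day⁻¹, demand 0.32 mm per MJ m⁻², soil evaporation 3 mm/day at a
full profile) were chosen once so that farmer practice on a high-PAWC soil
yields ≈ 3 t/ha with CV ≈ 0.17 and so that nitrogen above 50 kg/ha pays
only on deep soils in wet years. The proxy reproduces behaviours, not the
yield magnitudes of any station; water balance closes to 10⁻⁶ mm by
construction.

The model is deterministic — a seed argument is accepted for interface
symmetry but unused.

## 6. Verification

Standard definitions throughout: BS = mean (p−o)²; the reference forecast
issues the climatological base rate (0.5 or 1/3) every time;
BSS = 1 − BS/BS_ref. Percent consistent counts forecasts whose favoured
category (p above/below the base rate) verified; forecasts issued exactly
at the base rate leave the denominator, and an all-at-base-rate series is
reported undefined rather than zero. Reliability uses ten equal-width
bins; the slope `b` and RMSE come from a least-squares line of observed
frequency on bin-mean probability **weighted by bin counts**, which keeps
sparse extreme bins from dominating. AMD and VR compare each forecast
distribution with the climatological sample (sample variances, n−1).
Event conventions are fixed so outcomes are reproducible: above-median is
strict, ties fall to the lower category; terciles are type-7
(linear-interpolation) quantiles. Yield climatologies are computed
in-sample across the hindcast years from the observed-weather (trace 0)
runs, matching how the rainfall medians are used; this is flagged in the
output rather than cross-validated.

Monte Carlo standard errors for BSS use the delta method on the per-issue
numerator/denominator pair.

## 7. Decision layer

Profit per year: `yield × price(254 $/t) − 1% of gross (insurance) −
fixed cost (161 $/ha failed, 211 $/ha harvested) − urea cost of N above a
50 kg/ha base (0.30 $/kg urea, 46% N)`. The three published cost figures
cannot all be independent constants — the fixed totals, the percentage
insurance and the per-kg fertiliser price overlap — so the fixed costs are
taken as non-N, non-insurance totals with insurance and *incremental* N
added on top. This reproduces the failed-crop profit of −161 $/ha exactly
and keeps nitrogen rates economically distinct. Downside risk is the
percentage of years strictly below 600 $/ha.

Four strategies are compared per site × soil at the farmer environment
(October sowing, 60% of PAWC at sowing — the published typical practice,
applied to every site): the farmer's fixed design (medium maturity,
medium tillering, 5 plants/m², solid rows, 50 kg N); the static optimum
(exhaustive search for the design with the best mean observed-weather
profit); the forecast-informed strategy (designs whose above/below-median
yield-forecast BSS exceeds 0, then per year the survivor with the highest
ensemble-mean profit, realised under observed weather; an empty filter
falls back to the static optimum, flagged); and perfect knowledge (per
year argmax under observed weather). Ties in any argmax break to lower N,
then lower density, then listed order. Value_optS, Value_optSCF and
Value_PK are the mean-profit differences defined in the README; their
identities hold to 10⁻⁹ by construction and are asserted on every run.

The selection criterion in the forecast step is the risk-neutral ensemble
mean (not a quantile or utility); no switching cost is applied between
years.

## 8. The reduced factorial and what a green test establishes

The default configuration is one site, 3 soils (PAWC 400/344/274 mm),
5 monthly sowing windows Sep–Jan, 2 ISW levels {0.4, 0.6}, 2 densities
{5, 8}, 2 N rates {50, 100}, 2 maturities, 2 tillering types, 2 row
configurations, 35 hindcast years and 33 members: 1,142,400 crop-year
simulations, ~10 s on one CPU (the published full factorial, 4 sites ×
all levels × 100 traces, is 176,256,000 crop-years and is counted, not
simulated). Everything is a pure function of the config and one integer
seed; per-issue seeds are derived independently of `rho` so runs at
different skill levels are paired draws.

The synthetic world has, by construction, the properties the verification
and value layers are supposed to detect: calibrated ensembles whose skill
is known, an analogue system whose information content equals the
configured teleconnection, and a crop model whose season-dependence is
explicit. Green tests therefore establish that the *machinery* is correct
— scores are exact on worked cases, the no-skill null is not rejected,
value is monotone in skill, and the perfect-skill limit equals perfect
knowledge exactly. They do not establish anything about real stations,
real GCM output, or absolute dollar values; the profit levels here
(roughly 300–700 $/ha, Value_optS ≈ 12–70 $/ha, Value_optSCF ≈ 3–20 $/ha
depending on skill) sit below the published station values because the
proxy's yields and their variability do. What carries over is the
structure: optimising the static design is worth several times the
incremental value of the forecast, and forecast value falls roughly
mid-way between no skill and perfect knowledge once skill is moderate.

## 9. Known limitations

* Only rainfall carries forecast skill; temperature and radiation in
  member traces are climatological noise.
* The occurrence chain resets each 1 January; member daily traces are
  rescaled rather than re-simulated conditionally, so their wet-day
  statistics are slightly distorted at extreme member totals.
* The normal-scores back-transform clamps member totals to the observed
  range (mild under-dispersion of extremes with short climatologies).
* The analogue reference period and the phase centroids are declared
  defaults, not estimates of any historical system.
* Yield climatology for events is in-sample; with 35 years this inflates
  apparent skill slightly for all systems equally.
* ISW in v/v is interpreted as fraction of PAWC at sowing.
* A 180-day horizon truncates late-maturity crops sown into cool windows
  if thermal time accumulates unusually slowly.
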