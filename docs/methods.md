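# Methods

This note records the model structure, the defaults and why they were
chosen, the numerical conventions, and what the synthetic data can and
cannot support.

## Fleet model and regressions

A fleet is a list of vehicle-model records (registrations, kerb and WLTP
test mass, fuel, engine capacity, wheelbase, WLTP CO₂ g/km, optional RDE NOx
mg/km).  Annual per-model emissions multiply the per-km value by
registrations and an assumed fuel-class annual distance (petrol family
10,137 km; diesel family 15,125 km; battery-electric 15,180 km — national
travel-survey means).  Hybrids drive their base fuel's distance; plug-in
hybrids are treated as petrol throughout (their distance, diesel indicator
and fuel family), since no separate assumption exists for them.

Per-segment profiles divide total segment annual emissions by segment
registrations.  CO₂ means include battery-electric vehicles (zero
numerator); NOx means are taken over NOx-reporting registrations only,
mirroring the partial coverage of on-road test data (about 60% of
registrations; records without NOx stay in the CO₂ account).  SUV mass
boundaries: 1500 kg and 2000 kg both classify as *medium* (the defining
interval is read as closed); the boundary behaviour is unit-tested.

The CO₂ regression is ordinary least squares of WLTP CO₂ on test mass,
engine capacity, wheelbase and a diesel indicator over internal-combustion
models, one observation per model, classical homoskedastic errors and
t-based 95% CIs.  NOx is fitted separately for diesel and petrol on mass and
engine capacity.  Rank-deficient designs and all-zero predictor columns are
rejected (never silently dropped).  The published fit this mirrors reports
identical coefficient columns for the diesel and petrol NOx models while the
accompanying text gives different per-100 kg effects — an apparent
typesetting duplication; this implementation genuinely fits two models.

## Synthetic data

The fleet generator reproduces the documented 2020 structure: 181 models,
1,560,452 registrations multinomially allocated over the 33 published
segment-by-fuel cells (at least one model per cell, remainder by largest
remainder), kerb masses uniform within segment-specific ranges chosen so SUV
sub-classes land in their defining bands, and engine capacity and wheelbase
generated from the same latent size factor as mass (plus noise) to mimic the
real collinearity of size variables.  CO₂ and NOx come from the published
linear coefficient sets (CO₂: intercept 181.546, mass 0.1028/kg, engine
0.0198/cm³, wheelbase −0.0793/mm, diesel −24.366; NOx: intercept −57.04,
mass 0.0677/kg, engine 0.0299/cm³) plus independent Gaussian noise floored
at zero.  Noise scales were set numerically so the refitted models match the
published fit quality — `co2_noise_sd = 10.5` g/km gives R² ≈ 0.885 (target
0.8857) and `nox_noise_sd = 46` mg/km gives diesel R² ≈ 0.51 (target
0.513) — and then frozen.  Each model reports NOx with probability 0.595.
All draws flow from one seeded generator; a fixed seed reproduces the fleet
exactly.

The population generator uses a two-parameter Gompertz hazard per sex
(`α·e^{βa}`, defaults α = 1.6×10⁻⁵/3.0×10⁻⁵ and β = 0.105/0.103 for
females/males), flattened from age 90, with constant annual births (341k
female, 359k male) and the implied stationary age structure; deaths are
population × hazard exactly.  This yields life expectancies near 78/73
years — plausible but deliberately not a fit to real UK schedules.  Real
mortality has an infant hump and cohort trends the generator omits, so
passing tests demonstrate correctness of the life-table machinery, not
calibration to the real population; absolute life-year totals with synthetic
inputs are indicative only.

## Stock turnover

The survival schedule interpolates the published anchors piecewise-linearly:
S(0)=1, S(14)=0.5 (median 14-year service life), S(25)=0, giving an expected
service life of 13.75 years.  The published fleet-penetration milestones
(41%/77%/96% at 5/10/15 years) are *not* attainable from any non-increasing
schedule in a constant-sales steady-state fleet — monotonicity forces the
mean survival over ages 0–5 to be at least that over ages 6–10, while the
milestones would require 0.41/6 < 0.36/5 (`steady_state_feasibility`
certifies this).  The milestones embed the real, older-skewed age structure
of the pre-2020 fleet.  Calibration therefore keeps every published survival
fact exact and solves a three-level legacy-fleet age profile (one level per
milestone interval; the 3×3 linear system has a strictly positive solution)
so that coverage at each milestone age is exact by construction.  Calendar
convention: a vehicle registered in year y is age 0 and fully in service
during y.

## Scenarios and projections

Cohort composition scales the 2020 segment-by-fuel counts to the year's
sales (observed 1,560,452 in 2020; 2.5 M/year after), applies segment
substitutions (substituted vehicles adopt the target segment's 2020 fuel mix
and per-vehicle profile — "an average car of that segment"), then, in
electrified scenarios, a BEV share uniform across segments (linear between
the 2020 share and the 25/70/100% anchors), with the residual split by the
segment's 2020 non-BEV mix until 2030 and all petrol PHEV over 2031–2035.
The combined scenario applies substitution first, then electrification — the
operators commute on counts but not fuel mix, so the order is fixed and
tested.  The 2020 cohort keeps its observed composition in every scenario.
Totals are conserved exactly in each scenario-year.

Cumulative CO₂ integrates attrition for all drivetrains and counts emissions
through the horizon year inclusive.  The printed BEV charging formula
multiplies efficiency (km/kWh) by distance (km), which is dimensionally
inconsistent; the only unit-correct reading — energy used × intensity,
`(D/E)·I` — is implemented.  The default grid trajectory is piecewise linear
through 180 g/kWh (2020), 30 (2030), 2 (2035), 1 (2050): a public rendering
of a net-zero-consistent pathway in which electricity is essentially
decarbonised before the combustion ban completes.  Under it, BEV charging
contributes under 1% of the 2050 emission saving in electrified scenarios; a
slower linear 180→5 decline raises that to several percent, so the
trajectory matters and is fully overridable by file.

Whole-fleet NOx adds the legacy fleet (default: constant 2.5 M/year
historical sales, 45% diesel, emitting at bundled era-step EURO limits —
diesel 900/500/250/180/80 mg/km and petrol 500/150/80/60 mg/km by
registration era, overridable) to post-2020 cohorts at 2020 segment means.
New ICE vehicles are assumed to emit at 2020 rates indefinitely.  Fleet NOx
declines strictly in all scenarios as dirtier legacy cohorts retire; in
electrified scenarios it falls below 2% of the 2020 level by 2051 (residual
2027–2034 ICE/PHEV cohorts keep it just above zero).  The published ambient
baseline is printed as "2.59 mg/cm³", dimensionally implausible for urban
air; it is read as 2.59 µg/m³.  NO₂ scales with fleet NOx directly (no
atmospheric chemistry): Δ = 2.59·(1 − scenario/BAU), clamped to [0, 2.59].

## Life table

Hazards are annual death probabilities by sex and single year of age,
pooled over ages 90–105 on ingest.  Projection uses end-of-year accounting:
during each year the population faces baseline hazards times the relative
risk `rr^(−Δ_eff/10)` at ages 30+ (rr = 1.023, CI 1.008–1.037), survivors
age one year, constant births enter at age 0, and survivors of the terminal
age (105) exit.  The relative risk multiplies the annual death *probability*
directly; at these magnitudes the rate/probability distinction is
immaterial.  Δ_eff phases in each year-on-year increment of the
concentration change with the standard inception-lag distribution: 30% in
year 1, 50% spread over years 2–5, 20% over years 6–20 (only the year-1 and
year-20 anchors are published; the interior split is configurable).  The
last supplied Δ persists to the horizon (2126).  Life years gained are the
person-year difference between impacted and baseline projections over all
cohorts, including births after 2096 (they cannot reach age 30 by 2126 and
therefore contribute identically to both projections; `births_until`
exposes the alternative reading).  An array projection is used in
production; tests verify it against an independent per-cohort
survival-product microsimulation to 10⁻⁶ relative.  Valuation discounts each
year's life years to 2020 at 1.5%/year times £60,000 (VOLY); the
sensitivity grid spans VOLY {20k, 60k} × rate {1.5%, 3.5%} × coefficient
{1.008, 1.023, 1.037} from the same life-year streams, so VOLY rows differ
by an exact factor of 3.  With the default synthetic inputs the inception
lag reduces total life years gained by ≈4%, consistent with the published
4–5%.

## Problem sizes and runtime

Default runs use 181 vehicle models, five scenarios over 2020–2060 NOx
years, CO₂ horizons 2035/2050, and life tables of 2 sexes × 106 ages
projected to 2126.  A full pipeline run completes in a few seconds on one
CPU; the acceptance script (40 fleet generations plus regressions) in about
two.

## Known limitations

Tailpipe only: no embedded/life-cycle emissions, non-exhaust particulates,
collision risk, rebound effects or hydrogen vehicles.  Published cumulative
totals and life-year absolutes depend on the real fleet and population
microdata and are not reproduced by the synthetic stand-ins; published
quantities are asserted only where they are arithmetic consequences of
published inputs (valuation cells, percent-change columns, coverage
milestones, regression-coefficient recovery).  The small-SUV substitution
here yields a smaller CO₂ reduction (≈11%) than the published 49%, which is
not derivable from the published per-vehicle segment means under a 1:1
substitution; the pipeline reproduces the published *procedure* and treats
those absolutes as reference values.
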