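# suvhealth

A bottom-up model of UK passenger-vehicle tailpipe CO₂ and NOx emissions
under contrasting SUV-sales and electrification policies, with life-table
estimation and monetary valuation of the mortality impact of the implied
NO₂ changes.  It is aimed at public-health and transport-policy analysts who
want a transparent, fully scriptable alternative to spreadsheet-based health
impact assessment.

## The model

**Fleet accounting.**  Each vehicle model on sale contributes annual
emissions `T = C·R·D/10⁶` tonnes of CO₂ (with `C` the WLTP type-approval
value in g/km, `R` registrations, `D` the assumed annual distance for its
fuel class: 10,137 km petrol, 15,125 km diesel, 15,180 km battery-electric)
and `T = N·R·D/10⁹` tonnes of NOx (`N` the RDE on-road value in mg/km).
The SUV segment (EURO segment J) is sub-classified by kerb mass: small
(<1500 kg), medium (1500–2000 kg), large (>2000 kg).  Per-segment means of
these annual values drive all projections.

**Scenarios.**  Five new-sales policies from 2020: business as usual (BAU);
medium and large SUVs replaced 1:1 by small SUVs; all SUVs replaced by B/C/D
segment cars; electrification (BEV share 25% in 2025, 70% in 2030, 100% from
2035, residual sales petrol PHEV over 2031–2035); and electrification
combined with the small-SUV switch.  Sales are 2.5 M/year from 2021.

**Stock turnover.**  A sales cohort survives with schedule S(a): S(0)=1,
median service life 14 years (S(14)=0.5), fully retired by age 25.  The
legacy (pre-2020) fleet age profile is calibrated so that a policy applied
to new sales covers 41% of the on-road fleet after 5 years, 77% after 10 and
96% after 15, exactly.

**CO₂.**  Cumulative emissions to 2035/2050 sum surviving-count-weighted
annual emissions of every post-2020 cohort; BEVs emit
`(D/E)·I_year/10⁶` t/year from charging (`E` = 6.5 km/kWh, `I` the grid
carbon intensity, declining to near zero by 2035 by default).  Savings
versus BAU are valued at marginal abatement costs (central
£302.3/t in 2035, £378.3/t in 2050).

**NOx → NO₂ → health.**  Whole-fleet NOx (legacy vehicles at the EURO limit
of their registration era, new cohorts at 2020 segment means) scales an
assumed constant urban-background NO₂ contribution of 2.59 µg/m³
proportionally.  The reduction Δ enters an IOMLIFET-style life table as a
relative risk `1.023^(−Δ/10)` on mortality hazards at ages 30+, phased in
with the standard inception lag (30% in year 1, complete at year 20).  Life
years gained through 2126 are valued at £60,000/life-year discounted at
1.5%/year (sensitivity: £20,000, 3.5%, and the 1.008/1.037 coefficient CI).

## Worked example

No registration or mortality microdata ship with the package; a synthetic
fleet (181 models, 1,560,452 registrations, published segment/fuel
composition and emission–mass structure) and a synthetic Gompertz-mortality
population stand in.  One command runs everything:

```sh
suvhealth run-all --seed 1 --out results
```

`results/cumulative_co2.csv` (seed 1):

```
           scenario  cumulative_mt_2035  pct_change_vs_bau_2035  cumulative_mt_2050  pct_change_vs_bau_2050
                BAU               564.8                     0.0              1615.1                     0.0
           SmallSUV               502.8                   -11.0              1438.5                   -10.9
              NoSUV               506.6                   -10.3              1448.4                   -10.3
        Electrified               388.8                   -31.2               590.3                   -63.5
ElectrifiedSmallSUV               339.9                   -39.8               517.7                   -67.9
```

Each row is a policy's cumulative CO₂(e) in Mt from all post-2020 cohorts to
the horizon, and its change versus BAU: electrification dominates by 2050,
and adding the small-SUV switch removes a further ~70 Mt.
`results/life_years.csv` gives the health side — with this synthetic
population the combined scenario gains ≈3.20 M life years versus BAU by 2126
(+2.8% over electrification alone), valued at ≈£77 bn (+5.0%; the SUV switch
acts earlier, so its value gains more than its life years).  The bundle also
contains the segment profiles, regression tables, survival schedule, fleet
NOx/ΔNO₂ trajectories, carbon valuations, a VOLY × discount × coefficient
sensitivity grid, and a manifest (seed, config hash, version).  Re-running
with the same seed reproduces every file byte-for-byte.

Absolute levels depend on the synthetic stand-ins; the published study
values are reproduced only where they are functions of published inputs
(see `docs/methods.md`).

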