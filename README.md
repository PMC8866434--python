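# cobenefits

Air-quality and health co-benefit assessment of climate-policy scenarios.

Climate policies that cut CO₂ also cut co-emitted air pollutants. This
package quantifies that co-benefit for fine particulate matter (PM2.5):
starting from gridded annual-mean PM2.5 concentration fields under paired
scenarios (a no-policy reference vs. a mitigation pathway), a co-registered
age-structured population grid, cause-specific baseline mortality rates, and
exposure–response fit parameters, it estimates the mortality attributable to
long-term PM2.5 exposure, differences scenario pairs into avoided deaths,
monetizes them with value-of-statistical-life (VSL) models, and compares the
result against mitigation costs. It is aimed at integrated-assessment and
health-impact researchers who already have concentration fields (e.g., from
a chemistry-transport model) and want the health-and-valuation half of the
analysis to be reproducible and testable.

## The model

Relative risk follows the Global Exposure Mortality Model (GEMM), a
log-linear term damped by a logistic weight, with a theoretical
minimum-risk concentration of 2.4 μg/m³:

```
RR(c) = exp{ θ · ln(z/α + 1) / (1 + exp(−(z − μ)/ν)) },   z = c − 2.4
```

and RR = 1 for c ≤ 2.4 μg/m³. Attributable deaths for disease *i* and age
group *j* use the attributable-fraction bookkeeping

```
M_ij = Σ_g P_gj · Î_ij · (RR(C_g) − 1),      Î_ij = I_ij / R̄R_ij,
```

where R̄R is the population-weighted mean relative risk over the grid and
Î the "underlying incidence" that would remain at the minimum-risk
concentration. For a spatially uniform field this reduces to the familiar
M = P·I·(RR−1)/RR. Scenario co-benefits are ΔM = M_REF − M_policy, and
95% envelopes rerun the whole chain with θ ∓ 1.96·SE(θ). Benefits are
ΔM × VSL, with VSL either locally transferred over income growth
(VSL = VSL₀ + ΔINC × MVSL, default marginal VSL 14,550 USD per 145.8 USD
of annual income, from a Chongqing contingent-valuation study) or scaled
internationally (VSL_ref × (INC/INC_ref)^β).

## Worked example

Everything runs from synthetic inputs — no downloads. Generate a paired
scenario (reference vs. 10% uniform reduction) on a 32×32 grid with 10
million people, then run the full pipeline:

```
cobenefits simulate-data --out inputs --seed 1 --grid 32 32 --pop-total 10000000
cobenefits run --config inputs/config.yaml
cat inputs/out/summary.txt
```

which prints:

```
Exposure by scenario:
  SSP1_REF (2050): PWC = 50.64 ug/m3, population above 35 ug/m3 = 6,446,534
  SSP1_RCP1.9 (2050): PWC = 45.58 ug/m3, population above 35 ug/m3 = 5,774,768

Attributable deaths (all diseases and ages):
  SSP1_RCP1.9 (2050): 14,113 (95% CI 11,524-16,620)
  SSP1_REF (2050): 15,240 (95% CI 12,467-17,914)

Avoided deaths and monetized net benefit per scenario pair:
  SSP1_REF-SSP1_RCP1.9 (2050): 1,126 avoided deaths (95% CI 942-1,295); benefit 1.24 B USD, cost 100.00 B USD, net -98.76 B USD, benefit/cost 0.01
```

Reading this: the policy scenario lowers the population-weighted PM2.5
concentration (PWC) from 50.6 to 45.6 μg/m³ and moves ~0.7 million people
below the 35 μg/m³ air-quality threshold; of the ~15,200 deaths per year
attributable to PM2.5 in the reference scenario, ~1,126 are avoided under
the policy; at the configured VSL this is worth 1.24 billion USD against a
placeholder 100 billion USD mitigation cost. (The toy population is 1% of
a national scale, so benefits scale accordingly; costs here are an input,
not a model result.) The CI is the θ ∓ 1.96·SE envelope of the
exposure–response function.

Machine-readable tables land next to the summary: `exposure_summary.csv`,
`burden.csv`, `avoided_deaths.csv`, `valuation.csv`, and `run_log.json`
(versions, seed, config hash). Each stage is also available as its own
subcommand (`exposure`, `burden`, `cobenefit`, `valuate`), and the whole
library is importable — see `cobenefits.relative_risk`,
`cobenefits.attributable_mortality`, `cobenefits.monetize`, etc.

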