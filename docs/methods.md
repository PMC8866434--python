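# Methods

## Exposure–response model

Relative risk of cause-specific mortality from long-term ambient PM2.5
exposure follows the GEMM functional form: a log-linear term in
transformed concentration damped by a logistic weight,

    RR(c) = exp{ θ · ln(z/α + 1) / (1 + exp(−(z − μ)/ν)) },  z = c − cmin,

with RR ≡ 1 at or below the theoretical minimum-risk concentration
`cmin`. All logarithms are natural. `cmin` defaults to 2.4 μg/m³ but is a
parameter of `GEMMParamSet`, not a hard-coded constant, so sensitivity
analyses can move it. Parameters are per (disease endpoint, age band);
the standard layout is 5-year adult bands from 25–29 to 85+ plus an
optional all-adult aggregate. Ages under 25 receive no attributed risk:
they simply have no parameter set, and the burden module emits no rows
for them.

Uncertainty: only θ carries a standard error in the public fit tables,
so the confidence envelope replaces θ by θ ∓ z·SE(θ) (default z = 1.96,
an ~95% normal interval) and re-evaluates the entire function. This is a
documented modeling choice, configurable through `z_crit`; no profile
or simulation-based interval is attempted. With θ ≥ 1.96·SE the envelope
stays above the null; if a user supplies a large SE the lower rerun may
cross RR < 1, which the implementation tolerates internally (the bounds
are then re-ordered so low ≤ mean ≤ high always holds).

## Attributable mortality

Per (disease i, age j) the pipeline computes, over grid cells g,

1. the population-weighted mean relative risk
   R̄R = Σ_g P_gj·RR(C_g) / Σ_g P_gj (weights are that age group's
   population; the printed source formula indexes this sum ambiguously,
   and it is implemented as a sum over grid cells);
2. the underlying incidence Î_ij = I_ij / R̄R — the hypothetical rate at
   the minimum-risk concentration, given that the reported national rate
   I_ij already embeds prevailing exposure;
3. the grid sum M_ij = Σ_g P_gj · Î_ij · (RR(C_g) − 1).

For a uniform field this is algebraically the attributable-fraction
identity M = P·I·(RR−1)/RR, which the tests verify to 1e-12 relative
error; on heterogeneous grids the vectorized sum is checked against an
unvectorized cell-by-cell reference to 1e-9.

R̄R (and hence Î) is always computed with national, whole-grid weights;
regional tables are produced by zeroing population outside a boolean
mask and reusing the national Î (`national_pop=` argument). Whether a
province-level R̄R would be more faithful is not decidable from the
available description; national is the implemented and documented
choice. Baseline incidence is held at its input (2015) values for all
projection years — no baseline-mortality projection is attempted — and
years are labels, not dynamics.

CI bounds are produced by rerunning the full chain (RR, R̄R, Î, M) with
the shifted θ. Because that shift is a single global perturbation,
summing per-stratum bounds across diseases, ages, or regions is a
perfect-dependence bound, not an independently propagated interval;
every burden table carries this caveat in its `attrs["ci_note"]`
metadata and aggregation preserves it.

Scenario co-benefits are ΔM = M_REF − M_policy per matching (year,
disease, age, region) key, sign preserved: a policy run with the larger
burden (which can happen when, e.g., ammonia-driven secondary formation
offsets acid-gas reductions) yields negative avoided deaths and a
negative monetized benefit.

## Exposure summaries

The population-weighted concentration is Σ C_g·P_g / Σ P_g with
population summed over ages. "Population above a threshold" counts
people in cells strictly above it: the air-quality goal is "at most
35 μg/m³", so non-attainment is C > 35. Grids must be co-registered
(identical edges within 1e-9°, same ordering); the analysis core never
regrids. A nearest-neighbor regrid helper lives in the synthetic-data
module for fixture construction only.

## Valuation

Two VSL benefit-transfer variants, all in 2017 USD with no inflation
adjustment inside the pipeline:

* **local_linear** — VSL(y) = VSL₀ + (INC_y − INC₀)·MVSL. The default
  marginal VSL is the Chongqing contingent-valuation slope of
  14,550 USD of VSL per 145.8 USD of annual per-capita income
  (≈ 99.79 USD/USD). A large income decline can drive the line negative;
  the result is floored at zero with a warning (or raises with
  `floor=False`).
* **international_transfer** — VSL_ref·(INC/INC_ref)^β with income
  elasticity β ∈ [0, 2]; β = 0.8 and 0.4 are the conventional bracketing
  choices.

One national VSL per scenario-year (incomes are national per-capita
values; no regional differentiation). Baseline VSL and the income series
are configuration inputs: the bundled defaults (VSL₀ = 250,000 USD,
INC₀ = 3,500 USD, a 12,000 USD mid-century income) are placeholders of a
plausible order for China, not study-specific estimates, and any serious
application should supply its own. Benefits are total avoided deaths ×
VSL in billion USD; net benefit is benefit − mitigation cost, with the
cost an exogenous input (an integrated-assessment model's abatement-cost
output, not computed here). The benefit-cost ratio is flagged undefined
(NaN) at zero cost rather than infinite. GDP-share columns appear only
when the user supplies a GDP projection (`gdp_by_year`).

## Synthetic data generator

The generator produces inputs with the statistical structure the
analysis relies on; it does not emulate atmospheric chemistry,
meteorological variability, or satellite calibration.

* **Concentration** — white noise smoothed by a separable moving average
  (half-width `conc_spatial_corr_length` cells, wrap-around boundaries),
  standardized, exponentiated with log-scale `conc_lognormal_sigma`, and
  rescaled so the unweighted mean is exactly `conc_mean`. Positive and
  spatially correlated; the exact correlation model is not itself a
  claim. `conc_lognormal_sigma = 0` yields a spatially uniform field,
  the configuration under which closed-form recovery tests run. The
  policy member of a pair is the reference scaled by
  (1 − `reduction_fraction`) in every cell.
* **Population** — Gaussian clusters over a thin rural background,
  apportioned by largest-remainder rounding first across age bands and
  then across cells, so the national total and the age split are exact
  integers.
* **Incidence and fit parameters** — incidence rises exponentially with
  age (≈7e-4 per person-year at 25–29 to ≈0.2 at 85+, the shape of a
  combined NCD+LRI endpoint); θ is drawn near 0.12 with SE = θ/10, and
  α, μ, ν within the ranges of the published fits (α ∈ [1, 20],
  μ ∈ [5, 30], ν ∈ [1, 50]). A `theta_zero` mode produces an exact null.

Defaults mirror the study conditions at national scale: mean
concentration 53 μg/m³ (the 2015 population-weighted level in China), a
10% policy reduction (the scale of the strictest mid-century scenario),
a 1.37-billion population with a mid-2010s Chinese age profile, on a
64×64 grid spanning a China-sized lat/lon domain. One disease category,
"NCD+LRI", is the default; multi-disease tables are supported
everywhere downstream. All draws flow from the single spec seed through
per-product substreams, so every artifact is bit-reproducible.

What passing tests on these inputs do **not** show: fidelity of any real
chemistry-transport field (no emission inventories, no secondary
chemistry, no seasonal cycle), real spatial covariance between people
and pollution (clusters and plumes are independent here unless the user
couples them), or the validity of the published VSL and cost figures,
which enter only as arithmetic inputs.

## Numerical and design notes

* The exposure–response evaluation clips z at 0 before the log so the
  masked below-threshold branch never sees an invalid argument; the
  function is continuous at `cmin` (limit from above is 1).
* Weighted means raise a `WeightingError` on zero total weight rather
  than returning NaN.
* Table writers emit `%.17g` floats and fixed row/column order; the
  parameter reader parses with round-trip precision, so write-then-read
  is bit-exact and repeated pipeline runs are byte-identical.
* Aggregation uses stable sorts and sums within groups; the grand total
  is invariant under any grouping.
* Largest-remainder apportionment breaks ties by first index (stable
  argsort on descending fractional part).
* Test problem sizes (grids up to 64×64, populations ≤ 2 million in
  unit tests) are chosen so the full suite runs in seconds while still
  exercising every code path; the estimators themselves are scale-free
  and linear in population, which the suite verifies directly.

## Known limitations

* Mortality only, via PM2.5 mass concentration: no morbidity or
  years-of-life-lost endpoints, no ozone or NOx effects, no composition
  or particle-size differentiation, and no cessation lag (deaths are
  attributed to the exposure year).
* Only θ-uncertainty is propagated; concentration fields, population,
  incidence, and VSL enter as point values.
* Published national-scale headline burdens are not reproducible from
  synthetic inputs — they require the original concentration fields,
  gridded population, and burden-of-disease incidence — so the test
  suite validates the method's identities and oracles instead.
* Mitigation costs are exogenous; the package adds no discounting and
  no cost-side modeling.
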