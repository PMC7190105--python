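# Methods

`csasim` couples five stages — synthetic world generation, per-cell
practice adoption, FPU-level tailoring, partial-equilibrium market
propagation, and greenhouse-gas / food-security accounting — into a
deterministic pipeline driven entirely by a `(config, seed)` pair. This
note records the model assumptions, the parameter choices and why they
were made, the numerical decisions, and what the synthetic setting can and
cannot show.

## 1. The synthetic world

The generator emulates the statistical structure of a gridded global
crop-production database coupled to a crop-model response surface, not any
real geography. Each of the `n_cells` cells (default **2000**, in **40**
FPUs across **15** countries — large enough for stable within-FPU quartile
statistics, small enough for seconds-scale runs) carries:

- one crop (maize 38 %, wheat 34 %, rice 28 % of cells) and one water
  system (irrigated shares 25/35/60 % respectively); rice is the only crop
  with a flooded water regime, and rainfed rice is treated as flooded for
  CH₄ purposes (its baseline regime is continuous flooding; only irrigated
  rice can switch to multiple drainage via AWD);
- lognormal baseline yields (medians 4.5/3.1/4.2 t/ha), harvested areas
  (median 10⁵ ha — sized so three-crop world area is a few hundred Mha),
  and N inputs (mineral medians 85–100 kg N/ha, manure 18, residue 15;
  mineralized N normal around 30 kg N/ha);
- uniform growing-season lengths per crop (maize 100–160 d, wheat
  120–220 d, rice 100–150 d) and lognormal rice straw (median 1.5 t/ha)
  and farmyard-manure (0.8 t/ha) incorporation.

**Practice responses.** Yield deltas are truncated normals on
[−0.5, 0.5] with means/SDs chosen once from the field literature's
headline ranges: no-till +2 % ± 6 (positive-to-neutral, high variance),
ISFM +8 % ± 8, NUE +6 % ± 5, AWD −2 % ± 4 (lower-to-no yield change). Both
signs occur for every practice, which is what makes the adoption rules
non-trivial filters. SOC deltas: +0.15/+0.20/+0.02/0.00 t C/ha/yr
(SD 0.10/0.15/0.02/0.02). ISFM adds lognormal ~15 kg N/ha of organic
amendment on top of baseline manure; NUE applies 20 % less mineral N for
the same uptake (deep urea placement); AWD switches irrigated rice to
multiple drainage. The two pseudo-climate paths differ in an additive
offset to practice yield-delta means (0 vs −0.5 pp for the hotter path)
and in per-FPU×crop baseline yield trend modifiers (normal, mean
−0.1 %/yr vs −0.3 %/yr, SD 0.2 %/yr).

**What the generator does not emulate:** real spatial autocorrelation,
crop-model physiology (responses are draws, not simulations), actual
country yield/input distributions, multi-cropping, or any raster
geography. Passing tests therefore demonstrate that the *logic* — rules,
ledgers, equilibria, orderings — is correct and stable under realistic
heterogeneity; they say nothing about the magnitudes real data would give.

**Macro paths** are SSP2-style: population 0.6 %/yr from a 6.9-billion
base split by a Dirichlet draw; per-capita income 2 %/yr from lognormal
country bases. Growth rates are constant over 2010–2050.

## 2. Adoption rules

Implemented exactly at the grid-cell level, with full (100 %) adoption of
the chosen practice where a rule is satisfied:

- **Rule 1**: adopt the compatible candidate with the largest yield delta,
  provided it is strictly positive ("higher yields" is read strictly;
  equality retains the current practice).
- **Rule 2**: Rule 1 plus a strict decrease in cell-level emission
  intensity; cells whose BAU or candidate output is non-positive have
  undefined intensity and fail the comparison rather than erroring.
- **Rule 1 + rates**: decisions as Rule 1, adopted area scaled by a
  country×practice cap. The shipped default caps (no-till 0.40, ISFM 0.30,
  NUE 0.35, AWD 0.25, uniform across countries) are synthetic placeholders
  — the survey-based table they stand in for is not published at this
  granularity.
- **Rule 2 + AWD economics**: Rule 2, except AWD is also eligible when its
  yield decline is smaller than the break-even
  *d\** = irrigation-cost share × cost reduction × cost/revenue ratio
  (defaults 0.30 × 0.30 × 1.0 = 9 %), derived from equating the revenue
  loss of a yield decline with the irrigation-cost saving at cost ≈
  revenue.

Ties on yield delta break on a fixed practice order (no_till < isfm < nue
< awd), then cell id, so decisions are deterministic and invariant to
candidate row order. No-till is never offered in the six excluded
countries (a configurable country-id set; the generator picks 6 of 15).
Rule 2's eligible set is a subset of Rule 1's by construction, which is
the tested subset invariant.

## 3. Tier-1 emission ledger

All factors live in one config block (`EmissionFactors`), defaults:

| parameter | value | meaning |
|---|---|---|
| ef_n_mineral / organic / mineralized | 0.01 | N₂O-N per unit N input |
| ef_n_residue | 0.007 | residue channel (switchable to 0.01) |
| ef_n_flooded | 0.003 | flooded rice, applied N only by default |
| ch4_ef_base | 1.3 kg CH₄/ha/day | Tier-1 baseline |
| sf_continuous / sf_multiple_drainage | 1.0 / 0.52 | water-regime scaling |
| straw_param | 0.59 | exponent of organic-amendment scaling |
| cfoa_fym | 0.14 | farmyard-manure conversion factor |
| gwp_ch4 / gwp_n2o | 28 / 265 | GWP₁₀₀ (AR5) |

Interpretation choices worth recording: the residue-N factor uses the
residue-specific 0.7 % rather than the generic 1 % (one config field flips
it); the straw parameter 0.59 is read as the exponent of the IPCC-2006
organic-amendment scaling (1 + ROA_straw + 0.14·ROA_fym)^0.59 with straw
conversion factor 1; the flooded-soil N₂O factor covers applied N
(mineral + manure) with a switch to include mineralized N; the baseline
CH₄ factor carries kg CH₄ ha⁻¹ day⁻¹ units. N₂O-N→N₂O uses 44/28, SOC
C→CO₂ uses 44/12; SOC gains are negative emissions. Indirect N₂O
(volatilization, leaching) and process-based soil chemistry are out of
scope; SOC deltas are exogenous inputs, annualized.

Emission intensity is CO₂e per tonne of fresh output at the cell's
(possibly shifted) yield; it is flagged undefined (NaN) rather than raised
when output is non-positive. Aggregation multiplies per-ha totals by areas
and partitions exactly across cell/FPU/country/world.

## 4. Tailoring

The FPU×crop distribution of adopted yield deltas, weighted by adopted
area (a count-weighted switch exists), is summarized by three quartile
means. Convention on the weighted empirical CDF *F*: the lower-quartile
set is {x ≤ Q1} with Q1 = inf{x : F(x) ≥ 0.25}; the upper-quartile set is
{x ≥ Q3} with Q3 = inf{x : F(x) > 0.75}. The asymmetry (≥ vs >) makes both
sets non-empty for any sample, reproduces the natural four-point example
(poor 1 %, average 2.5 %, optimal 4 % from {1, 2, 3, 4} %), degenerates
correctly when all gains are equal, and preserves poor ≤ average ≤ optimal
always. A sort-and-slice oracle in the test suite pins this convention.

The adoption set is fixed across tailoring levels; only the realized gain
varies. Shifters enter the market in growth mode by default (supply-curve
growth-rate entry): the annualized increment (1+s)^(1/40) − 1 is
*compounded* onto the BAU yield growth, g' = (1+g)(1+s)^(1/40) − 1, so the
2050 yield ratio versus BAU is exactly 1+s. A level mode (first-year
multiplier) is also supported. Before entering the market, the FPU shifter
is scaled by the FPU's adopted production share and production-weighted up
to the country, so a country where little area adopts sees little shift.

## 5. Partial-equilibrium market

Log-linear (constant-elasticity) supply and demand per country×crop:
supply = base_area·P^εₛ × yield(t), demand = base_demand·pop(t)·
(income pc ratio)^η × P^ε_d, with defaults εₛ = 0.25, ε_d = −0.35, income
elasticities 0.15/0.20/0.25 (maize/wheat/rice) and exogenous yield growth
0.8 %/yr plus the climate trend modifier. One world price per crop clears
Σsupply = Σdemand (net-trade closure; no bilateral flows, no cross-price
terms, so crops clear independently). Demand intercepts are calibrated at
generation time so every base-year world price is exactly 1.

Area responds to the **current-year** world price: the clearing operation
is defined as finding P with supply(P) = demand(P), and the closed-form
single-region oracle P* = (b/a)^(1/(εₛ−ε_d)) — which the solver must match
— only exists under contemporaneous response.

**Solver.** Damped Newton-like fixed point on log price (step
0.9·(log D − log S)/mean-elasticity-spread), with an adaptive-bracket
Brent fallback; excess demand is evaluated with `logsumexp` so extreme
instances (log-price magnitudes in the hundreds) neither overflow nor lose
the bracket. Tolerance: relative excess demand < 1e-10; non-convergence
raises a diagnostic error carrying the year and last residual. Market
clearing is tested to |Σ net trade|/production < 1e-6 on every crop-year,
and the solver is tested against the closed form on 10 000 random
one-region instances.

**Livestock link.** A global herd responds to a feed-price index
(feed-share-weighted mean of maize/wheat prices; feed shares 0.50/0.20/
0.02) with constant elasticity −0.3 around a 1.5-billion-head base at
1.8 t CO₂e/head/yr. This reduced form captures the sign and mechanism of
the feed-price feedback only; its magnitude scales with the synthetic
world and is not comparable to full-model results.

## 6. Food security

kcal/capita/day = Σ consumption × energy density (3.58/3.34/3.60 Mkcal/t)
/ population / 365, three crops only — a deliberate understatement of
total diets, which is why availability is always used *relative* to the
base-year world average of the same measure (the configurable reference).
Hunger share = clip(s₀·availability^(−η), 0, 1) with per-country anchors
s₀ ~ U(0.04, 0.25) and η = 2: the simplest strictly decreasing,
correctly anchored form. Child undernourishment is a linear index in
kcal (coefficient −0.06 per 1000 kcal), education, life-expectancy ratio
and sanitation, clipped to [0, 1], times the under-five population (10 %
of total); the non-food covariates follow linear exogenous improvement
paths, standing in for socioeconomic-pathway drivers.

## 7. Scenario matrix and reporting

`build_matrix` enumerates 2 BAU + 4 schemes × 2 climates × 3 tailoring
levels = 26 runs in a fixed order. Each run re-uses a cached BAU
trajectory per (climate, climate-flag). Emission totals per year multiply
the blended per-ha ledger (BAU and adopted practice mixed by adopted
fraction) by cell areas scaled along the market's country×crop
harvested-area path; the reported abatement is the 2010–2050 mean of
BAU-minus-scenario. The no-climate-change flag zeroes the trend modifiers
of both the scenario and its BAU comparator. Summaries report, per scheme
and metric, the across-climate mean at average tailoring and the min–max
over all climate × tailoring runs; missing combinations are flagged, not
fatal. Every run can be persisted as CSVs plus a manifest (spec, seed,
config hash).

## 8. Problem sizes and determinism

Library defaults (2000 cells) run the full 26-run matrix in well under a
minute. The test suite uses 250–400-cell worlds for end-to-end checks and
10 000 cells/instances where a sampling or oracle property needs the
resolution; these sizes were chosen so the whole suite exercises every
stage at meaningful heterogeneity while staying fast enough to run on
every change. All randomness flows from `numpy.random.default_rng(seed)`;
identical `(config, seed)` reproduce every table bit-for-bit, and
property tests run derandomized.

## 9. Known limitations

- Responses are statistical draws, not crop-model output: no soil/weather
  covariance, no within-FPU spatial correlation (exposed as free
  parameters rather than guessed).
- One world price per crop; no bilateral trade, trade costs, stocks, or
  cross-price substitution; land competition between crops is not
  modelled (area responds to own price only).
- No indirect N₂O, no process-based SOC dynamics, no cultivar effects,
  no carbon-fertilization response.
- Hunger and child-undernourishment parameters are stylized forms with
  synthetic coefficients; levels are not calibrated to any country.
- Adoption is static (first-year, no diffusion dynamics) and driven by
  yield/intensity only; the rate caps are placeholders.
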