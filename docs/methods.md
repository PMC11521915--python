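# Methods

## The payment model

A district hospital's annual payout is the sum of three prospectively
determined streams.

**Outpatient: risk-adjusted global budget.** Annual outpatient cost is
modelled as a linear function of demand- and supply-side district
covariates,

```
cost = β₀ + β_t2·[tier 2] + β_t3·[tier 3] + β_pop·pop + β_beds·beds
         + β_imr·IMR + β_age·age% + β_util·util%
```

with tier-1 cities as the reference level of the city-type factor.
Covariates and units: district population in **lakhs** (the coefficient
magnitude of the published set, ₹60,858 per unit, is only consistent with
lakhs; the unit is configurable), bed strength in counts, infant mortality
rate in deaths per 1,000 live births (the population health-need proxy),
the percentage of population under 5 or over 60, and the percentage
utilisation of public facilities. The model is fitted by ordinary least
squares; `canonical_model()` exposes the published coefficient set
(intercept ₹75.4M; tier-2 −₹34.3M; tier-3 −₹51.4M; ₹89,121/bed;
₹565,977/IMR unit; R² 0.5603) for allocation without refitting. Negative
predictions — possible for small tier-3 hospitals with a high young/old
share — are floored at a configurable minimum (default 0) with a logged
warning; the behaviour of the original allocation rule in this corner is
unspecified, and a floor is the only choice that keeps payouts meaningful.

Diagnostics follow the standard battery: normality of the regressand and of
the residuals by the Kolmogorov–Smirnov test in its Lilliefors form
(parameters estimated from the data — a plain KS test against a fully
specified normal would be anti-conservative); homoscedasticity by the
Breusch–Pagan LM test; multicollinearity by variance inflation factors.
Plain (non-robust) OLS standard errors are reported, since homoscedasticity
is an explicitly tested assumption of the model.

**Inpatient: case-based bundled payment.** Expected annual admissions in a
specialty are `beds × bed_share × BOR × 365 / ALOS`. Admissions are kept
fractional through the costing (rounding is a report-layer concern;
rounding inside the sum would introduce order-dependent bias). Each
specialty's admissions split into an insured portion priced through a
health-benefit-package tariff table with a within-specialty case-mix, and a
remainder priced at the specialty's weighted average cost per admission
(packaged values: Paediatrics ₹10,415 … Ear Nose and Throat ₹14,104; any
non-negative weighting of the seven specialties therefore lies in
[₹9,867, ₹14,104]). Tariff values are taken to embed the economic-cost
convention — full recurrent cost plus 20% of capital — and
`economic_cost()` applies that rule when tariffs are built from raw
components. The budget is exactly linear in beds.

The actual national tariff list is not redistributable; the packaged
default carries two representative packages per specialty whose
case-mix-weighted mean sits near the specialty's non-insured cost level,
and users supply the real list as CSV.

**Indirect services: per-bed global budget.** `beds × rate`, with the
secondary rate ₹163,969/bed/year and the tertiary (medical-college) rate
₹294,441/bed/year. `estimate_per_bed_rate` recovers a rate from facility
records as the pooled ratio Σcost/Σbeds — pooling weights hospitals by
size, which is what an "average annual cost per bed" across a sample means;
a mean of per-hospital ratios would weight a 50-bed and a 700-bed hospital
equally.

## Upgrade scenarios

**IPHS.** Staffing is brought to a norms table (a step function of beds
over three cadres: doctors, paramedical, support); the shortfall is priced
at current salaries with `max(0, required − current)` per cadre, so a
surplus in one cadre never offsets a deficit in another. Capital upgrading
is financed at one-fifth of the existing capital stock per year (capital
projects absorb outlay gradually). Drugs and consumables grow with volume,
which the model captures by recomputing the inpatient stream at
`beds × uplift`; the uplift defaults to 1.0, with a documented preset of
2.3 consistent with the roughly 2.3-fold rise in mean inpatient payout
reported for this scenario. Shortfall and capital costs are attributed to
the outpatient stream by default (`op_shortfall_split = 1.0`, matching the
reported outpatient jump in this scenario), configurable toward inpatient.
The indirect stream is unchanged, consistent with the near-identical
indirect means reported for the base and IPHS cases.

**Medical college.** The hospital moves to tertiary pricing: a tertiary
outpatient coefficient set, tertiary tariffs, and the tertiary per-bed
indirect rate. The tertiary regression is not redistributable; when absent,
a clearly labelled synthetic placeholder (all secondary coefficients scaled
by 1.06) is used and the payout carries a `placeholder-tertiary-model`
provenance flag — the 1.06 factor is what the three reported scenario
uplifts (total +91.5%, inpatient +123%, indirect +79.6%) jointly leave for
the outpatient stream. Tertiary tariffs default to the secondary tables
scaled by 2.23, the ratio implied by the reported 123% inpatient uplift;
explicit tertiary tables override both.

## Synthetic data

The generator emulates the structure of the facility costing dataset the
analysis assumes, in two stages.

*Base sample* (default 27 hospitals: 5/9/13 in tiers 1/2/3). Covariates are
drawn uniformly from plausible Indian district-hospital ranges — population
3–90 lakhs, beds 100–700, IMR 15–60, young/old share 16–28%, utilisation
20–60% — identical across tiers: the tier classifies the *city*, and tying
district covariates to it would manufacture collinearity between the tier
dummies and population/beds that the design is reported not to have (all
VIFs between 1 and 5; the residual VIF of ~3.8 on the tier dummies is the
unavoidable consequence of a 7/29/64 mix of three mutually exclusive
levels). Outpatient cost is the exact linear predictor of a configurable
truth (default: the published coefficient set) plus N(0, noise_sd²) noise;
the default noise SD of ₹20M makes the fitted R² ≈ 0.56–0.62 on the default
design, matching the published fit quality. Inpatient, indirect and capital
costs scale with beds (≈₹876k, ₹163,969 and ₹2M per bed respectively, with
lognormal dispersion), and staffing headcounts scale at 0.18/0.55/0.40 per
bed for doctors/paramedical/support — below the packaged norms table, so
the IPHS scenario exhibits a genuine staffing shortfall.

*Expansion.* Per tier, the mean vector and covariance of all twelve numeric
facility fields (four district indicators, beds, three staffing counts,
four cost components) are estimated and the covariance shrunk by
Σ' = (1−λ)Σ + λ·diag(Σ) (default λ = 0.1) before multivariate-normal
sampling — without shrinkage the 5-record tier-1 stratum is singular, and
the sampler raises an explicit error advising shrinkage when λ = 0. Sampled
values are clipped to their physical bounds (beds ≥ 1, costs ≥ 0,
percentages in [0, 100]); specialty bed shares, being compositional, are
carried over as the tier's renormalised mean profile rather than sampled. A
resampling-with-replacement alternative (`expansion_method="bootstrap"`) is
provided, since small-sample expansion is described both ways in the
provider-payment literature. The default expansion is 7/29/64 = 100
records.

*National registry* (default 845 hospitals). Same covariate generator, tier
mix 7/29/64%, state labels from a fixed 20-state list.

**What the synthetic data does not emulate:** the true joint covariance of
Indian district-hospital costs and indicators, state-level clustering of
costs, the real bed-size distribution, or the real insured/non-insured case
split. Passing tests therefore demonstrate that the *machinery* —
estimation, allocation, scenario arithmetic, rollup — is correct under
known conditions; national aggregates computed on synthetic inputs (e.g. a
mean payout of ≈₹500M rather than the ≈₹326M obtained on the real data) are
properties of the synthetic conditions, not re-estimates of the published
ones. Quantities that do not depend on the unavailable data — coefficient
arithmetic, currency conversion, ratio/uplift arithmetic, the 123%
inpatient uplift under the 2.23 tariff multiplier — are reproduced exactly.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds (child streams via `SeedSequence`); no global state. Identical
  seed + config ⇒ byte-identical output.
- Rank of the OLS design is checked before fitting; a singular design
  raises an error naming the redundant columns rather than silently
  pseudo-inverting.
- In a noiseless fit the Breusch–Pagan auxiliary regression is vacuous;
  the diagnostic reports p = 1 instead of dividing by a zero residual
  scale.
- Currency: ₹82.54 per US$ (January 2024 average); conversion is exact and
  unrounded, display rounding happens in reports.
- Rollup reports raw values; rounding ratios to one decimal and shares to
  whole percentages is a presentation convention.
- Monte-Carlo suite sizes: 200 replicates for the 3-SE recovery check, 500
  for CI coverage and Breusch–Pagan calibration, 1,000 weight vectors for
  the specialty-cost bracketing property — sizes at which the binomial
  error of each estimated rate is comfortably inside the asserted band.

## Known limitations

- Coefficients refitted on an MVND-expanded sample drift from the base
  truth (shrinkage attenuates covariances and tier means are re-estimated
  from few records); recovery guarantees hold for the base generator, which
  is why parameter-recovery tests use it directly.
- Hospitals with zero actual expenditure are excluded from percentage
  comparisons (with a logged count); the deviation formula is undefined
  there.
- The comparison driver's synthetic "actual expenditure" table is a
  labelled stand-in; only user-supplied expenditure data make that
  comparison meaningful.
- No uncertainty propagation from the regression into payouts, and no
  alternative regression families (GLM-gamma, quantile) — the framework is
  a point-allocation rule.
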