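# hospfin — blended provider-payment simulation for district hospitals

Public-sector district hospitals in India are largely financed through
historical line-item budgets that ignore both the health needs of the
population served and the volume of care delivered. `hospfin` implements a
**blended provider-payment framework** that replaces the historical budget
with three complementary streams, and the simulation machinery needed to
study its fiscal consequences nationally:

1. **Outpatient care — risk-adjusted global budget.** A prospective annual
   budget from a multiple linear regression of outpatient cost on district
   covariates (tier-1 city reference):

   `cost = β₀ + β_t2·[tier 2] + β_t3·[tier 3] + β_pop·population +
   β_beds·beds + β_imr·IMR + β_age·age% + β_util·utilization%`

   The package both fits this model by OLS (with Kolmogorov–Smirnov,
   Breusch–Pagan and VIF diagnostics) and ships the published coefficient
   set (`canonical_model()`) so budgets can be allocated without refitting.
2. **Inpatient care — case-based bundled payment.** Expected annual
   admissions per specialty follow from bed capacity,
   `beds × bed_share × BOR × 365 / ALOS`; insured admissions are priced
   through a health-benefit-package tariff table with a case-mix, the rest
   at specialty-level weighted average costs.
3. **Indirect services — per-bed global budget.** Administration,
   registration, governance, biomedical waste, laundry and dietetics scale
   with hospital size: `beds × rate`, with rates of ₹163,969/bed/year for
   secondary hospitals and ₹294,441 for medical colleges.

Because the underlying facility costing data are not publicly deposited,
the package includes a first-class synthetic-data module: a stratified base
sample whose outpatient cost obeys a known linear truth, a tier-wise
multivariate-normal expansion (7/29/64 records across city tiers 1/2/3,
100 in total) with covariance shrinkage, and an 845-hospital national bed
registry. Everything downstream is exercised and tested against it; real
facility tables can be supplied as CSV in the documented schema.

Intended users: health-financing researchers and health-economics analysts
studying provider-payment reform, strategic purchasing and budget-impact
analysis in low- and middle-income settings.

## Worked example

```python
from hospfin import DistrictIndicators, canonical_model, predict_outpatient_budget
from hospfin import default_specialty_profiles, default_tariff_table
from hospfin import default_specialty_costs, inpatient_budget, indirect_budget
from hospfin import IndirectRateConfig

district = DistrictIndicators(
    district_id="EX", state="Tamil Nadu", city_tier=3,
    population=20.0,          # lakhs
    imr=40.0,                 # infant deaths per 1,000 live births
    pct_young_old=20.0, pct_public_utilization=30.0,
)
beds = 300

op = predict_outpatient_budget(canonical_model(), district, beds)
ip = inpatient_budget(beds, default_specialty_profiles(),
                      default_tariff_table(), default_specialty_costs())
ind = indirect_budget(beds, IndirectRateConfig().rate_base)
print(f"outpatient {op:,.0f}  inpatient {ip:,.0f}  indirect {ind:,.0f}")
```

prints

```
outpatient 40,521,170  inpatient 290,804,712  indirect 49,190,700
```

i.e. a 300-bed tier-3 hospital in this district receives an annual
outpatient global budget of ₹40.5 million (the published coefficients
evaluated term by term), a case-based inpatient budget of ₹290.8 million
(expected admissions in seven specialties, split between insured tariffs
and non-insured weighted costs), and ₹49.2 million for indirect services
(300 beds × ₹163,969).

## Analysis pipeline

The numbered drivers under `analysis/` reproduce the full study flow and
write their tables under `results/`:

```bash
python analysis/01_simulate_facilities.py --seed 1   # base 27 → 100 + registry
python analysis/02_fit_outpatient_model.py           # OLS fit + diagnostics
python analysis/03_national_budget_impact.py         # 845-hospital rollup
python analysis/04_scenarios.py                      # IPHS / medical-college
python analysis/05_compare_payouts.py                # vs actual expenditure
```

`04_scenarios.py --scenario iphs|medical-college|base` selects a single
scenario; norms, salaries, tariffs and cost tables are all replaceable by
CSV inputs.

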