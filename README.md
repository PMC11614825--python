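# campcost

Micro-costing of integrated vaccination campaigns and routine immunization
delivery, built around Malawi's 2023 introduction of typhoid conjugate
vaccine (TCV) through a four-intervention campaign (TCV, measles–rubella
vaccine, bivalent oral polio vaccine, vitamin A supplementation).

The package is aimed at health economists and immunization-program analysts
who need to go from raw line-item cost records and dose ledgers to
defensible per-dose delivery costs — and at methodologists who want a
tested, reproducible implementation of the estimators behind such studies.

## What it computes

Costs are recorded bottom-up as line items (quantity × unit cost in
Malawian Kwacha, flagged as direct expenditure or opportunity cost),
converted to 2020 US$ at the official rate (749.53 MWK/US$), and summed
into activity × cost-type matrices per health-system unit. Capital is
annualized with an annuity factor at discount rate r over useful life L:

    annual cost = price / A(r, L),   A(r, L) = (1 − (1+r)^−L) / r,  A(0, L) = L

**Campaign cost per dose.** Each sampled unit contributes the ratio
cᵢ = (total cost)ᵢ / (total doses)ᵢ. At the facility level the estimate is
the design-weighted mean ȳ_w = Σwᵢcᵢ / Σwᵢ with weights from
size-proportional sampling, with a normal-approximation CI from the
design-weighted variance of the weighted mean; the single national unit is
an exact ratio without a CI. Levels combine by summing point estimates and
(by default) interval bounds.

**Routine TCV cost per dose.** Annual routine program costs are allocated
to one TCV dose by cost type: dose-proportional pools (meetings, per diem,
supplies, human resources, printing) divide by total doses delivered;
volume-proportional pools (transport, fuel/maintenance/energy, capital
equipment) divide by total packed vaccine volume (cm³) and multiply by the
packed volume of one TCV dose.

**Standalone-campaign scenarios.** Base/low/high scenarios rescale each
activity's cost by TCV's dose share, volume share, or a fixed fraction,
and divide by TCV doses — bounding what a TCV-only campaign would have
cost.

A synthetic-data module generates full study bundles (50 facilities in 10
districts in 3 zones plus a national unit, with size-proxy PPS survey
designs) calibrated to the published cost and dose magnitudes, so every
stage is testable without access to the unreleased unit-level data.

## Worked example

```sh
campcost synth campaign --seed 1 --out data/campaign
campcost campaign data/campaign --out results/campaign
```

prints the per-level and combined cost-per-dose table (2020 US$):

```
     level     basis  n_units  mean_cost_usd  mean_doses  cost_per_dose_usd  ci_low_usd  ci_high_usd
  facility financial       50         300.48    28591.66               0.01        0.01         0.01
  district financial       10      201634.98   743353.30               0.27        0.22         0.33
  national financial        1     3313164.35 15235388.00               0.22         NaN          NaN
  facility  economic       50        8832.73    28591.66               0.35        0.24         0.45
  district  economic       10      206535.37   743353.30               0.28        0.22         0.34
  national  economic        1     3332099.30 15235388.00               0.22         NaN          NaN
all_levels financial       61            NaN         NaN               0.50        0.44         0.56
all_levels  economic       61            NaN         NaN               0.85        0.69         1.00
```

Reading it: the 50 sampled facilities delivered ~28,600 doses each at a
weighted mean financial cost of $300 — one cent per dose of direct
spending, but $0.35 per dose once the opportunity cost of existing staff
time is counted (economic basis). Districts carry most direct spending
(vaccinator per diems are recorded there), and the combined campaign cost
per dose across levels is $0.50 financial / $0.85 economic for this seed.
`campcost scenarios` and `campcost routine` produce the standalone-TCV
scenario table and the routine TCV cost-per-dose table the same way. The
same operations are available as library functions
(`run_campaign_analysis`, `run_routine_analysis`, `run_scenarios`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a campaign and a routine bundle at the default configuration,
runs all three analyses end to end from scratch, prints the summary
tables, and writes the results JSON.
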