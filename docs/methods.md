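# Methods

## Cost model

Every resource use is a line item: quantity × unit cost in Malawian Kwacha
(MWK), located at a health-system unit (facility, district, zone, or
national), in a program activity (training, service delivery, supervision,
…) and a cost type (per diem, human resources, fuel, …), flagged as direct
expenditure or opportunity cost. Conversion to 2020 US$ (749.53 MWK per
dollar) happens before any aggregation, so all downstream arithmetic is in
one currency. Commodity costs (vaccines, vitamin A tablets, syringes,
safety boxes) are out of scope by design; "supplies" excludes them.

Financial cost is the sum of direct-expenditure lines; economic cost adds
opportunity costs and annualized capital, so economic ≥ financial holds
cell-wise for any valid unit. The financial/economic distinction lives on
the line item, not the cost type, because the same cost type can be either
(hired campaign staff are a financial cost; seconded staff an opportunity
cost).

### Capital annualization

Capital purchases are spread over their useful life with an annuity factor
A(r, L) = (1 − (1+r)^−L)/r at discount rate r (default 3%/yr), with the
zero-rate limit A(0, L) = L handled analytically. Annuity annualization
rather than straight-line depreciation is the convention in immunization
costing guidance; the two coincide as r → 0. Capital is an economic-only
cost unless an asset is flagged as a campaign-period purchase. A campaign
carries a configurable fraction of the annual equivalent
(`campaign_capital_fraction`, default 1/12 for a one-month campaign); a
routine year carries the full annual cost. Whether the source study
period-apportioned or expensed campaign capital is not documented; both
are representable and the default is an explicit assumption. Capital rows
are attributed to the distribution & storage activity (vehicles and
cold-chain equipment), also configurable.

## Survey estimation

Facilities are a stratified size-proportional (PPS) sample; the design
weight is the reciprocal inclusion probability, with the number of
first-dose MRV doses as the size proxy. The per-dose cost estimator is the
weighted mean of per-unit ratios (mean of ratios, not ratio of means),
matching a "weighted mean cost per dose" reading; the ratio-of-means
alternative is available for sensitivity. Units with zero doses are
excluded from per-dose estimation (the ratio is undefined) but retained in
cost totals, with a logged warning.

Confidence intervals use a normal approximation with the design-weighted
variance of the weighted (Hájek ratio) mean,
n/(n−1) · Σ w̃ᵢ²(xᵢ − x̄_w)² with normalized weights w̃ᵢ, which reduces to
s²/n under equal weights. The source tables print 95% CIs without stating
a method; this choice is transparent and testable (Monte-Carlo coverage is
part of the suite) and is flagged in reports. Strata are ignored in
variance estimation. No finite-population correction and no bootstrap.

Cross-level combination sums the per-level point estimates; interval
bounds are summed too, treating levels without an interval (national,
n = 1) as constants — demonstrably the arithmetic behind the published
combined cells (e.g. 0.01+0.27+0.14 = 0.42 and 0.02+0.41+0.14 = 0.57).
A quadrature (variance-sum) combination is available behind
`combine_ci_method`. Reported dollars are rounded half-up to cents only at
the reporting layer, after combination — required to reproduce the
published cross-footing exactly.

## Routine allocation

Routine 2022-style program costs are shared across antigens. Cost types
are allocated to one TCV dose by rule: meetings, per diem, supplies,
human resources → divide by total doses delivered; vehicle rental and
transport, fuel/maintenance/energy, capital equipment → divide by total
packed vaccine volume and multiply by TCV's packed volume per dose.
Printing/stationery is not assigned to either group in the source text; it
defaults to dose-proportional (it scales with forms per child) and is
overridable. "Volume of vaccines delivered" is interpreted as
Σ(doses × packed cm³ per dose); packed wastage and vial overage are not
modelled. The incrementality assumption is replicated as stated: routine
costs for other antigens do not change when TCV is added.

TCV's packed volume per dose is required configuration — the source never
prints it. The shipped default (3.0 cm³/dose, a 5-dose-vial class figure)
is a documented placeholder, not a measured value.

## Scenarios

Base: every campaign activity scales with TCV's dose share except
distribution & storage, which scales with TCV's volume share. Low: 25% of
every activity's cost, keeping base rules for service delivery and
distribution & storage. High: 100% of every activity, keeping base rules
for service delivery and waste management. "Similar assumption to the base
case for service delivery" is interpreted as keeping the base rule for
that activity (the detailed per-activity assumptions live in an
unavailable supplement); rules are config-overridable. Scaling is applied
per sampled unit before weighted estimation so CIs propagate through the
same machinery, and denominators are each level's TCV doses. Whenever the
dose share ≥ 0.25 (Malawi: ≈0.46), totals are ordered low ≤ base ≤ high;
with both shares equal to 1 the base and high scenarios reduce exactly to
the integrated analysis with a TCV-dose denominator (the low scenario does
not, by construction of its fixed 0.25 fractions).

## Synthetic data

The generator emulates the study structure: 50 sampled facilities (from a
frame of 800) in 10 districts in 3 zones plus one national unit; four
campaign interventions at the published dose magnitudes; activity and
cost-type mixtures that reproduce the published composition (service
delivery dominant at facilities, human resources ~94% of facility economic
cost, per diem dominant at district and national level). Vaccinator per
diems are generated at the district level, replicating the study's
data-collection quirk, so aggregation is tested against realistic
mis-leveling. Zones carry only routine records.

Distributions: costs are log-normal around the published means (positive,
right-skewed); doses are negative-binomial. Published tables give means
but no dispersions, so these are assumptions fixed once: SD of log cost
0.5 (a plausible ~2.5-fold interquartile spread across facilities, echoing
the wide published workforce range of 4–338 persons), negative-binomial
size k = 8 (dose-total CV ≈ 0.35 per intervention). Workforce records use
log-SD 0.9 for persons involved (mean 77) and an overdispersed negative
binomial for hires (mean 17, k = 0.6), reproducing min–max ranges of the
published order. Setting `cost_sigma=0` and `dose_dispersion=None` yields
the degenerate world with every unit exactly at its mean.

Routine dose throughput is not published. Defaults are a realistic Malawi
EPI year that cross-foots across levels: ~12,000 doses per facility per
year over seven antigens (≈750-infant birth cohort per facility), ~331,000
per district, ~1.92M per zone, 9.6M nationally (800 facilities, 29
districts, 5 zones).

What a green test does and does not establish: generated bundles exercise
every reader, validation rule, estimator, and allocation path at the
published magnitudes, and parameter-recovery tests show the estimators are
unbiased with ~95% interval coverage under the stated world. They do not
establish that the generator matches the true (unreleased) facility-level
joint distribution — real data have spatial structure, ownership effects,
and cost–size correlations the generator deliberately omits. Published
scenario point estimates and level totals that depend on the unit-level
data are therefore calibration references, not test targets.

## Numerical choices

- Internal arithmetic is full double precision; rounding half-up to cents
  happens only in report tables, after cross-level combination.
- Zero-dose units: excluded from ratios, retained in totals, warned.
- Zero-variance inputs give zero-width CIs; n = 1 levels give no CI.
- PPS inclusion probabilities are capped at 1 by iterative rescaling
  (certainty units removed, remainder re-scaled); systematic PPS sampling
  on a randomly permuted order gives fixed sample size without
  replacement.
- Seeds: every stochastic routine takes an explicit seed or
  `numpy.random.Generator`; identical seeds give byte-identical CSVs.

## Known limitations

- The CI method and the bound-summing combination are modelling choices
  made for transparency; they are not guaranteed to match the source
  study's unstated method, and bound-summing has no frequentist coverage
  guarantee for the combined estimate.
- Variance estimation ignores strata and any weight–value correlation
  beyond what the Hájek linearization captures.
- The 2020 exchange rate is applied to later-year expenditures without
  deflation, replicating the stated conversion verbatim.
- No wastage, cold-chain capacity, payer attribution, or coverage
  denominators.
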