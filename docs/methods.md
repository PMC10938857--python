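# Methods

## Study design

The pipeline implements a prevalence-based matched case-cohort design on
person-level register tables.

**Follow-up.** Every person contributes the half-open interval
`[max(2004-01-01, birth, immigration), min(death, 95th birthday,
emigration, 2017-04-23))`.  Degenerate intervals are dropped.  Cost data
exist for calendar years 2004–2017; the averaging denominator for "annual"
estimands is the sum of yearly window fractions, `13 + 112/365 ≈ 13.31`
(the final year is partial).

**Cases.** A case for disorder *d* is a person whose first hospital contact
(inpatient, outpatient or emergency) carrying an ICD-10 code under one of
*d*'s code prefixes, at or above *d*'s assumed earliest onset age, falls in
1995–2017.  ICD-10 matching is by prefix after stripping dots and
upper-casing, so `F32` covers `F32.1` and the undotted dialect `F321`.  A
person is a case once per disorder but may be a case for several disorders;
"any mental disorder" is a 19th definition whose code set is the union of
the 18 disorder code sets (earliest onset = the minimum).  The bundled code
sets and onset ages are standard F-chapter prefixes with plausible onset
floors; they are configuration, not doctrine — supply a catalogue file to
override them.

**Matching.** Each case receives up to 10 controls drawn uniformly at
random from persons of the same sex with birthdate within ± 2 *calendar*
months (same day-of-month two months away, clamped to month end), alive and
resident on the index date, and without a qualifying index-disorder
diagnosis on or before the index date.  Controls may be reused across sets
but not within one; a control later diagnosed keeps their control role
(eligibility is assessed at the index date only — incidence-density
sampling); controls are censored by their own death/emigration and are not
replaced.  Sets with fewer than 10 eligible candidates are kept and logged
as deficient.  Sampling uses a per-case substream keyed by (seed, disorder,
case id), so matched sets are reproducible and independent of input row
order.  A configuration switch (`control_history_rule="ever"`) instead
requires controls to be disorder-free for their entire registered history.

**Money.** All register amounts are nominal local currency attributed to
the calendar year of the register row.  `to_eur2017` multiplies by the
GDP-deflator ratio (reference year over cost year) and divides by the 2017
average exchange rate (default 7.4386 local units per Euro).  The deflator
series bundled as a default is a plausible stand-in and should be replaced
by the official series for production use.  Per person-year:
`rx_subsidised = max(service − out_of_pocket, 0)` (negative inputs are
floored and logged; annual registers cannot produce them),
`healthcare = psych DRG + somatic DRG + rx_subsidised + primary care`
(out-of-pocket is carried separately and excluded), `transfers_total` is
the sum of the nine transfer components.  Person-time is prorated within
years; amounts are not (the registers are annual).

## Estimands

For each disorder, component, cost kind (absolute / excess) and stratum
(overall, sex, 5-year attained-age band at 1 July):

* **nationwide annual** — sum of the per-year totals over 2004–2017 divided
  by the summed window fractions (13.31).  Stratified values sum exactly to
  the overall value because each case-year belongs to one stratum.
* **per-case annual** — total over follow-up divided by case person-years.
  A `per_case_weighting="persons"` switch averages per-case ratios instead.
* **per-capita annual** — nationwide annual divided by the population
  denominator of the stratum on 1 January 2017 (zero denominators omit the
  estimate, logged).

The **excess** value of a set-year is the case's annual amount minus the
*equal-weight* mean over the set's controls with follow-up time in that
year.  Equal weights are deliberate: an annual register amount already
scales with the person's own presence in the year (a control who emigrates
in October has ~10/12 of a full-year amount), so weighting controls again
by person-time double-discounts censored controls and biases the reference
— measurably so for near-deterministic components such as flat benefit
entitlements.  Set-years whose controls all lack follow-up time are skipped
for the excess measures (counted in the diagnostics), never imputed.
Income excess is case − control, hence negative when cases earn less.
Excess estimates are invariant to any constant cost shift applied to all
persons.

**Years since diagnosis.** Restricted to cases first diagnosed inside the
follow-up period (cost data do not exist before 2004).  Offset *k* covers
`[index + k years, index + k + 1 years)`.  Because the registers are
annual, a calendar year's excess mixes the one or two offsets it straddles,
and a plain overlap-weighted mean cannot recover the profile at the
diagnosis year: in closed form its offset-0→1 ratio tends to ~1 whatever
the true decay.  The profile is therefore estimated by ordinary least
squares of set-year excess on the offset-exposure design (each row's
exposure to offset *k* is the time inside the offset interval, the calendar
year and the person's alive-and-resident interval).  Exposures use
residency capped at the end of the final study year rather than the
administrative 23 April cut-off, because annual register amounts cover
residency within the year.  Under the generator below the estimator is
unbiased at every offset and the fitted year-over-year ratio recovers the
decay factor.

No standard errors or confidence intervals accompany the study outputs
(the design reports point estimates); `excess_with_se` provides a
matched-set-clustered standard error — optionally with a covariance term
for controls shared between sets — for simulation validation only.

## The synthetic registers

The generator emulates the statistical skeleton of the register setting,
not Denmark itself:

* **Demography** — births uniform over 1930–2016, sex ratio 0.5, mortality
  from a Gompertz-type hazard (`2e-4 + 3.5e-5·e^{0.094·age}`), 6%
  immigrants arriving at a uniform age below 50, emigration hazard
  0.003/year.  All event dates are floored to days; register records exist
  only inside the alive-and-resident interval, and recorded deaths stop at
  the data horizon.
* **Diagnoses** — per-disorder constant first-contact hazards scaled from
  published Danish case counts (≈ 1.5 × 10⁻³/year for major depressive
  disorder down to ≈ 1.6 × 10⁻⁵ for cocaine-use disorder), split by sex
  according to the published female shares, with the clock starting at the
  latest of the onset-age anniversary, residency start and the 1995
  register start.  Each case gets Poisson(0.8) repeat contacts.  Persons
  whose waiting time exceeds the horizon are simply never registered.
* **Baseline costs** (2017 Euro, converted to nominal when written) —
  zero-inflated lognormals per category (e.g. 1.5% of person-years carry a
  psychiatric DRG cost of median e⁷ ≈ 1,100 EUR; somatic costs rise with
  age), prescription out-of-pocket a uniform 10–50% share of the service
  cost, income a work-life age profile × persistent person effect
  (lognormal σ = 0.35) × year noise × employment indicator, and transfer
  components from age rules (child benefit < 18, state pension ≥ 67,
  education grants 18–25, …) with lognormal σ = 0.3 heterogeneity across
  recipients — without that spread the components are near-deterministic
  and stratum-level excess variance degenerates.
* **Injected effects** — per disorder: excess psychiatric cost, excess
  somatic cost, income decrement and transfer increment per case-year, each
  multiplied by `decay^k` at offset *k* and by the offset interval's
  overlap with the year and residency.  The income decrement is floored so
  income stays non-negative; realised decrements are allocated across a
  person's disorders in proportion to their targets.  Every injected amount
  is recorded exactly in the ground truth.  Amounts are written to the
  registers in nominal currency via the inverse deflator, so recovered
  excesses come back on the Euro scale without deflator error.

Defaults are one fixed scenario: sample size 20,000 persons, the hazard
table above, and plausible per-disorder effect magnitudes (e.g.
schizophrenia 12,000 EUR/case-year psychiatric excess with decay 0.92).
One global seed drives stage-wise substreams; identical parameters and seed
give byte-identical register files.

What the generator does **not** emulate: comorbidity correlation between
disorders (diagnoses are independent given age and sex), cost dependence on
proximity to death, age-dependent diagnosis hazards within the onset-age
floor, re-immigration, household structure, and regional or calendar-time
effects.  Passing tests therefore show that the pipeline measures what the
generative model puts in — they do not validate the placeholder catalogue,
the default deflator series, or any substantive claim about real registers.

## Validation against the ground truth

* **Exact expectation by enumeration.** `expected_estimands` sums the
  recorded injections over the case person-years the pipeline observes —
  per person, so comorbid disorders are included — and, when given the
  matched sets, subtracts the control-side contamination (controls
  diagnosed after the index date keep their sets, and their own injected
  costs shrink the measured gap).  The result is the exact expectation of
  the matched excess estimator over the baseline noise; at n = 50,000 the
  psychiatric-cost excess reproduces it to ~0.1%.
* **Monte-Carlo standard errors by replication.** `conditional_mc_se`
  redraws the baseline cost/income stage (a dedicated `cost_stream`
  substream) over the *fixed* population, diagnosis history and matched
  sets, and takes the across-replication spread of each stratum estimator.
  Under heavy-tailed DRG costs a single-realisation plug-in variance is
  itself noisy (observed to range over a factor of ~4 across replicates of
  one stratum), so null- and recovery-checks measure their tolerance
  against the replication SE.
* **Brute-force oracle.** The test suite recomputes every stratum estimate
  on small bundles with an independent pure-Python implementation
  (dict-and-loop date arithmetic, no shared code) and requires agreement to
  1 × 10⁻⁹ relative.

## Numerical and degenerate-input choices

Calendar-month arithmetic clamps the day to the target month's end
(31 Mar − 2 months = 31 Jan; 29 Feb anniversaries fall back to 28 Feb).
Attained age uses `floor((date − birth)/365.25)`; the rare mid-year age of
95 (the window having ended earlier that year) folds into the 90–94 band.
Empty registers with a header row are valid; zero diagnosis hazards yield
an empty psychiatric register and zero cases everywhere; an empty eligible
pool yields a zero-control set with a warning, not an error.  Computations
run in full precision; values are rounded only in written reports.  The
simulation treats waiting times beyond 200 years as "never" to keep
nanosecond datetime arithmetic in range.

## Problem sizes

The bundled analysis and the validation suite use 20,000 simulated persons
(≈ 3,000 matched sets, ≈ 214,000 panel rows) for the worked study, null
checks and matching validation, 50,000 for parameter recovery, and ≤ 150
for the brute-force oracle — sizes at which the Monte-Carlo tolerances
above are meaningful while a full run stays interactive.
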