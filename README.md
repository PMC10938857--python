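# mindcost

Register-based, matched-cohort cost-of-illness analysis of mental disorders,
as a tested, reusable Python pipeline.

Health planners need to know what mental disorders cost — in healthcare
consumption, in lost personal income, and in public transfer payments — and
how those costs divide across disorder types, sex, age and time since
diagnosis.  Nationwide administrative registers (civil registration,
psychiatric hospital contacts, DRG hospital tariffs, prescriptions,
primary-care services, income statistics) make it possible to answer this
with a prevalence-based matched design: every person with a first hospital
diagnosis of a disorder (the *case*, at their *index date*) is compared with
10 randomly drawn persons of the same sex and birthdate (± 2 calendar
months) who were alive, resident and free of that disorder on the index
date.  The **excess cost** of a disorder is the case-minus-control
difference — an associational, not causal, attribution.

`mindcost` implements the full chain:

1. **register_io** — schemas, validation and CSV round-trips for the six
   person-level register tables;
2. **synthetic** — a register simulator with known, exactly recorded
   ground-truth cost effects (individual-level register data are never
   public, so the pipeline is exercised end to end on synthetic registers);
3. **cohort** — follow-up windows (1 Jan 2004 or birth/immigration → death,
   95th birthday, emigration or 23 Apr 2017), case identification
   (first qualifying ICD-10 F-chapter contact 1995–2017, onset-age
   filtered) and incidence-density matching;
4. **costing** — per-person per-calendar-year cost panels in 2017 Euro
   (GDP-deflator inflation adjustment, 2017 average exchange rate,
   subsidised prescriptions = service − out-of-pocket, combined healthcare
   cost = psychiatric DRG + somatic DRG + subsidised prescriptions +
   primary care);
5. **estimation** — for each disorder × component × stratum the estimands

   * nationwide annual: `Σ_years total / Σ_years window-fraction`,
   * per-case annual: `Σ follow-up values / case person-years`,
   * per-capita annual: nationwide / population denominator,

   each absolute (cases' costs) and excess (case − mean over surviving
   controls), overall and by sex and 5-year age band, plus the excess-cost
   profile by years since diagnosis (offsets 0–13, estimated by least
   squares on the offset-exposure design to undo the smearing of annual
   register amounts);
6. **reporting / cli** — a `mindcost` command with `simulate`, `cohort`,
   `cost`, `estimate`, `report` and `all` subcommands, figure-style ranking
   tables and a deterministic run log.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study of
20,000 persons (seed 2017), writing intermediate tables to `scratch/study/`
and compact summaries to `results/`:

```bash
python analysis/01_simulate_registers.py
python analysis/02_build_cohort.py
python analysis/03_assemble_costs.py
python analysis/04_estimate_costs.py
python analysis/05_rank_and_profile.py
```

The run prints, among other things:

```
persons with any mental disorder: 1485
3051 matched sets across 19 disorders
8 deficient sets (< 10 controls)
213552 person-year panel rows, 200,213 person-years of follow-up
any mental disorder, per-case annual excess (2017 EUR):
  healthcare_cost       1,507
  income               -2,547
  transfers_total       1,371
per-case annual excess healthcare cost, top 5 (2017 EUR):
  schizophrenia                     5,291
  autism spectrum disorders         2,418
  anorexia nervosa                  2,375
  bipolar disorder                  2,366
  intellectual disabilities         2,344
any mental disorder, excess healthcare by years since diagnosis:
  k=0: 4,374  k=1: 3,986  k=2: 3,232  k=3: 3,123  k=4: 2,489  k=5: 2,226
```

Reading this: 1,485 of 20,000 simulated persons acquire a hospital-diagnosed
mental disorder; compared with their matched controls they cost on average
1,507 EUR more per person-year in combined healthcare, earn 2,547 EUR less
(income excess is case − control, hence negative when cases earn less) and
receive 1,371 EUR more in public transfers.  Schizophrenia is the most
expensive disorder per case, and the excess healthcare cost is highest in
the first year after diagnosis and declines thereafter while remaining
positive — the qualitative structure the matched design is built to expose.
The same tables can be produced from a YAML configuration via
`mindcost all --config study.yaml`.

The equivalent library calls:

```python
import mindcost as mc

params = mc.SimulationParams(n_persons=20000, seed=2017)
bundle, truth = mc.simulate_registers(params)

study = mc.StudyConfig(seed=2017)
catalogue = mc.default_catalogue()
windows = mc.followup_windows(bundle.civil, study)
cases = mc.identify_all_cases(bundle.psychiatric, bundle.civil, catalogue, study)
matched = mc.match_controls(cases, bundle.civil, bundle.psychiatric, catalogue, study)
panels = mc.build_panels(bundle, windows, mc.default_deflators(), study)
table = mc.set_year_table(matched, panels, bundle.civil)
estimates = mc.aggregate(table, mc.denominators_from_bundle(bundle), study)
```

## Data and scope

Real Danish register data are not publicly available, and this package
deliberately contains no access layer for them; the bundled ICD-10 code
sets and onset ages are plausible placeholders meant to be replaced by a
user-supplied catalogue (`load_catalogue`) when the study-specific
definitions are available.  The pipeline reports no confidence intervals
for the study estimands and makes no causal claims; see
`docs/methods.md` for the model, its assumptions and its limitations.
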