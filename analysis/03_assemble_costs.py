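#!/usr/bin/env python
"""Build the per-person-year cost panel in 2017 Euro.

Applies GDP-deflator inflation adjustment and the 2017 exchange rate to all
register amounts, derives subsidised prescription cost (service minus
out-of-pocket) and the combined healthcare cost, and prorates person-time
within calendar years.  The full panel goes to scratch/study/panels.csv; a
mean-cost-by-age-band summary goes to results/panel_summary.csv.
"""

from pathlib import Path

import mindcost as mc
from mindcost.config import age_band
from mindcost import _dates
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SEED = 2017


def main() -> None:
    study = mc.StudyConfig(seed=SEED)
    deflators = mc.default_deflators()
    bundle = mc.RegisterBundle.read_dir(ROOT / "scratch" / "study" / "registers")

    windows = mc.followup_windows(bundle.civil, study)
    panels = mc.build_panels(bundle, windows, deflators, study)
    panels.to_csv(ROOT / "scratch" / "study" / "panels.csv", index=False)

    births = bundle.civil.set_index("person_id")["birth_date"]
    july1 = pd.to_datetime(dict(year=panels["year"], month=7, day=1))
    bands = age_band(_dates.age_on(july1, panels["person_id"].map(births)))
    summary = panels.assign(age_band=bands).groupby("age_band", sort=False).agg(
        person_years=("person_years", "sum"),
        mean_healthcare=("healthcare_cost", "mean"),
        mean_income=("income", "mean"),
        mean_transfers=("transfers_total", "mean"),
    ).reset_index()
    summary.to_csv(ROOT / "results" / "panel_summary.csv", index=False)

    total_py = panels["person_years"].sum()
    print(f"{len(panels)} person-year panel rows, {total_py:,.0f} person-years of follow-up")
    print(f"mean combined healthcare cost: {panels['healthcare_cost'].mean():,.0f} EUR/person-year")
    print(f"mean personal income:          {panels['income'].mean():,.0f} EUR/person-year")


if __name__ == "__main__":
    main()
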