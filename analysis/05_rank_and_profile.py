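#!/usr/bin/env python
"""Rank disorders by cost and trace excess cost over years since diagnosis.

Renders the figure-style tables: disorders ordered by nationwide annual and
per-case annual cost (absolute and excess, with the healthcare component
breakdown), and the years-since-diagnosis excess profile for cases first
diagnosed inside the follow-up period.  All outputs land in results/.
"""

from pathlib import Path

import pandas as pd

import mindcost as mc

ROOT = Path(__file__).resolve().parents[1]
SEED = 2017


def main() -> None:
    study = mc.StudyConfig(seed=SEED)
    bundle = mc.RegisterBundle.read_dir(ROOT / "scratch" / "study" / "registers")
    out_dir = ROOT / "scratch" / "study"
    results = ROOT / "results"

    estimates = pd.read_csv(out_dir / "estimates.csv")
    for measure in ("nationwide_annual", "per_case_annual"):
        for kind in ("absolute", "excess"):
            for component in ("healthcare_cost", "income", "transfers_total"):
                ranking = mc.rank_disorders(estimates, measure, kind, component)
                ranking.round(2).to_csv(
                    results / f"ranking_{measure}_{kind}_{component}.csv", index=False)

    sets = pd.read_csv(out_dir / "matched_sets.csv")
    sets["index_date"] = pd.to_datetime(sets["index_date"])
    controls = pd.read_csv(out_dir / "matched_controls.csv")
    matched = mc.MatchedCohort(sets=sets, controls=controls,
                               target_controls=study.controls_per_case)
    panels = pd.read_csv(out_dir / "panels.csv")
    table = mc.set_year_table(matched, panels, bundle.civil)
    profile = mc.years_since_diagnosis_profile(table, bundle.civil, study)
    profile.round(2).to_csv(results / "years_since_diagnosis.csv", index=False)

    hc_rank = mc.rank_disorders(estimates, "per_case_annual", "excess", "healthcare_cost")
    named = hc_rank[hc_rank["disorder"] != mc.ANY_MENTAL_DISORDER]
    print("per-case annual excess healthcare cost, top 5 (2017 EUR):")
    for _, r in named.head(5).iterrows():
        print(f"  {r['disorder']:28s} {r['value']:>10,.0f}")
    any_prof = profile[profile["disorder"] == mc.ANY_MENTAL_DISORDER]
    head = any_prof.set_index("offset")["healthcare_cost"].head(6)
    print("any mental disorder, excess healthcare by years since diagnosis:")
    print("  " + "  ".join(f"k={k}: {v:,.0f}" for k, v in head.items()))


if __name__ == "__main__":
    main()
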