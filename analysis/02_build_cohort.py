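#!/usr/bin/env python
"""Identify cases and attach 10 matched controls per case.

Reads the registers written by 01_simulate_registers.py, finds each
person's first qualifying diagnosis per disorder (1995-2017, onset-age
filtered) and samples sex- and birthdate-matched, disorder-free-at-index
controls.  Matched sets go to scratch/study; the per-disorder matching
summary goes to results/matching_summary.csv.
"""

from pathlib import Path

import mindcost as mc

ROOT = Path(__file__).resolve().parents[1]
SEED = 2017


def main() -> None:
    catalogue = mc.default_catalogue()
    study = mc.StudyConfig(seed=SEED)
    bundle = mc.RegisterBundle.read_dir(ROOT / "scratch" / "study" / "registers")

    cases = mc.identify_all_cases(bundle.psychiatric, bundle.civil, catalogue, study)
    matched = mc.match_controls(cases, bundle.civil, bundle.psychiatric, catalogue, study)

    out_dir = ROOT / "scratch" / "study"
    matched.sets.assign(
        index_date=matched.sets["index_date"].dt.strftime("%Y-%m-%d")
    ).to_csv(out_dir / "matched_sets.csv", index=False)
    matched.controls.to_csv(out_dir / "matched_controls.csv", index=False)

    summary = matched.sets.groupby("disorder").agg(
        sets=("set_id", "size"),
        mean_controls=("n_controls", "mean"),
        deficient=("n_controls", lambda s: int((s < study.controls_per_case).sum())),
    ).reset_index()
    summary.to_csv(ROOT / "results" / "matching_summary.csv", index=False)

    print(f"{len(matched.sets)} matched sets across {cases['disorder'].nunique()} disorders")
    print(f"{len(matched.deficient)} deficient sets (< {study.controls_per_case} controls)")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
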