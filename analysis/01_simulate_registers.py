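#!/usr/bin/env python
"""Generate the synthetic register bundle for the worked study.

Simulates 20,000 persons under the default scenario (Danish-register-like
incidence, plausible disorder-attributable cost effects) and writes the six
register files plus the injected ground truth under scratch/study/registers.
A compact summary of realised case counts lands in results/case_counts.csv.
"""

from pathlib import Path

import mindcost as mc

ROOT = Path(__file__).resolve().parents[1]
SEED = 2017
N = 20000


def main() -> None:
    catalogue = mc.default_catalogue()
    params = mc.SimulationParams(n_persons=N, seed=SEED)
    bundle, truth = mc.simulate_registers(params, catalogue)

    reg_dir = ROOT / "scratch" / "study" / "registers"
    bundle.write_dir(reg_dir)
    mc.denominators_from_bundle(bundle).to_csv(reg_dir / "denominators.csv")
    truth.index_dates.assign(
        index_date=truth.index_dates["index_date"].dt.strftime("%Y-%m-%d")
    ).to_csv(reg_dir / "ground_truth_index_dates.csv", index=False)
    truth.injections.to_csv(reg_dir / "ground_truth_injections.csv", index=False)

    counts = (
        truth.index_dates.groupby("disorder").size().rename("cases").reset_index()
    )
    out = ROOT / "results" / "case_counts.csv"
    out.parent.mkdir(exist_ok=True)
    counts.to_csv(out, index=False)

    print(f"simulated {N} persons (seed {SEED})")
    print(f"psychiatric register: {len(bundle.psychiatric)} contacts")
    print(f"persons with any mental disorder: {truth.case_counts['any mental disorder']}")
    print(f"registers written to {reg_dir}")


if __name__ == "__main__":
    main()
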