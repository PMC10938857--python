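"""Shared fixtures: a small, fully wired synthetic study.

The toy study uses boosted diagnosis hazards so a ~150-person population
still yields cases for several disorders; everything downstream (windows,
matched sets, panels, estimates) is derived once per session.
"""

from __future__ import annotations

import pandas as pd
import pytest

import mindcost as mc


def boosted_params(n_persons: int, seed: int, factor: float = 30.0, **kwargs) -> mc.SimulationParams:
    hazards = {k: min(v * factor, 0.5) for k, v in mc.synthetic.DEFAULT_HAZARDS.items()}
    return mc.SimulationParams(n_persons=n_persons, seed=seed, disorder_hazards=hazards, **kwargs)


@pytest.fixture(scope="session")
def catalogue():
    return mc.default_catalogue()


@pytest.fixture(scope="session")
def study():
    return mc.StudyConfig(seed=42)


@pytest.fixture(scope="session")
def deflators():
    return mc.default_deflators()


@pytest.fixture(scope="session")
def toy(catalogue, study, deflators):
    """A complete toy study: ~150 persons, boosted hazards, default effects."""
    params = boosted_params(150, seed=42)
    bundle, truth = mc.simulate_registers(params, catalogue)
    windows = mc.followup_windows(bundle.civil, study)
    cases = mc.identify_all_cases(bundle.psychiatric, bundle.civil, catalogue, study)
    matched = mc.match_controls(cases, bundle.civil, bundle.psychiatric, catalogue, study)
    panels = mc.build_panels(bundle, windows, deflators, study)
    table = mc.set_year_table(matched, panels, bundle.civil)
    denominators = mc.denominators_from_bundle(bundle)
    estimates = mc.aggregate(table, denominators, study)
    return {
        "params": params, "bundle": bundle, "truth": truth, "windows": windows,
        "cases": cases, "matched": matched, "panels": panels, "table": table,
        "denominators": denominators, "estimates": estimates,
    }


def civil_row(pid, sex="female", birth="1980-01-01", imm=None, emig=None, death=None):
    return {
        "person_id": pid, "sex": sex, "birth_date": birth,
        "immigration_date": imm or "", "emigration_date": emig or "",
        "death_date": death or "",
    }


def make_civil(rows) -> pd.DataFrame:
    return mc.validate_register(pd.DataFrame(rows), "civil")


def make_psych(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["person_id", "event_date", "icd10_code", "contact_type"])
    return mc.validate_register(df, "psychiatric")
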