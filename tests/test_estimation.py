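"""Excess estimator arithmetic, invariances and the brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

import mindcost as mc
import _brute

from conftest import civil_row, make_civil


def _tiny_table():
    """One matched set, one year: case cost 100, controls at 30 and 50."""
    sets = pd.DataFrame({
        "set_id": [0], "disorder": ["schizophrenia"], "case_id": ["CASE"],
        "index_date": [pd.Timestamp("2008-01-01")], "n_eligible": [2], "n_controls": [2],
    })
    controls = pd.DataFrame({"set_id": [0, 0], "control_id": ["A", "B"]})
    cohort = mc.MatchedCohort(sets=sets, controls=controls)
    comps = {c: 0.0 for c in mc.COMPONENTS}
    rows = []
    for pid, psych in (("CASE", 100.0), ("A", 30.0), ("B", 50.0)):
        rows.append({"person_id": pid, "year": 2010, "person_years": 1.0,
                     **{**comps, "psych_cost": psych}})
    panels = pd.DataFrame(rows)
    civil = make_civil([
        civil_row("CASE", birth="1980-01-01"),
        civil_row("A", birth="1980-01-15"),
        civil_row("B", birth="1980-02-01"),
    ])
    return mc.set_year_table(cohort, panels, civil), cohort, panels, civil


def test_two_control_arithmetic_forced_by_definition():
    table, *_ = _tiny_table()
    assert mc.excess_by_year(table, "psych_cost", 2010) == pytest.approx(100.0 - 40.0)


def test_censored_controls_keep_equal_weight_in_the_reference():
    """A control followed for only part of the year still counts once: their
    annual amount already reflects the shorter presence, so re-weighting by
    person-time would double-discount them."""
    table, cohort, panels, civil = _tiny_table()
    panels.loc[panels["person_id"] == "B", "person_years"] = 0.25
    table = mc.set_year_table(cohort, panels, civil)
    assert mc.excess_by_year(table, "psych_cost", 2010) == pytest.approx(100.0 - 40.0)


def test_identical_case_and_control_panels_give_zero_excess(toy, study):
    """Every matched set compared against itself nets out exactly."""
    matched = toy["matched"]
    panels = toy["panels"]
    civil = toy["bundle"].civil
    self_controls = matched.sets[["set_id", "case_id"]].rename(columns={"case_id": "control_id"})
    cohort = mc.MatchedCohort(sets=matched.sets, controls=self_controls)
    table = mc.set_year_table(cohort, panels, civil)
    for comp in mc.COMPONENTS:
        vals = table.data[f"exc_{comp}"].dropna()
        assert np.allclose(vals, 0.0, atol=1e-9)


def test_unknown_component_errors(toy):
    with pytest.raises(mc.errors.ConfigError, match="unknown cost component"):
        mc.excess_by_year(toy["table"], "not_a_component", 2010)


def test_excess_invariant_to_constant_cost_shift(toy, study):
    """Adding the same constant to everyone's costs leaves excess unchanged."""
    matched, civil = toy["matched"], toy["bundle"].civil
    panels = toy["panels"].copy()
    base = mc.set_year_table(matched, panels, civil)
    shifted = panels.copy()
    shifted["psych_cost"] = shifted["psych_cost"] + 500.0
    after = mc.set_year_table(matched, shifted, civil)
    a = base.data["exc_psych_cost"].dropna().to_numpy()
    b = after.data["exc_psych_cost"].dropna().to_numpy()
    assert np.allclose(a, b, atol=1e-9)


def test_partition_conservation_for_sex_and_age(toy):
    est = toy["estimates"]
    nat = est[est["measure"] == "nationwide_annual"]
    overall = nat[nat["stratifier"] == "overall"].set_index(
        ["disorder", "cost_kind", "component"])["value"]
    for stratifier in ("sex", "age_band"):
        parts = nat[nat["stratifier"] == stratifier].groupby(
            ["disorder", "cost_kind", "component"])["value"].sum()
        joined = pd.concat([overall.rename("overall"), parts.rename("parts")], axis=1).dropna()
        assert len(joined) > 0
        assert np.allclose(joined["overall"], joined["parts"], rtol=1e-9, atol=1e-9)


def test_per_capita_is_nationwide_over_denominator(toy):
    est, denoms = toy["estimates"], toy["denominators"]
    nat = est[est["measure"] == "nationwide_annual"].set_index(
        ["disorder", "cost_kind", "component", "stratifier", "stratum"])["value"]
    cap = est[est["measure"] == "per_capita_annual"]
    assert len(cap) > 0
    for _, row in cap.iterrows():
        denom = denoms.for_stratum(row["stratifier"], row["stratum"])
        expected = nat[(row["disorder"], row["cost_kind"], row["component"],
                        row["stratifier"], row["stratum"])] / denom
        assert row["value"] == pytest.approx(expected, rel=1e-12)


def test_income_excess_sign_convention(toy):
    """Cases earn less in the default scenario, so income excess is negative."""
    est = toy["estimates"]
    sel = est[(est["disorder"] == "any mental disorder")
              & (est["measure"] == "per_case_annual")
              & (est["cost_kind"] == "excess")
              & (est["stratifier"] == "overall")].set_index("component")["value"]
    assert sel["income"] < 0
    assert sel["transfers_total"] > 0


def test_every_stratum_estimate_matches_brute_force(toy, study, deflators, catalogue):
    """Full oracle equivalence on a toy bundle (<= ~150 persons)."""
    est = toy["estimates"]
    brute = _brute.estimates(
        toy["bundle"], toy["matched"].sets, toy["matched"].controls,
        toy["denominators"], deflators, study,
    )
    checked = 0
    for _, row in est.iterrows():
        key = (row["disorder"], row["measure"], row["cost_kind"], row["component"],
               row["stratifier"], row["stratum"])
        assert key in brute, key
        assert row["value"] == pytest.approx(brute[key], rel=1e-9, abs=1e-9), key
        py_key = (row["disorder"], "py", row["cost_kind"], row["stratifier"], row["stratum"])
        assert row["n_case_person_years"] == pytest.approx(brute[py_key], rel=1e-9)
        checked += 1
    assert checked == len(est) > 1000
    # and nothing the oracle produces is missing from the pipeline output
    pipeline_keys = {
        (r["disorder"], r["measure"], r["cost_kind"], r["component"], r["stratifier"], r["stratum"])
        for _, r in est.iterrows()
    }
    brute_keys = {k for k in brute if k[1] != "py"}
    assert brute_keys == pipeline_keys


def test_profile_contributions_limited_by_censoring(study, catalogue, deflators):
    """A case diagnosed mid-2016 reaches only offsets 0 and (fractionally) 1."""
    civil = make_civil([
        civil_row("CASE", birth="1980-06-01"),
        *[civil_row(f"C{i}", birth="1980-06-15") for i in range(10)],
    ])
    psych = pd.DataFrame({
        "person_id": ["CASE"], "event_date": ["2016-06-01"],
        "icd10_code": ["F20.0"], "contact_type": ["inpatient"],
    })
    psych = mc.validate_register(psych, "psychiatric")
    cases = mc.identify_cases(psych, civil, "schizophrenia", study, catalogue)
    matched = mc.match_controls(cases, civil, psych, catalogue, study)
    windows = mc.followup_windows(civil, study)
    bundle = mc.RegisterBundle(
        civil=civil, psychiatric=psych,
        drg_costs=mc.empty_register("drg_costs"),
        prescriptions=mc.empty_register("prescriptions"),
        primary_care=mc.empty_register("primary_care"),
        income=mc.empty_register("income"),
    )
    panels = mc.build_panels(bundle, windows, deflators, study)
    table = mc.set_year_table(matched, panels, civil)
    profile = mc.years_since_diagnosis_profile(table, civil, study)
    offsets = set(profile["offset"])
    assert offsets == {0, 1}
    p = profile.set_index("offset")["person_years"]
    assert p[0] == pytest.approx(1.0, rel=0.01)      # Jun 2016 - Jun 2017
    assert 0 < p[1] < 0.7                            # Jun 2017 - end of 2017


def test_profile_zero_for_null_effects(study, catalogue, deflators):
    from conftest import boosted_params
    params = boosted_params(800, seed=13).with_zero_effects()
    bundle, _ = mc.simulate_registers(params, catalogue)
    windows = mc.followup_windows(bundle.civil, study)
    cases = mc.identify_all_cases(bundle.psychiatric, bundle.civil, catalogue, study)
    matched = mc.match_controls(cases, bundle.civil, bundle.psychiatric, catalogue, study)
    panels = mc.build_panels(bundle, windows, deflators, study)
    table = mc.set_year_table(matched, panels, bundle.civil)
    profile = mc.years_since_diagnosis_profile(table, bundle.civil, study)
    sel = profile[(profile["disorder"] == "any mental disorder") & (profile["person_years"] > 50)]
    assert len(sel) >= 3
    # no injected effects: psychiatric excess indistinguishable from zero
    assert (sel["psych_cost"].abs() < 2000).all()


def test_excess_with_se_recovers_scale(toy):
    se_table = mc.excess_with_se(toy["table"], "healthcare_cost")
    any_row = se_table[se_table["disorder"] == "any mental disorder"].iloc[0]
    assert any_row["se"] > 0
    assert any_row["case_person_years"] > 0
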