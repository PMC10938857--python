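"""Follow-up windows, case identification and matching."""

import numpy as np
import pandas as pd
import pytest

import mindcost as mc
import _brute

from conftest import civil_row, make_civil, make_psych


@pytest.mark.parametrize(
    "row,expected",
    [
        # Resident all along: the full study window.
        (civil_row("P1", birth="1990-03-15"), ("2004-01-01", "2017-04-23")),
        # 95th birthday before the study starts: no follow-up at all.
        (civil_row("P2", birth="1908-01-01"), None),
        # Immigrated then died inside the window.
        (civil_row("P3", birth="1970-06-01", imm="2010-05-01", death="2015-03-02"),
         ("2010-05-01", "2015-03-02")),
        # 95th birthday censors inside the window.
        (civil_row("P4", birth="1920-06-10"), ("2004-01-01", "2015-06-10")),
        # Emigration before the study starts.
        (civil_row("P5", birth="1980-01-01", emig="2001-01-01"), None),
    ],
)
def test_followup_window_min_max_rule(row, expected, study):
    windows = mc.followup_windows(make_civil([row]), study)
    if expected is None:
        assert windows.empty
    else:
        assert len(windows) == 1
        assert windows["start"].iloc[0] == pd.Timestamp(expected[0])
        assert windows["end"].iloc[0] == pd.Timestamp(expected[1])


class TestIdentifyCases:
    def _disorder(self):
        return mc.DisorderDefinition("major depressive disorder", ("F32", "F33"), 6)

    def test_earliest_qualifying_event_wins(self, study):
        civil = make_civil([civil_row("P1", birth="1980-01-01")])
        psych = make_psych([
            ("P1", "2005-02-01", "F32.1", "inpatient"),
            ("P1", "2001-06-15", "F33.0", "outpatient"),
        ])
        cases = mc.identify_cases(psych, civil, self._disorder(), study)
        assert len(cases) == 1
        assert cases["index_date"].iloc[0] == pd.Timestamp("2001-06-15")

    def test_event_before_case_window_disqualifies(self, study):
        civil = make_civil([civil_row("P1", birth="1960-01-01")])
        psych = make_psych([("P1", "1994-12-31", "F32.0", "inpatient")])
        cases = mc.identify_cases(psych, civil, self._disorder(), study)
        assert cases.empty

    def test_events_below_onset_age_ignored(self, study):
        civil = make_civil([civil_row("P1", birth="2000-01-01")])
        psych = make_psych([
            ("P1", "2004-06-01", "F32.0", "outpatient"),   # age 4 < onset 6
            ("P1", "2010-06-01", "F32.0", "outpatient"),
        ])
        cases = mc.identify_cases(psych, civil, self._disorder(), study)
        assert cases["index_date"].iloc[0] == pd.Timestamp("2010-06-01")

    def test_unknown_disorder_name_errors(self, study, catalogue):
        civil = make_civil([civil_row("P1")])
        psych = make_psych([])
        with pytest.raises(mc.errors.ConfigError, match="unknown disorder"):
            mc.identify_cases(psych, civil, "not a disorder", study, catalogue)

    def test_zero_hazards_give_zero_cases(self, catalogue, study):
        params = mc.SimulationParams(
            n_persons=300, seed=7,
            disorder_hazards={k: 0.0 for k in mc.synthetic.DEFAULT_HAZARDS},
        )
        bundle, truth = mc.simulate_registers(params, catalogue)
        assert bundle.psychiatric.empty
        cases = mc.identify_all_cases(bundle.psychiatric, bundle.civil, catalogue, study)
        assert cases.empty
        assert truth.case_counts["any mental disorder"] == 0

    def test_person_can_be_case_for_several_disorders(self, study, catalogue):
        civil = make_civil([civil_row("P1", birth="1980-01-01")])
        psych = make_psych([
            ("P1", "2005-01-01", "F32.0", "inpatient"),
            ("P1", "2007-01-01", "F20.0", "inpatient"),
        ])
        cases = mc.identify_all_cases(psych, civil, catalogue, study)
        names = set(cases["disorder"])
        assert {"major depressive disorder", "schizophrenia", "any mental disorder"} <= names
        any_row = cases[cases["disorder"] == "any mental disorder"]
        assert any_row["index_date"].iloc[0] == pd.Timestamp("2005-01-01")


class TestMatching:
    def test_control_diagnosed_day_before_index_excluded(self, study, catalogue):
        rows = [civil_row("CASE", birth="1980-01-01")]
        rows += [civil_row(f"C{i}", birth="1980-02-01") for i in range(12)]
        civil = make_civil(rows)
        psych = make_psych([
            ("CASE", "2010-06-15", "F32.0", "inpatient"),
            ("C0", "2010-06-14", "F32.0", "inpatient"),   # index disorder, one day early
            ("C1", "2010-06-16", "F32.0", "inpatient"),   # diagnosed after: stays eligible
        ])
        cases = mc.identify_cases(psych, civil, "major depressive disorder", study, catalogue)
        cases = cases[cases["person_id"] == "CASE"]
        matched = mc.match_controls(cases, civil, psych, catalogue, study)
        chosen = set(matched.controls["control_id"])
        assert "C0" not in chosen
        assert matched.sets["n_eligible"].iloc[0] == 11  # C1..C11

    def test_engineered_pool_of_four_eligible(self, study, catalogue, caplog):
        rows = [civil_row("CASE", birth="1980-01-01")]
        # Four eligible; the rest fail one rule each.
        rows += [civil_row(f"OK{i}", birth="1980-02-01") for i in range(4)]
        rows += [
            civil_row("XSEX", sex="male", birth="1980-01-15"),
            civil_row("XBD", birth="1980-03-02"),              # just over +2 months
            civil_row("XDEAD", birth="1980-01-20", death="2009-01-01"),
            civil_row("XGONE", birth="1980-01-20", emig="2005-01-01"),
            civil_row("XLATE", birth="1980-01-20", imm="2012-01-01"),
        ]
        civil = make_civil(rows)
        psych = make_psych([("CASE", "2010-06-15", "F32.0", "inpatient")])
        cases = mc.identify_cases(psych, civil, "major depressive disorder", study, catalogue)
        with caplog.at_level("WARNING"):
            matched = mc.match_controls(cases, civil, psych, catalogue, study)
        assert matched.sets["n_controls"].iloc[0] == 4
        assert set(matched.controls["control_id"]) == {f"OK{i}" for i in range(4)}
        assert "deficient" in caplog.text
        # Brute-force eligibility agrees.
        brute = _brute.eligible_controls(
            "CASE", cases["index_date"].iloc[0],
            mc.catalogue.as_mapping(catalogue)["major depressive disorder"],
            civil.to_dict("records"), psych.to_dict("records"), study,
        )
        assert brute == {f"OK{i}" for i in range(4)}

    def test_empty_pool_yields_zero_control_set(self, study, catalogue):
        civil = make_civil([civil_row("CASE", birth="1980-01-01")])
        psych = make_psych([("CASE", "2010-06-15", "F32.0", "inpatient")])
        cases = mc.identify_cases(psych, civil, "major depressive disorder", study, catalogue)
        matched = mc.match_controls(cases, civil, psych, catalogue, study)
        assert matched.sets["n_controls"].iloc[0] == 0
        assert matched.controls.empty

    def test_matched_set_invariants_hold_exhaustively(self, toy, study, catalogue):
        bundle, matched = toy["bundle"], toy["matched"]
        civ = bundle.civil.set_index("person_id")
        sets = matched.sets.merge(matched.controls, on="set_id")
        assert (sets["case_id"] != sets["control_id"]).all()
        case_sex = sets["case_id"].map(civ["sex"])
        assert (case_sex == sets["control_id"].map(civ["sex"])).all()
        case_bd = pd.to_datetime(sets["case_id"].map(civ["birth_date"]))
        ctrl_bd = pd.to_datetime(sets["control_id"].map(civ["birth_date"]))
        lo = mc._dates.add_months(case_bd, -2)
        hi = mc._dates.add_months(case_bd, 2)
        assert ((ctrl_bd >= lo.to_numpy()) & (ctrl_bd <= hi.to_numpy())).all()
        # no control within a set twice
        assert not sets.duplicated(subset=["set_id", "control_id"]).any()

    def test_eligible_set_matches_brute_force_on_small_pool(self, toy, study, catalogue):
        """Matcher-reported eligible counts equal a full brute-force scan."""
        bundle, matched = toy["bundle"], toy["matched"]
        civil_rows = bundle.civil.to_dict("records")
        psych_rows = bundle.psychiatric.to_dict("records")
        mapping = mc.catalogue.as_mapping(catalogue)
        sample = matched.sets.head(25)
        for _, s in sample.iterrows():
            brute = _brute.eligible_controls(
                s["case_id"], s["index_date"], mapping[s["disorder"]],
                civil_rows, psych_rows, study,
            )
            assert len(brute) == s["n_eligible"]
            chosen = set(matched.controls[matched.controls["set_id"] == s["set_id"]]["control_id"])
            assert chosen <= brute

    def test_matching_deterministic_and_order_invariant(self, toy, study, catalogue):
        bundle, cases = toy["bundle"], toy["cases"]
        a = mc.match_controls(cases, bundle.civil, bundle.psychiatric, catalogue, study)
        shuffled_cases = cases.sample(frac=1, random_state=0)
        shuffled_civil = bundle.civil.sample(frac=1, random_state=1)
        b = mc.match_controls(shuffled_cases, shuffled_civil, bundle.psychiatric, catalogue, study)
        pd.testing.assert_frame_equal(a.sets, b.sets)
        pd.testing.assert_frame_equal(a.controls, b.controls)

    def test_seed_changes_sampled_controls(self, catalogue):
        rows = [civil_row("CASE", birth="1980-01-01")]
        rows += [civil_row(f"C{i:02d}", birth="1980-02-01") for i in range(30)]
        civil = make_civil(rows)
        psych = make_psych([("CASE", "2010-06-15", "F32.0", "inpatient")])
        cases = mc.identify_cases(psych, civil, "major depressive disorder",
                                  mc.StudyConfig(), catalogue)
        a = mc.match_controls(cases, civil, psych, catalogue, mc.StudyConfig(seed=1))
        b = mc.match_controls(cases, civil, psych, catalogue, mc.StudyConfig(seed=2))
        # eligibility identical, the 10-of-30 sample differs
        pd.testing.assert_series_equal(a.sets["n_eligible"], b.sets["n_eligible"])
        assert len(a.controls) == len(b.controls) == 10
        assert set(a.controls["control_id"]) != set(b.controls["control_id"])
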