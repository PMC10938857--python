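"""Deflation, panel assembly and the cost identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mindcost as mc
from mindcost.errors import DeflatorError, PipelineError


class TestToEur2017:
    def test_reference_year_identity_up_to_fx(self):
        table = mc.DeflatorTable(values={2017: 100.0}, fx_rate_2017=1.0)
        assert mc.to_eur2017(500.0, 2017, table) == pytest.approx(500.0)

    def test_hand_computed_two_step_adjustment(self):
        table = mc.DeflatorTable(values={2010: 100.0, 2017: 110.0}, fx_rate_2017=7.5)
        # 1000 * 1.10 / 7.5
        assert mc.to_eur2017(1000.0, 2010, table) == pytest.approx(146.6666666667)

    def test_default_series_ratio_against_spreadsheet_recomputation(self, deflators):
        # independent recomputation straight from the stored numbers
        expected = 1000.0 * deflators.values[2017] / deflators.values[2004] / deflators.fx_rate_2017
        assert mc.to_eur2017(1000.0, 2004, deflators) == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(0, 1e6, allow_nan=False),
        year=st.sampled_from(range(2004, 2018)),
    )
    def test_linearity(self, a, b, year):
        table = mc.default_deflators()
        lhs = mc.to_eur2017(a + b, year, table)
        rhs = mc.to_eur2017(a, year, table) + mc.to_eur2017(b, year, table)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_unknown_year_errors(self, deflators):
        with pytest.raises(DeflatorError, match="1999"):
            mc.to_eur2017(10.0, 1999, deflators)


class TestPanels:
    def test_combined_healthcare_identity_on_every_panel(self, toy):
        p = toy["panels"]
        lhs = p["healthcare_cost"]
        rhs = p["psych_cost"] + p["somatic_cost"] + p["rx_subsidised_cost"] + p["primary_care_cost"]
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-9)
        assert (p[["psych_cost", "somatic_cost", "rx_subsidised_cost",
                   "rx_out_of_pocket_cost", "primary_care_cost"]].to_numpy() >= 0).all()
        assert ((p["person_years"] > 0) & (p["person_years"] <= 1.0 + 1e-12)).all()

    def test_no_panel_outside_followup_window(self, toy, study):
        p, windows = toy["panels"], toy["windows"]
        allowed = set(map(tuple, windows.assign(
            y0=windows["start"].dt.year,
            y1=(windows["end"] - pd.Timedelta(days=1)).dt.year,
        )[["person_id", "y0", "y1"]].itertuples(index=False)))
        win = windows.set_index("person_id")
        merged = p.merge(windows, on="person_id", how="left")
        assert merged["start"].notna().all()
        assert (merged["year"] >= merged["start"].dt.year).all()
        assert (merged["year"] <= (merged["end"] - pd.Timedelta(days=1)).dt.year).all()

    def test_conservation_against_raw_registers(self, toy, deflators, study):
        """Per category, panel totals equal the register totals restricted to
        follow-up person-time (compared on the deflated scale)."""
        bundle, p, windows = toy["bundle"], toy["panels"], toy["windows"]
        covered = set(map(tuple, p[["person_id", "year"]].itertuples(index=False)))
        drg = bundle.drg_costs
        drg = drg[[tuple(t) in covered for t in drg[["person_id", "year"]].itertuples(index=False)]]
        for cat, col in (("psych_drg", "psych_cost"), ("somatic_drg", "somatic_cost")):
            sel = drg[drg["category"] == cat]
            expected = mc.to_eur2017(sel["amount_nominal"].to_numpy(), sel["year"].to_numpy(), deflators).sum()
            assert p[col].sum() == pytest.approx(expected, rel=1e-9)

    def test_person_year_with_no_rows_has_zero_components(self, study, deflators):
        civil = mc.validate_register(pd.DataFrame([{
            "person_id": "P1", "sex": "female", "birth_date": "1980-01-01",
            "immigration_date": "", "emigration_date": "", "death_date": "",
        }]), "civil")
        bundle = mc.RegisterBundle(
            civil=civil,
            psychiatric=mc.empty_register("psychiatric"),
            drg_costs=mc.empty_register("drg_costs"),
            prescriptions=mc.empty_register("prescriptions"),
            primary_care=mc.empty_register("primary_care"),
            income=mc.empty_register("income"),
        )
        windows = mc.followup_windows(civil, study)
        row = mc.assemble_annual_costs("P1", 2010, bundle, windows, deflators, study)
        assert row["healthcare_cost"] == 0.0
        assert row["person_years"] == 1.0
        with pytest.raises(PipelineError, match="outside the follow-up window"):
            mc.assemble_annual_costs("P1", 2001, bundle, windows, deflators, study)

    def test_rx_subsidised_is_service_minus_out_of_pocket(self, study):
        table = mc.DeflatorTable(values={y: 100.0 for y in range(2004, 2018)}, fx_rate_2017=1.0)
        civil = mc.validate_register(pd.DataFrame([{
            "person_id": "P1", "sex": "male", "birth_date": "1970-01-01",
            "immigration_date": "", "emigration_date": "", "death_date": "",
        }]), "civil")
        rx = pd.DataFrame({"person_id": ["P1"], "year": [2017],
                           "service_nominal": [300.0], "out_of_pocket_nominal": [120.0]})
        bundle = mc.RegisterBundle(
            civil=civil,
            psychiatric=mc.empty_register("psychiatric"),
            drg_costs=mc.empty_register("drg_costs"),
            prescriptions=mc.validate_register(rx, "prescriptions"),
            primary_care=mc.empty_register("primary_care"),
            income=mc.empty_register("income"),
        )
        windows = mc.followup_windows(civil, study)
        row = mc.assemble_annual_costs("P1", 2017, bundle, windows, table, study)
        assert row["rx_subsidised_cost"] == pytest.approx(180.0)
        assert row["rx_out_of_pocket_cost"] == pytest.approx(120.0)
        assert row["healthcare_cost"] == pytest.approx(180.0)

    def test_negative_subsidised_cost_floored_with_warning(self, study, caplog):
        table = mc.DeflatorTable(values={y: 100.0 for y in range(2004, 2018)}, fx_rate_2017=1.0)
        civil = mc.validate_register(pd.DataFrame([{
            "person_id": "P1", "sex": "male", "birth_date": "1970-01-01",
            "immigration_date": "", "emigration_date": "", "death_date": "",
        }]), "civil")
        rx = pd.DataFrame({"person_id": ["P1"], "year": [2017],
                           "service_nominal": [50.0], "out_of_pocket_nominal": [80.0]})
        bundle = mc.RegisterBundle(
            civil=civil,
            psychiatric=mc.empty_register("psychiatric"),
            drg_costs=mc.empty_register("drg_costs"),
            prescriptions=mc.validate_register(rx, "prescriptions"),
            primary_care=mc.empty_register("primary_care"),
            income=mc.empty_register("income"),
        )
        windows = mc.followup_windows(civil, study)
        with caplog.at_level("WARNING"):
            row = mc.assemble_annual_costs("P1", 2017, bundle, windows, table, study)
        assert row["rx_subsidised_cost"] == 0.0
        assert "floored" in caplog.text

    def test_missing_deflator_year_errors(self, toy, study):
        bundle, windows = toy["bundle"], toy["windows"]
        short = mc.DeflatorTable(values={2017: 100.0})
        with pytest.raises(DeflatorError):
            mc.build_panels(bundle, windows, short, study)
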