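"""Per-person per-calendar-year cost panels in reference-year (2017) Euro.

Register amounts are nominal local currency attributed to the calendar year
of the register row (the cost registers are annual).  Each amount is taken to
2017 price level with the GDP-deflator ratio and converted to Euro with the
2017 average exchange rate.  Person-time is prorated within years; amounts
are not.

Panel identities:

* ``rx_subsidised_cost``   = prescription service cost - out-of-pocket cost
  (floored at zero with a logged warning; annual registers cannot go negative
  but noisy synthetic input could),
* ``healthcare_cost``      = psychiatric DRG + somatic DRG + subsidised
  prescriptions + primary care (out-of-pocket excluded, reported separately),
* ``transfers_total``      = sum of the nine public transfer components.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import _dates
from .config import DeflatorTable, StudyConfig
from .errors import PipelineError
from .register_io import TRANSFER_COLUMNS, RegisterBundle

log = logging.getLogger(__name__)

#: Cost/income components carried on every panel row, all in 2017 Euro.
PANEL_COMPONENTS = (
    "psych_cost",
    "somatic_cost",
    "rx_subsidised_cost",
    "rx_out_of_pocket_cost",
    "primary_care_cost",
    "healthcare_cost",
    "income",
    "transfers_total",
) + TRANSFER_COLUMNS


def to_eur2017(amount_nominal, year, deflators: DeflatorTable):
    """Nominal local currency in ``year`` -> reference-year Euro.

    Linear in the amount; the identity (up to currency conversion) for the
    reference year.  Scalar or array.
    """
    amounts = np.asarray(amount_nominal, dtype=float)
    years = np.asarray(year, dtype=int)
    if years.ndim == 0:
        return float(amounts * deflators.factor(int(years)))
    return amounts * deflators.factors(years)


def person_year_grid(windows: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """One row per person per calendar year overlapping the follow-up window.

    ``person_years`` is the window overlap with the year divided by the
    year's length; it is always in (0, 1].
    """
    if windows.empty:
        return pd.DataFrame({"person_id": pd.Series(dtype=str),
                             "year": pd.Series(dtype=int),
                             "person_years": pd.Series(dtype=float)})
    start = windows["start"].to_numpy().astype("datetime64[ns]")
    end = windows["end"].to_numpy().astype("datetime64[ns]")
    y0 = windows["start"].dt.year.to_numpy()
    # Last calendar year with positive overlap: the year containing end - 1 day.
    y1 = (windows["end"] - pd.Timedelta(days=1)).dt.year.to_numpy()
    counts = y1 - y0 + 1
    rep = np.repeat(np.arange(len(windows)), counts)
    # Concatenated per-person year ranges.
    offsets = np.concatenate([np.arange(c) for c in counts])
    years = y0[rep] + offsets
    ys = pd.to_datetime(pd.DataFrame({"year": years, "month": 1, "day": 1}))
    ye = pd.to_datetime(pd.DataFrame({"year": years + 1, "month": 1, "day": 1}))
    overlap = _dates.overlap_days(start[rep], end[rep], ys.to_numpy(), ye.to_numpy())
    py = overlap / _dates.days_in_year(years)
    out = pd.DataFrame({
        "person_id": windows["person_id"].to_numpy()[rep],
        "year": years,
        "person_years": py,
    })
    return out[out["person_years"] > 0].reset_index(drop=True)


def _sum_by_person_year(df: pd.DataFrame, value_col: str, out_name: str) -> pd.DataFrame:
    g = df.groupby(["person_id", "year"], as_index=False)[value_col].sum()
    return g.rename(columns={value_col: out_name})


def build_panels(
    bundle: RegisterBundle,
    windows: pd.DataFrame,
    deflators: DeflatorTable,
    config: StudyConfig,
) -> pd.DataFrame:
    """Assemble the annual cost panel for every follow-up person-year.

    Register rows for person-years outside follow-up windows are excluded;
    within a covered year the full annual amount is attributed (person-time,
    not money, is prorated).  A person-year with no register rows still gets
    a panel row with all components zero.
    """
    grid = person_year_grid(windows, config)

    drg = bundle.drg_costs
    psych = _sum_by_person_year(drg[drg["category"] == "psych_drg"], "amount_nominal", "psych_cost")
    somatic = _sum_by_person_year(drg[drg["category"] == "somatic_drg"], "amount_nominal", "somatic_cost")
    rx = bundle.prescriptions.groupby(["person_id", "year"], as_index=False)[
        ["service_nominal", "out_of_pocket_nominal"]
    ].sum()
    primary = _sum_by_person_year(bundle.primary_care, "amount_nominal", "primary_care_cost")
    income_cols = ["personal_income", *TRANSFER_COLUMNS]
    income = bundle.income.groupby(["person_id", "year"], as_index=False)[income_cols].sum()

    panel = grid
    for part in (psych, somatic, rx, primary, income):
        panel = panel.merge(part, on=["person_id", "year"], how="left")
    money_cols = [c for c in panel.columns if c not in ("person_id", "year", "person_years")]
    panel[money_cols] = panel[money_cols].fillna(0.0)

    factors = deflators.factors(panel["year"].to_numpy()) if len(panel) else np.array([])
    for col in money_cols:
        panel[col] = panel[col].to_numpy() * factors

    sub = panel["service_nominal"] - panel["out_of_pocket_nominal"]
    negative = sub < 0
    if negative.any():
        log.warning(
            "%d person-year(s) with out-of-pocket cost above prescription service cost; "
            "subsidised cost floored at 0", int(negative.sum()),
        )
    panel["rx_subsidised_cost"] = sub.clip(lower=0.0)
    panel = panel.rename(columns={
        "out_of_pocket_nominal": "rx_out_of_pocket_cost",
        "personal_income": "income",
    }).drop(columns=["service_nominal"])
    panel["healthcare_cost"] = (
        panel["psych_cost"] + panel["somatic_cost"]
        + panel["rx_subsidised_cost"] + panel["primary_care_cost"]
    )
    panel["transfers_total"] = panel[list(TRANSFER_COLUMNS)].sum(axis=1)
    ordered = ["person_id", "year", "person_years", *PANEL_COMPONENTS]
    return panel[ordered]


def assemble_annual_costs(
    person_id: str,
    year: int,
    bundle: RegisterBundle,
    windows: pd.DataFrame,
    deflators: DeflatorTable,
    config: StudyConfig,
) -> pd.Series:
    """One person-year panel row; errors if the year is outside the window."""
    w = windows[windows["person_id"] == person_id]
    if w.empty:
        raise PipelineError(f"{person_id} has no follow-up window")
    panel = build_panels(bundle, w, deflators, config)
    row = panel[panel["year"] == year]
    if row.empty:
        raise PipelineError(f"year {year} is outside the follow-up window of {person_id}")
    return row.iloc[0]
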