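"""Study configuration, deflator series and population denominators.

The study design constants mirror the Danish register setting: persons are
followed from 1 January 2004, birth or immigration (whichever is last) until
death, 95th birthday, emigration or 23 April 2017 (whichever is first); cases
are identified from first hospital diagnoses 1995-2017; each case gets 10
controls matched on sex and birthdate within +/- two calendar months.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from . import _dates
from .errors import ConfigError, DeflatorError

#: 5-year attained-age bands used for age stratification (0-4 ... 90-94).
AGE_BANDS = tuple(f"{lo}-{lo + 4}" for lo in range(0, 95, 5))


def age_band(age_years) -> np.ndarray:
    """Map attained ages to 5-year band labels.

    Person-years can only exist below the 95th-birthday censor; the rare
    mid-year attained age of 95 (window ends earlier that year) is folded
    into the top 90-94 band.
    """
    a = np.clip(np.asarray(age_years, dtype=float), 0, 94)
    idx = (np.floor(a / 5)).astype(int)
    return np.asarray(AGE_BANDS, dtype=object)[idx]


class StudyConfig(BaseModel):
    """Follow-up window, case window and matching parameters."""

    followup_start: dt.date = dt.date(2004, 1, 1)
    followup_end: dt.date = dt.date(2017, 4, 23)
    case_window: tuple[int, int] = (1995, 2017)
    censor_age: int = 95
    controls_per_case: int = Field(default=10, ge=1)
    birthdate_tolerance_months: int = Field(default=2, ge=0)
    seed: int = Field(default=0, ge=0, lt=2**31)
    per_case_weighting: Literal["person_years", "persons"] = "person_years"
    # Controls must be free of the index disorder either only up to the case's
    # index date ("at_index", the wording of the design) or for their entire
    # registered history ("ever").
    control_history_rule: Literal["at_index", "ever"] = "at_index"
    max_offset: int = 13

    @model_validator(mode="after")
    def _check(self):
        if self.followup_start >= self.followup_end:
            raise ValueError("followup_start must precede followup_end")
        if self.case_window[0] > self.case_window[1]:
            raise ValueError("case_window must be an increasing year range")
        if self.case_window[1] < self.followup_end.year:
            raise ValueError("case_window must extend to the follow-up end year")
        return self

    @property
    def study_years(self) -> range:
        return range(self.followup_start.year, self.followup_end.year + 1)

    def year_fraction(self, year: int) -> float:
        """Fraction of calendar ``year`` inside the follow-up window."""
        ys = pd.Timestamp(year, 1, 1)
        ye = pd.Timestamp(year + 1, 1, 1)
        days = _dates.overlap_days(
            ys, ye, pd.Timestamp(self.followup_start), pd.Timestamp(self.followup_end)
        )
        return float(days) / float(_dates.days_in_year(year))

    @property
    def total_year_fraction(self) -> float:
        """Sum of yearly window fractions (the 'annual' averaging denominator)."""
        return sum(self.year_fraction(y) for y in self.study_years)


class DeflatorTable(BaseModel):
    """GDP-deflator index by year plus the 2017 average exchange rate.

    ``values`` is the deflator index (reference year = 100 is conventional but
    any positive scale works: only ratios matter).  ``fx_rate_2017`` is local
    currency units per Euro.
    """

    values: dict[int, float]
    fx_rate_2017: float = Field(default=7.4386, gt=0)
    reference_year: int = 2017

    @field_validator("values")
    @classmethod
    def _positive(cls, v):
        if not v:
            raise ValueError("deflator series is empty")
        for year, idx in v.items():
            if idx <= 0:
                raise ValueError(f"deflator for {year} must be > 0")
        return v

    @model_validator(mode="after")
    def _has_reference(self):
        if self.reference_year not in self.values:
            raise ValueError(f"deflator series lacks reference year {self.reference_year}")
        return self

    def factor(self, year: int) -> float:
        """Multiplier taking a nominal amount in ``year`` to reference-year Euro."""
        try:
            base = self.values[int(year)]
        except KeyError:
            raise DeflatorError(f"no deflator for year {year}") from None
        return self.values[self.reference_year] / base / self.fx_rate_2017

    def factors(self, years) -> np.ndarray:
        ys = np.asarray(years, dtype=int)
        missing = sorted(set(ys.tolist()) - set(self.values))
        if missing:
            raise DeflatorError(f"no deflator for year(s) {missing}")
        ref = self.values[self.reference_year]
        base = np.array([self.values[y] for y in ys.tolist()])
        return ref / base / self.fx_rate_2017


#: Plausible Danish GDP-deflator series (2017 = 100); replace with the real
#: World Bank series for production use.
_DEFAULT_DEFLATORS = {
    2004: 80.6, 2005: 83.0, 2006: 84.9, 2007: 87.0, 2008: 90.1,
    2009: 90.8, 2010: 93.6, 2011: 94.2, 2012: 96.5, 2013: 97.3,
    2014: 98.0, 2015: 98.7, 2016: 99.0, 2017: 100.0,
}


def default_deflators() -> DeflatorTable:
    return DeflatorTable(values=dict(_DEFAULT_DEFLATORS))


class PopulationDenominators:
    """Mid-study population counts by (sex, age band) for per-capita estimates."""

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age_band", "count"}
        if not required.issubset(table.columns):
            raise ConfigError(f"denominator table needs columns {sorted(required)}")
        if (table["count"] < 0).any():
            raise ConfigError("denominator counts must be non-negative")
        if table["count"].sum() <= 0:
            raise ConfigError("denominator total must be positive")
        self.table = table.reset_index(drop=True)

    @property
    def total(self) -> float:
        return float(self.table["count"].sum())

    def for_stratum(self, stratifier: str, stratum: str) -> float:
        """Denominator for one stratum; 'overall' is the grand total."""
        if stratifier == "overall":
            return self.total
        if stratifier == "sex":
            sel = self.table[self.table["sex"] == stratum]
        elif stratifier == "age_band":
            sel = self.table[self.table["age_band"] == stratum]
        else:
            raise ConfigError(f"unknown stratifier {stratifier!r}")
        return float(sel["count"].sum())

    @classmethod
    def from_civil(cls, civil: pd.DataFrame, reference_date) -> "PopulationDenominators":
        """Counts of persons alive and resident on ``reference_date``."""
        ref = pd.Timestamp(reference_date)
        born = civil["birth_date"] <= ref
        here = civil["immigration_date"].isna() | (civil["immigration_date"] <= ref)
        alive = civil["death_date"].isna() | (civil["death_date"] > ref)
        stayed = civil["emigration_date"].isna() | (civil["emigration_date"] > ref)
        sel = civil[born & here & alive & stayed].copy()
        sel["age_band"] = age_band(_dates.age_on(np.full(len(sel), ref), sel["birth_date"]))
        counts = (
            sel.groupby(["sex", "age_band"], observed=True).size().rename("count").reset_index()
        )
        return cls(counts)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationDenominators":
        return cls(pd.read_csv(path, dtype={"sex": str, "age_band": str}))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def load_study_config(path: str | Path) -> StudyConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return StudyConfig(**raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(f"invalid study config {path}: {exc}") from exc
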