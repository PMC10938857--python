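"""Schemas, validation and delimited-file I/O for the six register tables.

The register bundle emulates the person-level sources of a Danish
cost-of-illness study:

* ``civil``          -- civil registration (birth, migration, death)
* ``psychiatric``    -- psychiatric hospital contacts with ICD-10 codes
* ``drg_costs``      -- psychiatric and somatic hospital DRG tariff sums
* ``prescriptions``  -- prescription service cost and out-of-pocket cost
* ``primary_care``   -- primary-sector services (GP, specialist, ...)
* ``income``         -- personal income and nine public transfer components

File dialect: UTF-8 CSV, ISO-8601 dates, header row mandatory, missing
optional dates written as the empty string.  Row order is preserved by
reading and writing.  Validation reports offending rows by 0-based position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

SEXES = ("female", "male")
CONTACT_TYPES = ("inpatient", "outpatient", "emergency")
DRG_CATEGORIES = ("psych_drg", "somatic_drg")
PROVIDER_TYPES = (
    "general_practitioner",
    "specialist",
    "psychologist",
    "dentist",
    "physiotherapist",
    "chiropodist",
    "chiropractor",
)
TRANSFER_COLUMNS = (
    "unemployment_benefits",
    "social_assistance",
    "state_educational_grants",
    "housing_benefits",
    "child_youth_benefits",
    "old_age_pension",
    "disability_pension",
    "flexi_job",
    "early_retirement",
)

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,2})?$")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # 'id' | 'date' | 'opt_date' | 'year' | 'money' | 'category' | 'code'
    categories: tuple[str, ...] | None = None


@dataclass(frozen=True)
class RegisterSchema:
    name: str
    columns: tuple[ColumnSpec, ...]
    table_checks: tuple[Callable[[pd.DataFrame], list[tuple[int, str]]], ...] = ()

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


def _civil_date_order(df: pd.DataFrame) -> list[tuple[int, str]]:
    errors: list[tuple[int, str]] = []
    birth = df["birth_date"]
    for col in ("immigration_date", "emigration_date", "death_date"):
        bad = df[col].notna() & (df[col] < birth)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append((int(i), f"{col} precedes birth_date"))
    death = df["death_date"]
    for col in ("immigration_date", "emigration_date"):
        bad = death.notna() & df[col].notna() & (df[col] > death)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append((int(i), f"{col} is later than death_date"))
    dup = df["person_id"].duplicated(keep=False)
    for i in np.flatnonzero(dup.to_numpy()):
        errors.append((int(i), "duplicate person_id"))
    return errors


def _unique_person_year(df: pd.DataFrame) -> list[tuple[int, str]]:
    dup = df.duplicated(subset=["person_id", "year"], keep=False)
    return [(int(i), "more than one record per person per year") for i in np.flatnonzero(dup.to_numpy())]


SCHEMAS: dict[str, RegisterSchema] = {
    "civil": RegisterSchema(
        "civil",
        (
            ColumnSpec("person_id", "id"),
            ColumnSpec("sex", "category", SEXES),
            ColumnSpec("birth_date", "date"),
            ColumnSpec("immigration_date", "opt_date"),
            ColumnSpec("emigration_date", "opt_date"),
            ColumnSpec("death_date", "opt_date"),
        ),
        (_civil_date_order,),
    ),
    "psychiatric": RegisterSchema(
        "psychiatric",
        (
            ColumnSpec("person_id", "id"),
            ColumnSpec("event_date", "date"),
            ColumnSpec("icd10_code", "code"),
            ColumnSpec("contact_type", "category", CONTACT_TYPES),
        ),
    ),
    "drg_costs": RegisterSchema(
        "drg_costs",
        (
            ColumnSpec("person_id", "id"),
            ColumnSpec("year", "year"),
            ColumnSpec("category", "category", DRG_CATEGORIES),
            ColumnSpec("amount_nominal", "money"),
        ),
    ),
    "prescriptions": RegisterSchema(
        "prescriptions",
        (
            ColumnSpec("person_id", "id"),
            ColumnSpec("year", "year"),
            ColumnSpec("service_nominal", "money"),
            ColumnSpec("out_of_pocket_nominal", "money"),
        ),
        (_unique_person_year,),
    ),
    "primary_care": RegisterSchema(
        "primary_care",
        (
            ColumnSpec("person_id", "id"),
            ColumnSpec("year", "year"),
            ColumnSpec("provider_type", "category", PROVIDER_TYPES),
            ColumnSpec("amount_nominal", "money"),
        ),
    ),
    "income": RegisterSchema(
        "income",
        (
            ColumnSpec("person_id", "id"),
            ColumnSpec("year", "year"),
            ColumnSpec("personal_income", "money"),
            *(ColumnSpec(c, "money") for c in TRANSFER_COLUMNS),
        ),
        (_unique_person_year,),
    ),
}


def _raise_rows(schema: str, problems: list[tuple[int, str]]) -> None:
    if not problems:
        return
    problems.sort()
    shown = "; ".join(f"row {i}: {msg}" for i, msg in problems[:5])
    more = "" if len(problems) <= 5 else f" (+{len(problems) - 5} more)"
    raise ValidationError(f"{schema}: {shown}{more}", rows=[i for i, _ in problems])


def validate_register(df: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    """Return a normalised copy of ``df`` or raise Schema/ValidationError.

    Normalisation: dates become datetime64 (empty -> NaT), years int,
    money float.  Row order is preserved.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown register schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    missing = [c for c in schema.column_names if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema_name}: missing required column(s) {missing}")

    out = pd.DataFrame(index=df.index.copy())
    problems: list[tuple[int, str]] = []
    for col in schema.columns:
        raw = df[col.name]
        if col.kind == "id":
            vals = raw.astype(str)
            for i in np.flatnonzero((vals.str.len() == 0).to_numpy()):
                problems.append((int(i), f"{col.name} is empty"))
            out[col.name] = vals
        elif col.kind in ("date", "opt_date"):
            if pd.api.types.is_datetime64_any_dtype(raw):
                s = raw
                parsed = pd.to_datetime(raw)
            else:
                s = raw.astype(str).replace({"": None, "nan": None, "NaT": None, "None": None})
                parsed = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
            bad = parsed.isna() & s.notna()
            for i in np.flatnonzero(bad.to_numpy()):
                problems.append((int(i), f"{col.name} is not an ISO date"))
            if col.kind == "date":
                for i in np.flatnonzero((parsed.isna() & s.isna()).to_numpy()):
                    problems.append((int(i), f"{col.name} is missing"))
            out[col.name] = parsed
        elif col.kind == "year":
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna() | (vals != vals.round())
            for i in np.flatnonzero(bad.to_numpy()):
                problems.append((int(i), f"{col.name} is not an integer year"))
            out[col.name] = vals.fillna(0).astype(int)
        elif col.kind == "money":
            vals = pd.to_numeric(raw, errors="coerce")
            for i in np.flatnonzero(vals.isna().to_numpy()):
                problems.append((int(i), f"{col.name} is not a number"))
            for i in np.flatnonzero((vals < 0).to_numpy()):
                problems.append((int(i), f"{col.name} is negative"))
            out[col.name] = vals.astype(float)
        elif col.kind == "category":
            vals = raw.astype(str)
            bad = ~vals.isin(col.categories)
            for i in np.flatnonzero(bad.to_numpy()):
                problems.append((int(i), f"{col.name} {vals.iat[i]!r} not in {col.categories}"))
            out[col.name] = vals
        elif col.kind == "code":
            vals = raw.astype(str).str.strip().str.upper()
            bad = ~vals.str.match(_ICD10_RE)
            for i in np.flatnonzero(bad.to_numpy()):
                problems.append((int(i), f"{col.name} {vals.iat[i]!r} is not a valid ICD-10 code"))
            out[col.name] = vals
        else:  # pragma: no cover - schema definition bug
            raise SchemaError(f"unknown column kind {col.kind!r}")

    _raise_rows(schema_name, problems)
    for check in schema.table_checks:
        _raise_rows(schema_name, check(out))
    out = out.reset_index(drop=True)
    return out


def read_register(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate one register file; empty data sections are fine."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"register file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_register(df, schema_name)


def write_register(df: pd.DataFrame, path: str | Path, schema_name: str) -> None:
    """Validate and write one register file (ISO dates, empty string for NaT)."""
    out = validate_register(df, schema_name)
    schema = SCHEMAS[schema_name]
    text = pd.DataFrame(index=out.index)
    for col in schema.columns:
        if col.kind in ("date", "opt_date"):
            text[col.name] = out[col.name].dt.strftime("%Y-%m-%d").fillna("")
        else:
            text[col.name] = out[col.name]
    text.to_csv(path, index=False)


BUNDLE_FILES = {
    "civil": "civil.csv",
    "psychiatric": "psychiatric.csv",
    "drg_costs": "drg_costs.csv",
    "prescriptions": "prescriptions.csv",
    "primary_care": "primary_care.csv",
    "income": "income.csv",
}


@dataclass
class RegisterBundle:
    """The six validated register tables of one study population."""

    civil: pd.DataFrame
    psychiatric: pd.DataFrame
    drg_costs: pd.DataFrame
    prescriptions: pd.DataFrame
    primary_care: pd.DataFrame
    income: pd.DataFrame

    def validate(self) -> "RegisterBundle":
        for f in dc_fields(self):
            setattr(self, f.name, validate_register(getattr(self, f.name), f.name))
        known = set(self.civil["person_id"])
        for name in ("psychiatric", "drg_costs", "prescriptions", "primary_care", "income"):
            ids = getattr(self, name)["person_id"]
            unknown = ~ids.isin(known)
            if unknown.any():
                rows = np.flatnonzero(unknown.to_numpy())[:5].tolist()
                raise ValidationError(
                    f"{name}: person_id not present in civil register (rows {rows})",
                    rows=rows,
                )
        return self

    def write_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, fname in BUNDLE_FILES.items():
            write_register(getattr(self, name), directory / fname, name)

    @classmethod
    def read_dir(cls, directory: str | Path) -> "RegisterBundle":
        directory = Path(directory)
        tables = {
            name: read_register(directory / fname, name)
            for name, fname in BUNDLE_FILES.items()
        }
        return cls(**tables).validate()


def empty_register(schema_name: str) -> pd.DataFrame:
    """An empty but schema-complete table (useful for degenerate scenarios)."""
    schema = SCHEMAS[schema_name]
    return validate_register(pd.DataFrame({c: [] for c in schema.column_names}), schema_name)
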