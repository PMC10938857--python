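"""Independent brute-force recomputation of the pipeline's quantities.

Everything here is deliberately written with plain Python loops, dicts and
``datetime.date`` arithmetic, sharing no code with the package internals, so
it can serve as an oracle for the vectorised implementation on small inputs.
"""

from __future__ import annotations

import calendar
import datetime as dt
from collections import defaultdict

import pandas as pd


def to_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and value != value) or value is pd.NaT:
        return None
    ts = pd.Timestamp(value)
    if ts is pd.NaT:
        return None
    return ts.date()


def add_years(d: dt.date, n: int) -> dt.date:
    try:
        return d.replace(year=d.year + n)
    except ValueError:  # 29 Feb
        return d.replace(year=d.year + n, day=28)


def add_months(d: dt.date, n: int) -> dt.date:
    total = d.year * 12 + (d.month - 1) + n
    year, month = divmod(total, 12)
    month += 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def overlap_days(a0, a1, b0, b1) -> int:
    lo = max(a0, b0)
    hi = min(a1, b1)
    return max((hi - lo).days, 0)


def window(person: dict, config) -> tuple[dt.date, dt.date] | None:
    birth = to_date(person["birth_date"])
    start = max(config.followup_start, birth)
    imm = to_date(person["immigration_date"])
    if imm is not None:
        start = max(start, imm)
    end = config.followup_end
    for key in ("death_date", "emigration_date"):
        d = to_date(person[key])
        if d is not None:
            end = min(end, d)
    end = min(end, add_years(birth, config.censor_age))
    if start >= end:
        return None
    return start, end


def norm_code(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def qualifies(code: str, event_date, birth, disorder) -> bool:
    n = norm_code(code)
    if not any(n.startswith(norm_code(p)) for p in disorder.icd10_codes):
        return False
    return to_date(event_date) >= add_years(to_date(birth), disorder.earliest_onset_age)


def first_qualifying(psych_rows, birth_by_person, disorder) -> dict:
    first: dict = {}
    for row in psych_rows:
        pid = row["person_id"]
        if qualifies(row["icd10_code"], row["event_date"], birth_by_person[pid], disorder):
            d = to_date(row["event_date"])
            if pid not in first or d < first[pid]:
                first[pid] = d
    return first


def eligible_controls(case_pid, index_date, disorder, civil_rows, psych_rows, config) -> set:
    """Brute-force scan of the whole pool for one case."""
    by_id = {r["person_id"]: r for r in civil_rows}
    case = by_id[case_pid]
    case_birth = to_date(case["birth_date"])
    lo = add_months(case_birth, -config.birthdate_tolerance_months)
    hi = add_months(case_birth, config.birthdate_tolerance_months)
    idx = to_date(index_date)
    birth_by_person = {r["person_id"]: r["birth_date"] for r in civil_rows}
    fq = first_qualifying(psych_rows, birth_by_person, disorder)
    out = set()
    for r in civil_rows:
        pid = r["person_id"]
        if pid == case_pid or r["sex"] != case["sex"]:
            continue
        b = to_date(r["birth_date"])
        if not (lo <= b <= hi) or b > idx:
            continue
        imm = to_date(r["immigration_date"])
        if imm is not None and imm > idx:
            continue
        death = to_date(r["death_date"])
        if death is not None and death <= idx:
            continue
        emig = to_date(r["emigration_date"])
        if emig is not None and emig <= idx:
            continue
        if config.control_history_rule == "ever":
            if pid in fq:
                continue
        elif pid in fq and fq[pid] <= idx:
            continue
        out.add(pid)
    return out


def panels(bundle, deflators, config) -> dict:
    """(person_id, year) -> component dict in reference-year Euro."""
    civil_rows = bundle.civil.to_dict("records")
    win = {}
    for person in civil_rows:
        w = window(person, config)
        if w is not None:
            win[person["person_id"]] = w

    ref = deflators.values[deflators.reference_year]

    def eur(amount, year):
        return amount * ref / deflators.values[year] / deflators.fx_rate_2017

    nominal = defaultdict(lambda: defaultdict(float))
    for row in bundle.drg_costs.to_dict("records"):
        key = "psych_cost" if row["category"] == "psych_drg" else "somatic_cost"
        nominal[(row["person_id"], row["year"])][key] += row["amount_nominal"]
    for row in bundle.prescriptions.to_dict("records"):
        k = (row["person_id"], row["year"])
        nominal[k]["rx_service"] += row["service_nominal"]
        nominal[k]["rx_oop"] += row["out_of_pocket_nominal"]
    for row in bundle.primary_care.to_dict("records"):
        nominal[(row["person_id"], row["year"])]["primary_care_cost"] += row["amount_nominal"]
    transfer_cols = [c for c in bundle.income.columns if c not in ("person_id", "year", "personal_income")]
    for row in bundle.income.to_dict("records"):
        k = (row["person_id"], row["year"])
        nominal[k]["income"] += row["personal_income"]
        for c in transfer_cols:
            nominal[k][c] += row[c]

    out = {}
    for pid, (start, end) in win.items():
        for year in range(start.year, (end - dt.timedelta(days=1)).year + 1):
            ys, ye = dt.date(year, 1, 1), dt.date(year + 1, 1, 1)
            py = overlap_days(start, end, ys, ye) / days_in_year(year)
            if py <= 0:
                continue
            raw = nominal.get((pid, year), {})
            comp = {key: eur(val, year) for key, val in raw.items()}
            rx_sub = max(comp.get("rx_service", 0.0) - comp.get("rx_oop", 0.0), 0.0)
            panel = {
                "person_years": py,
                "psych_cost": comp.get("psych_cost", 0.0),
                "somatic_cost": comp.get("somatic_cost", 0.0),
                "rx_subsidised_cost": rx_sub,
                "rx_out_of_pocket_cost": comp.get("rx_oop", 0.0),
                "primary_care_cost": comp.get("primary_care_cost", 0.0),
                "income": comp.get("income", 0.0),
                "transfers_total": sum(comp.get(c, 0.0) for c in transfer_cols),
            }
            panel["healthcare_cost"] = (
                panel["psych_cost"] + panel["somatic_cost"]
                + panel["rx_subsidised_cost"] + panel["primary_care_cost"]
            )
            out[(pid, year)] = panel
    return out


COMPONENTS = (
    "psych_cost", "somatic_cost", "rx_subsidised_cost", "rx_out_of_pocket_cost",
    "primary_care_cost", "healthcare_cost", "income", "transfers_total",
)


def age_band_of(birth, year: int) -> str:
    age = (dt.date(year, 7, 1) - to_date(birth)).days / 365.25
    lo = min(int(age // 5) * 5, 90)
    lo = max(lo, 0)
    return f"{lo}-{lo + 4}"


def estimates(bundle, sets_df, controls_df, denominators, deflators, config) -> dict:
    """(disorder, measure, kind, component, stratifier, stratum) -> value.

    Recomputes every stratum estimate by direct looping.
    """
    pan = panels(bundle, deflators, config)
    civil_by_id = bundle.civil.set_index("person_id")
    controls_by_set = defaultdict(list)
    for row in controls_df.to_dict("records"):
        controls_by_set[row["set_id"]].append(row["control_id"])

    # Study-period averaging denominator.
    F = 0.0
    for year in range(config.followup_start.year, config.followup_end.year + 1):
        ys, ye = dt.date(year, 1, 1), dt.date(year + 1, 1, 1)
        F += overlap_days(config.followup_start, config.followup_end, ys, ye) / days_in_year(year)

    sums = defaultdict(lambda: defaultdict(float))   # (kind, stratifier)(key) -> totals
    for s in sets_df.to_dict("records"):
        pid = s["case_id"]
        sex = civil_by_id.at[pid, "sex"]
        birth = civil_by_id.at[pid, "birth_date"]
        for year in range(config.followup_start.year, config.followup_end.year + 1):
            case_panel = pan.get((pid, year))
            if case_panel is None:
                continue
            band = age_band_of(birth, year)
            strata = {"overall": "overall", "sex": sex, "age_band": band}
            ctrl_w = 0.0
            ctrl_sum = defaultdict(float)
            for cid in controls_by_set.get(s["set_id"], []):
                cp = pan.get((cid, year))
                if cp is None:
                    continue
                ctrl_w += 1.0
                for comp in COMPONENTS:
                    ctrl_sum[comp] += cp[comp]
            for stratifier, stratum in strata.items():
                key = (s["disorder"], stratifier, stratum)
                sums[("absolute", "py")][key] += case_panel["person_years"]
                for comp in COMPONENTS:
                    sums[("absolute", comp)][key] += case_panel[comp]
                if ctrl_w > 0:
                    sums[("excess", "py")][key] += case_panel["person_years"]
                    for comp in COMPONENTS:
                        sums[("excess", comp)][key] += case_panel[comp] - ctrl_sum[comp] / ctrl_w

    out = {}
    kinds = ("absolute", "excess")
    for kind in kinds:
        for key, py in sums[(kind, "py")].items():
            disorder, stratifier, stratum = key
            for comp in COMPONENTS:
                total = sums[(kind, comp)][key]
                out[(disorder, "nationwide_annual", kind, comp, stratifier, stratum)] = total / F
                out[(disorder, "per_case_annual", kind, comp, stratifier, stratum)] = total / py
                denom = denominators.for_stratum(stratifier, stratum)
                if denom > 0:
                    out[(disorder, "per_capita_annual", kind, comp, stratifier, stratum)] = total / F / denom
    for kind in kinds:
        for key, py in sums[(kind, "py")].items():
            disorder, stratifier, stratum = key
            out[(disorder, "py", kind, stratifier, stratum)] = py
    return out
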