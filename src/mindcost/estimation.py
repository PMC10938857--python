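"""Absolute and excess cost estimands for matched case-control person-years.

Estimands, all in 2017 Euro:

* ``nationwide_annual``: the cases' yearly total (absolute) or yearly total of
  case-minus-control differences (excess), averaged over the study period with
  the partial final year entering at its window fraction:
  ``sum over study years of the yearly total / sum of yearly window fractions``.
* ``per_case_annual``:   total over follow-up divided by case person-years.
* ``per_capita_annual``: nationwide annual divided by the population
  denominator of the stratum.

Within a matched set the control reference value for a calendar year is the
mean over the controls still under follow-up that year (equal weights:
annual register amounts already scale with each control's own presence, so
weighting them again by person-time would bias the reference); sets whose
controls all lack person-time in a year are skipped for the excess measures
in that year (counted in the diagnostics, never imputed).  Income excess is
case minus control, hence negative when cases earn less.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _dates
from .cohort import MatchedCohort
from .config import PopulationDenominators, StudyConfig, age_band
from .errors import ConfigError

log = logging.getLogger(__name__)

#: Components for which estimands are produced.
COMPONENTS = (
    "psych_cost",
    "somatic_cost",
    "rx_subsidised_cost",
    "rx_out_of_pocket_cost",
    "primary_care_cost",
    "healthcare_cost",
    "income",
    "transfers_total",
)

MEASURES = ("nationwide_annual", "per_case_annual", "per_capita_annual")
COST_KINDS = ("absolute", "excess")
STRATIFIERS = ("overall", "sex", "age_band")


@dataclass
class SetYearTable:
    """Per (matched set, calendar year) case values and control references.

    ``data`` columns: set_id, disorder, case_id, index_date, year, sex,
    age_band, case_py, has_controls, <comp> (case value), ctrl_<comp>
    (mean over surviving controls), exc_<comp> (difference; NaN when no
    controls).
    """

    data: pd.DataFrame
    components: tuple[str, ...]
    diagnostics: dict = field(default_factory=dict)


def set_year_table(
    cohort: MatchedCohort,
    panels: pd.DataFrame,
    civil: pd.DataFrame,
    components=COMPONENTS,
) -> SetYearTable:
    """Join case and control panels per matched set and calendar year."""
    components = tuple(components)
    for comp in components:
        if comp not in panels.columns:
            raise ConfigError(f"unknown cost component {comp!r}")

    case_cols = ["set_id", "disorder", "case_id", "index_date"]
    case = cohort.sets[case_cols].merge(
        panels.rename(columns={"person_id": "case_id"}), on="case_id", how="inner"
    )
    case = case.rename(columns={"person_years": "case_py"})

    sexes = civil.set_index("person_id")["sex"]
    births = civil.set_index("person_id")["birth_date"]
    case["sex"] = case["case_id"].map(sexes)
    july1 = pd.to_datetime(pd.DataFrame({"year": case["year"], "month": 7, "day": 1}))
    case["age_band"] = age_band(_dates.age_on(july1, case["case_id"].map(births)))

    ctrl = cohort.controls.merge(
        panels.rename(columns={"person_id": "control_id"}), on="control_id", how="inner"
    )
    # Controls under follow-up in the year enter the reference mean with equal
    # weight: their annual amounts already scale with their own presence, so
    # weighting again by person-years would bias the reference (censored
    # controls carry mechanically smaller annual amounts).
    present = (ctrl["person_years"].to_numpy() > 0).astype(float)
    weighted = {"ctrl_w": present}
    for comp in components:
        weighted[f"ctrl_{comp}"] = ctrl[comp].to_numpy() * present
    wdf = pd.DataFrame(weighted, index=ctrl.index)
    wdf[["set_id", "year"]] = ctrl[["set_id", "year"]]
    ctrl_sums = wdf.groupby(["set_id", "year"], as_index=False).sum()

    data = case.merge(ctrl_sums, on=["set_id", "year"], how="left")
    ctrl_w = data.pop("ctrl_w").fillna(0.0)
    data["has_controls"] = ctrl_w.to_numpy() > 0
    for comp in components:
        mean = np.where(ctrl_w > 0, data[f"ctrl_{comp}"].fillna(0.0) / ctrl_w.where(ctrl_w > 0, 1.0), np.nan)
        data[f"ctrl_{comp}"] = mean
        data[f"exc_{comp}"] = data[comp] - mean

    skipped = int((~data["has_controls"]).sum())
    if skipped:
        log.info("%d set-year(s) skipped for excess measures (no control person-time)", skipped)
    diagnostics = {
        "n_sets": int(len(cohort.sets)),
        "n_set_years": int(len(data)),
        "skipped_set_years": skipped,
        "deficient_sets": int(len(cohort.deficient)),
    }
    return SetYearTable(data=data, components=components, diagnostics=diagnostics)


def excess_by_year(table: SetYearTable, component: str, year: int) -> float:
    """Nationwide excess for one component in one calendar year.

    Sum over matched sets (with case person-time and surviving controls in
    the year) of case value minus the mean over surviving controls.
    """
    if component not in table.components:
        raise ConfigError(f"unknown cost component {component!r}")
    rows = table.data
    sel = rows[(rows["year"] == year) & rows["has_controls"]]
    return float(sel[f"exc_{component}"].sum())


def _strata(df: pd.DataFrame, stratifier: str) -> pd.Series:
    if stratifier == "overall":
        return pd.Series("overall", index=df.index)
    if stratifier in ("sex", "age_band"):
        return df[stratifier]
    raise ConfigError(f"unknown stratifier {stratifier!r}")


def aggregate(
    table: SetYearTable,
    denominators: PopulationDenominators,
    config: StudyConfig,
) -> pd.DataFrame:
    """All StratumEstimates: measure x cost kind x component x stratum.

    Output columns: disorder, measure, cost_kind, component, stratifier,
    stratum, value, n_case_person_years.  Strata with a zero population
    denominator are omitted with a logged reason.
    """
    rows = table.data
    F = config.total_year_fraction
    out_parts = []
    for stratifier in STRATIFIERS:
        strata = _strata(rows, stratifier)
        for kind in COST_KINDS:
            if kind == "excess":
                sel = rows["has_controls"].to_numpy()
                cols = {c: f"exc_{c}" for c in table.components}
            else:
                sel = np.ones(len(rows), dtype=bool)
                cols = {c: c for c in table.components}
            sub = rows[sel]
            key = pd.DataFrame({
                "disorder": sub["disorder"], "stratum": strata[sel],
            })
            agg_cols = {comp: sub[col].to_numpy() for comp, col in cols.items()}
            agg_cols["case_py"] = sub["case_py"].to_numpy()
            g = pd.DataFrame(agg_cols, index=sub.index)
            g[["disorder", "stratum"]] = key
            sums = g.groupby(["disorder", "stratum"], as_index=False).sum()
            if config.per_case_weighting == "persons":
                pc = _per_case_person_weighted(sub, strata[sel], cols)
                sums = sums.merge(pc, on=["disorder", "stratum"], how="left")
            for comp in table.components:
                total = sums[comp].to_numpy()
                py = sums["case_py"].to_numpy()
                nat = total / F
                with np.errstate(invalid="ignore", divide="ignore"):
                    if config.per_case_weighting == "persons":
                        per_case = sums[f"pw_{comp}"].to_numpy()
                    else:
                        per_case = np.where(py > 0, total / np.where(py > 0, py, 1.0), np.nan)
                for measure, values in (
                    ("nationwide_annual", nat),
                    ("per_case_annual", per_case),
                ):
                    out_parts.append(pd.DataFrame({
                        "disorder": sums["disorder"],
                        "measure": measure,
                        "cost_kind": kind,
                        "component": comp,
                        "stratifier": stratifier,
                        "stratum": sums["stratum"],
                        "value": values,
                        "n_case_person_years": py,
                    }))
                denom = np.array([
                    denominators.for_stratum(stratifier, s) for s in sums["stratum"]
                ])
                keep = denom > 0
                if (~keep).any():
                    log.info("omitting %d per-capita stratum estimate(s) with zero denominator",
                             int((~keep).sum()))
                out_parts.append(pd.DataFrame({
                    "disorder": sums["disorder"][keep],
                    "measure": "per_capita_annual",
                    "cost_kind": kind,
                    "component": comp,
                    "stratifier": stratifier,
                    "stratum": sums["stratum"][keep],
                    "value": nat[keep] / denom[keep],
                    "n_case_person_years": py[keep],
                }))
    out = pd.concat(out_parts, ignore_index=True)
    return out.sort_values(
        ["disorder", "measure", "cost_kind", "component", "stratifier", "stratum"],
        kind="stable",
    ).reset_index(drop=True)


def _per_case_person_weighted(sub: pd.DataFrame, strata: pd.Series, cols: dict) -> pd.DataFrame:
    """Optional person-weighted per-case average: mean over cases of each
    case's own follow-up total divided by their person-years."""
    g = pd.DataFrame({
        "disorder": sub["disorder"], "stratum": strata, "case_id": sub["case_id"],
        "case_py": sub["case_py"].to_numpy(),
    })
    for comp, col in cols.items():
        g[comp] = sub[col].to_numpy()
    per_case = g.groupby(["disorder", "stratum", "case_id"], as_index=False).sum()
    out = per_case[["disorder", "stratum"]].drop_duplicates().reset_index(drop=True)
    for comp in cols:
        ratio = per_case[comp] / per_case["case_py"]
        tmp = per_case[["disorder", "stratum"]].assign(r=ratio)
        m = tmp.groupby(["disorder", "stratum"], as_index=False)["r"].mean()
        out = out.merge(m.rename(columns={"r": f"pw_{comp}"}), on=["disorder", "stratum"])
    return out


def years_since_diagnosis_profile(
    table: SetYearTable,
    civil: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Annual excess rate by years since diagnosis (offsets 0..13).

    Only cases first diagnosed inside the follow-up period (2004-2017 by
    default) contribute, mirroring the restriction imposed by cost-data
    availability.  Offset k covers [index + k years, index + k + 1 years).

    Because the cost registers are annual, a calendar year's excess mixes
    the offsets it straddles (a case diagnosed in June 2016 contributes
    offset 0 and, fractionally, offset 1 to calendar 2017).  The profile is
    therefore estimated by least squares on the exposure design: each
    set-year's annual excess is modelled as the sum over offsets of
    offset-level times the case's exposure to that offset within the year
    (time inside the offset interval while alive and resident).  This
    deconvolution returns the per-offset annual rate free of the smearing
    an overlap-weighted mean would leave at the diagnosis year.

    Returns columns: disorder, offset, component..., person_years, where
    person_years is the total exposure behind each offset estimate.
    """
    rows = table.data
    rows = rows[rows["has_controls"]]
    rows = rows[rows["index_date"] >= pd.Timestamp(config.followup_start)].reset_index(drop=True)
    if rows.empty:
        return pd.DataFrame(columns=["disorder", "offset", *table.components, "person_years"])

    # Alive-and-resident interval per case, capped at the final study year's
    # end: annual register amounts cover residency, not the (administrative)
    # follow-up cut-off inside the final year.
    civ = civil.set_index("person_id")
    horizon = pd.Timestamp(config.followup_end.year + 1, 1, 1)
    res_start = np.maximum(
        rows["case_id"].map(civ["birth_date"]).to_numpy().astype("datetime64[ns]"),
        rows["case_id"].map(civ["immigration_date"]).fillna(pd.Timestamp("1800-01-01")).to_numpy().astype("datetime64[ns]"),
    )
    res_end = np.minimum(
        rows["case_id"].map(civ["death_date"]).fillna(horizon).to_numpy().astype("datetime64[ns]"),
        rows["case_id"].map(civ["emigration_date"]).fillna(horizon).to_numpy().astype("datetime64[ns]"),
    )
    res_end = np.minimum(res_end, horizon.to_numpy())

    ystart = pd.to_datetime(pd.DataFrame({"year": rows["year"], "month": 1, "day": 1})).to_numpy()
    yend = pd.to_datetime(pd.DataFrame({"year": rows["year"] + 1, "month": 1, "day": 1})).to_numpy()
    diy = _dates.days_in_year(rows["year"].to_numpy())

    n_off = config.max_offset + 1
    idx = pd.Series(rows["index_date"].to_numpy(), index=rows.index)
    ann = [
        _dates.add_years(idx, k).to_numpy().astype("datetime64[ns]")
        for k in range(n_off + 1)
    ]
    design = np.zeros((len(rows), n_off))
    for k in range(n_off):
        a = np.maximum.reduce([ystart, res_start, ann[k]])
        b = np.minimum.reduce([yend, res_end, ann[k + 1]])
        design[:, k] = np.maximum((b - a) / np.timedelta64(1, "D"), 0.0) / diy

    out_parts = []
    for disorder, grp_idx in rows.groupby("disorder").groups.items():
        loc = rows.index.get_indexer(grp_idx)
        O = design[loc]
        exposure = O.sum(axis=0)
        seen = exposure > 0
        part = pd.DataFrame({"disorder": disorder, "offset": np.arange(n_off)[seen],
                             "person_years": exposure[seen]})
        for comp in table.components:
            y = rows.loc[grp_idx, f"exc_{comp}"].to_numpy()
            beta, *_ = np.linalg.lstsq(O[:, seen], y, rcond=None)
            part[comp] = beta
        out_parts.append(part)
    out = pd.concat(out_parts, ignore_index=True)
    return out[["disorder", "offset", *table.components, "person_years"]].sort_values(
        ["disorder", "offset"], kind="stable"
    ).reset_index(drop=True)


def excess_with_se(
    table: SetYearTable,
    component: str,
    stratifier: str = "overall",
    cohort: MatchedCohort | None = None,
    panels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-case-annual excess with a matched-set-clustered standard error.

    Used to validate simulations (null and parameter recovery); the study
    outputs themselves carry no interval estimates.  Treating matched sets
    as independent clusters, for per-set sums d_s (excess) and p_s (case
    person-years) the ratio estimate is R = sum d / sum p with
    SE = sqrt(sum (d_s - R p_s)^2) / sum p.

    When ``cohort`` and ``panels`` are supplied, the variance additionally
    accounts for controls shared between sets: a person serving in several
    sets correlates their excess residuals, which pure set-clustering
    ignores (under-covering).  The covariance is estimated from each shared
    control's within-set-year deviations, sum over persons of
    (sum_s dev)^2 - sum_s dev^2 with dev = -(v - set mean)/m.
    """
    rows = table.data
    rows = rows[rows["has_controls"]]
    strata = _strata(rows, stratifier)
    g = pd.DataFrame({
        "disorder": rows["disorder"], "stratum": strata, "set_id": rows["set_id"],
        "d": rows[f"exc_{component}"].to_numpy(), "p": rows["case_py"].to_numpy(),
    })
    per_set = g.groupby(["disorder", "stratum", "set_id"], as_index=False)[["d", "p"]].sum()

    cross: dict[tuple, float] = {}
    if cohort is not None and panels is not None:
        meta = rows[["set_id", "year", f"ctrl_{component}"]].copy()
        meta["stratum"] = strata
        meta["disorder"] = rows["disorder"]
        ctrl = cohort.controls.merge(
            panels[["person_id", "year", component]].rename(
                columns={"person_id": "control_id", component: "v"}),
            on="control_id",
        )
        ctrl = ctrl.merge(meta, on=["set_id", "year"], how="inner")
        m = ctrl.groupby(["set_id", "year"])["control_id"].transform("size")
        ctrl["dev"] = -(ctrl["v"] - ctrl[f"ctrl_{component}"]) / m
        per_person = ctrl.groupby(["disorder", "stratum", "control_id"])["dev"].agg(
            S="sum", Q=lambda s: float((s**2).sum()))
        per_person["cross"] = per_person["S"] ** 2 - per_person["Q"]
        cross = per_person.groupby(["disorder", "stratum"])["cross"].sum().to_dict()

    out_rows = []
    for (dis, stratum), grp in per_set.groupby(["disorder", "stratum"]):
        p_tot = grp["p"].sum()
        if p_tot <= 0:
            continue
        r = grp["d"].sum() / p_tot
        resid = grp["d"] - r * grp["p"]
        var = float((resid**2).sum()) + max(cross.get((dis, stratum), 0.0), 0.0)
        se = float(np.sqrt(max(var, 0.0)) / p_tot)
        out_rows.append((dis, stratifier, stratum, float(r), se, float(p_tot), len(grp)))
    return pd.DataFrame(
        out_rows,
        columns=["disorder", "stratifier", "stratum", "estimate", "se", "case_person_years", "n_sets"],
    )
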