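"""Synthetic register bundles with known ground-truth cost effects.

The generator emulates the statistical skeleton of the Danish register
setting: a population with births 1930-2016, age-dependent mortality
(Gompertz-type), a small immigrant fraction and a low emigration hazard;
psychiatric first-contact hazards per disorder scaled so disorder
frequencies resemble the published Danish case counts; right-skewed,
zero-inflated baseline healthcare costs; an age-profiled personal income
with persistent person effects; and age-rule-based public transfers.

Disorder-attributable effects are injected deterministically per case
person-year: an extra psychiatric and somatic hospital cost, an income
decrement (floored so income stays non-negative) and a transfer increment,
each scaled by ``decay**k`` where k is years since the index diagnosis and
prorated by the time the offset interval overlaps the calendar year within
the person's residency.  Because the injected amounts are recorded exactly
(the ground truth), downstream excess estimates can be validated against
direct enumeration rather than against a second stochastic model.

Amounts are parameterised in 2017 Euro and written to the registers in
nominal local currency (the inverse of the pipeline's deflation), so the
injected effects come back on the Euro scale without deflator error.

Discrete-time structure: costs live at yearly resolution (2004-2017, the
years with cost data); event dates are continuous.  One global seed drives
stage-wise substreams, so identical parameters and seed give byte-identical
bundles.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from . import _dates, cohort
from .catalogue import ANY_MENTAL_DISORDER, DisorderDefinition, default_catalogue
from .config import DeflatorTable, PopulationDenominators, StudyConfig, default_deflators
from .errors import ConfigError
from .register_io import PROVIDER_TYPES, TRANSFER_COLUMNS, RegisterBundle

#: Annual first-contact hazards, scaled from published Danish case counts
#: (cases / ~5.6M population / ~20 observed years).
DEFAULT_HAZARDS: dict[str, float] = {
    "alcohol-use disorder": 4.3e-4,
    "opioid-use disorder": 4.5e-5,
    "cannabis-use disorder": 1.4e-4,
    "cocaine-use disorder": 1.6e-5,
    "amphetamine-use disorder": 2.1e-5,
    "other drug-use disorders": 5.8e-5,
    "schizophrenia": 3.1e-4,
    "bipolar disorder": 2.3e-4,
    "major depressive disorder": 1.5e-3,
    "dysthymia": 5.5e-5,
    "anxiety disorders": 9.7e-4,
    "anorexia nervosa": 8.4e-5,
    "bulimia nervosa": 4.7e-5,
    "personality disorders": 6.8e-4,
    "intellectual disabilities": 1.8e-4,
    "autism spectrum disorders": 2.7e-4,
    "ADHD": 4.2e-4,
    "conduct disorders": 1.8e-5,
}

#: Share of cases that are female, from the published sex-specific counts.
DEFAULT_FEMALE_SHARE: dict[str, float] = {
    "alcohol-use disorder": 0.34,
    "opioid-use disorder": 0.34,
    "cannabis-use disorder": 0.24,
    "cocaine-use disorder": 0.25,
    "amphetamine-use disorder": 0.27,
    "other drug-use disorders": 0.54,
    "schizophrenia": 0.42,
    "bipolar disorder": 0.59,
    "major depressive disorder": 0.63,
    "dysthymia": 0.64,
    "anxiety disorders": 0.61,
    "anorexia nervosa": 0.94,
    "bulimia nervosa": 0.98,
    "personality disorders": 0.65,
    "intellectual disabilities": 0.40,
    "autism spectrum disorders": 0.26,
    "ADHD": 0.32,
    "conduct disorders": 0.24,
}


class DisorderEffect(BaseModel):
    """Disorder-attributable per-case-year effects in 2017 Euro at offset 0."""

    excess_psych_cost: float = Field(default=0.0, ge=0)
    excess_somatic_cost: float = Field(default=0.0, ge=0)
    income_decrement: float = Field(default=0.0, ge=0)
    transfer_increment: float = Field(default=0.0, ge=0)
    decay: float = Field(default=1.0, gt=0, le=1)


#: Plausible default scenario, magnitudes in the range of published per-case
#: figures (severe psychotic and substance-use disorders most costly).
DEFAULT_EFFECTS: dict[str, DisorderEffect] = {
    "alcohol-use disorder": DisorderEffect(excess_psych_cost=2500, excess_somatic_cost=2000, income_decrement=12000, transfer_increment=4000, decay=0.85),
    "opioid-use disorder": DisorderEffect(excess_psych_cost=3500, excess_somatic_cost=2500, income_decrement=18000, transfer_increment=7000, decay=0.90),
    "cannabis-use disorder": DisorderEffect(excess_psych_cost=3000, excess_somatic_cost=800, income_decrement=12000, transfer_increment=5000, decay=0.85),
    "cocaine-use disorder": DisorderEffect(excess_psych_cost=3000, excess_somatic_cost=900, income_decrement=13000, transfer_increment=5000, decay=0.85),
    "amphetamine-use disorder": DisorderEffect(excess_psych_cost=3200, excess_somatic_cost=1000, income_decrement=15000, transfer_increment=6000, decay=0.88),
    "other drug-use disorders": DisorderEffect(excess_psych_cost=3200, excess_somatic_cost=1500, income_decrement=16000, transfer_increment=6500, decay=0.88),
    "schizophrenia": DisorderEffect(excess_psych_cost=12000, excess_somatic_cost=1500, income_decrement=22000, transfer_increment=9000, decay=0.92),
    "bipolar disorder": DisorderEffect(excess_psych_cost=6000, excess_somatic_cost=1000, income_decrement=12000, transfer_increment=5000, decay=0.90),
    "major depressive disorder": DisorderEffect(excess_psych_cost=2800, excess_somatic_cost=900, income_decrement=8000, transfer_increment=3000, decay=0.82),
    "dysthymia": DisorderEffect(excess_psych_cost=2000, excess_somatic_cost=700, income_decrement=7000, transfer_increment=2500, decay=0.85),
    "anxiety disorders": DisorderEffect(excess_psych_cost=1800, excess_somatic_cost=700, income_decrement=6500, transfer_increment=2500, decay=0.82),
    "anorexia nervosa": DisorderEffect(excess_psych_cost=7000, excess_somatic_cost=900, income_decrement=5000, transfer_increment=2000, decay=0.85),
    "bulimia nervosa": DisorderEffect(excess_psych_cost=3500, excess_somatic_cost=700, income_decrement=4500, transfer_increment=1800, decay=0.82),
    "personality disorders": DisorderEffect(excess_psych_cost=4500, excess_somatic_cost=1200, income_decrement=10000, transfer_increment=4000, decay=0.85),
    "intellectual disabilities": DisorderEffect(excess_psych_cost=3000, excess_somatic_cost=1500, income_decrement=14000, transfer_increment=8000, decay=0.97),
    "autism spectrum disorders": DisorderEffect(excess_psych_cost=4000, excess_somatic_cost=800, income_decrement=9000, transfer_increment=5000, decay=0.95),
    "ADHD": DisorderEffect(excess_psych_cost=2500, excess_somatic_cost=600, income_decrement=7000, transfer_increment=3000, decay=0.90),
    "conduct disorders": DisorderEffect(excess_psych_cost=2500, excess_somatic_cost=600, income_decrement=5000, transfer_increment=2000, decay=0.88),
}


class BaselineParams(BaseModel):
    """Baseline (disorder-independent) cost and income generators, 2017 Euro.

    Healthcare categories are zero-inflated lognormals; somatic cost rises
    with age; income follows a work-life age profile with a persistent
    person effect; transfers follow simple age rules.
    """

    p_psych: float = Field(default=0.015, ge=0, le=1)
    psych_mu: float = 7.0
    psych_sigma: float = 1.0
    p_somatic: float = Field(default=0.20, ge=0, le=1)
    somatic_mu: float = 7.0
    somatic_sigma: float = 1.2
    somatic_age_slope: float = 0.015
    p_rx: float = Field(default=0.55, ge=0, le=1)
    rx_mu: float = 5.2
    rx_sigma: float = 1.1
    oop_frac_low: float = 0.10
    oop_frac_high: float = 0.50
    p_primary: float = Field(default=0.80, ge=0, le=1)
    primary_mu: float = 5.0
    primary_sigma: float = 0.8
    income_mean: float = 36000.0
    income_person_sigma: float = 0.35
    income_year_sigma: float = 0.15
    employment_rate: float = Field(default=0.85, ge=0, le=1)
    # lognormal spread of individual transfer amounts around their age-rule
    # level (benefit entitlements vary across households)
    transfer_sigma: float = Field(default=0.3, ge=0)


class SimulationParams(BaseModel):
    """Everything that defines one synthetic study population."""

    n_persons: int = Field(default=20000, gt=0)
    seed: int = Field(default=0, ge=0, lt=2**31)
    birth_year_range: tuple[int, int] = (1930, 2016)
    sex_ratio_female: float = Field(default=0.5, ge=0, le=1)
    p_immigrant: float = Field(default=0.06, ge=0, le=1)
    immigration_max_age: float = Field(default=50.0, ge=0)
    emigration_hazard: float = Field(default=0.003, ge=0, le=1)
    mortality_base: float = Field(default=2e-4, ge=0, le=1)
    gompertz_scale: float = Field(default=3.5e-5, ge=0)
    gompertz_shape: float = Field(default=0.094, ge=0)
    register_start_year: int = 1995
    cost_start_year: int = 2004
    horizon_year: int = 2017
    extraction_date: dt.date = dt.date(2017, 4, 23)
    extra_contacts_rate: float = Field(default=0.8, ge=0)
    # Substream index for the baseline-cost stage.  Replications that share a
    # seed but vary this index redraw costs/income over a fixed population,
    # cohort and diagnosis history (used to measure estimator Monte-Carlo
    # error conditional on the cohort).
    cost_stream: int = Field(default=0, ge=0)
    disorder_hazards: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    disorder_female_share: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_FEMALE_SHARE))
    effects: dict[str, DisorderEffect] = Field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    baseline: BaselineParams = Field(default_factory=BaselineParams)
    deflators: DeflatorTable = Field(default_factory=default_deflators)

    @field_validator("disorder_hazards")
    @classmethod
    def _hazard_range(cls, v):
        for name, h in v.items():
            if not (0 <= h <= 1):
                raise ValueError(f"hazard for {name!r} must be in [0, 1] per year")
        return v

    @model_validator(mode="after")
    def _ranges(self):
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be increasing")
        return self

    def with_uniform_effects(self, effect: DisorderEffect) -> "SimulationParams":
        """Copy with the same effect for every disorder (scenario helper)."""
        return self.model_copy(update={"effects": {n: effect for n in self.disorder_hazards}})

    def with_zero_effects(self) -> "SimulationParams":
        return self.with_uniform_effects(DisorderEffect())


@dataclass
class GroundTruth:
    """What was injected, exactly, per case person-year (2017 Euro).

    ``injections`` columns: person_id, disorder, year, psych_cost,
    somatic_cost, transfers_total, income_decrement (the realised decrement
    after the income floor).  ``index_dates``: person_id, disorder,
    index_date for every registered first diagnosis.
    """

    params: SimulationParams
    index_dates: pd.DataFrame
    injections: pd.DataFrame
    case_counts: dict[str, int]


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage)])


def _date_from_days(origin: pd.Timestamp, days: np.ndarray) -> np.ndarray:
    return origin.to_numpy() + (days * 86400e9).astype("timedelta64[ns]")


def _floor_day(stamps: np.ndarray) -> np.ndarray:
    """Truncate datetime64[ns] values to day precision (NaT-safe)."""
    return stamps.astype("datetime64[D]").astype("datetime64[ns]")


def _simulate_demography(params: SimulationParams):
    n = params.n_persons
    rng = _stage_rng(params.seed, 1)
    ids = np.array([f"P{i:07d}" for i in range(n)])
    female = rng.random(n) < params.sex_ratio_female
    sex = np.where(female, "female", "male")

    b0 = pd.Timestamp(params.birth_year_range[0], 1, 1)
    b1 = pd.Timestamp(params.birth_year_range[1] + 1, 1, 1)
    span_days = (b1 - b0).days
    birth = _date_from_days(b0, np.floor(rng.random(n) * span_days))

    # Age at death from a Gompertz-type hazard, inverted on a yearly grid.
    ages = np.arange(0, 121)
    haz = params.mortality_base + params.gompertz_scale * np.exp(params.gompertz_shape * ages)
    cum = np.concatenate([[0.0], np.cumsum(haz)])
    e = rng.exponential(1.0, n)
    e = np.minimum(e, cum[-1] - 1e-9)  # force death by age 121
    idx = np.searchsorted(cum, e, side="right") - 1
    death_age = ages[idx] + (e - cum[idx]) / haz[idx]
    # All event dates are floored to day precision: the registers are daily.
    death = _floor_day(birth + (death_age * 365.2425 * 86400e9).astype("timedelta64[ns]"))

    # Immigration: a fraction arrives at a uniform age; arrivals after death
    # or after the data horizon are treated as never-resident natives.
    imm_age = rng.uniform(0, params.immigration_max_age, n)
    is_imm = rng.random(n) < params.p_immigrant
    imm = _floor_day(birth + (imm_age * 365.2425 * 86400e9).astype("timedelta64[ns]"))
    horizon = pd.Timestamp(params.horizon_year + 1, 1, 1).to_numpy()
    is_imm &= (imm < death) & (imm < horizon)
    imm = np.where(is_imm, imm, np.datetime64("NaT"))

    # Emigration: constant hazard from the start of residency.
    res_start = np.where(is_imm, imm, birth).astype("datetime64[ns]")
    if params.emigration_hazard > 0:
        t_emig = rng.exponential(1.0 / params.emigration_hazard, n)
    else:
        t_emig = np.full(n, np.inf)
    # Waits beyond the data horizon are equivalent to "never"; capping keeps
    # the ns-resolution datetime arithmetic from overflowing.
    t_emig = np.where(t_emig > 200.0, np.inf, t_emig)
    with np.errstate(invalid="ignore"):
        emig = _floor_day(res_start + np.where(
            np.isfinite(t_emig), t_emig * 365.2425 * 86400e9, np.nan
        ).astype("timedelta64[ns]"))
    has_emig = (~np.isnat(emig)) & (emig < death) & (emig < horizon) & (emig > res_start)
    emig = np.where(has_emig, emig, np.datetime64("NaT"))

    res_end = np.where(has_emig, emig, death).astype("datetime64[ns]")
    civil = pd.DataFrame({
        "person_id": ids,
        "sex": sex,
        "birth_date": birth,
        "immigration_date": imm,
        "emigration_date": emig,
        # Deaths beyond the data horizon are unknown to the registers.
        "death_date": np.where(death < horizon, death, np.datetime64("NaT")),
    })
    return civil, res_start, res_end


def _simulate_diagnoses(params, catalogue, civil, res_start, res_end):
    """First registered contact per (person, disorder), plus repeat contacts."""
    rng = _stage_rng(params.seed, 2)
    rng_extra = _stage_rng(params.seed, 3)
    n = len(civil)
    female = (civil["sex"] == "female").to_numpy()
    birth = civil["birth_date"].to_numpy()
    reg_start = pd.Timestamp(params.register_start_year, 1, 1).to_numpy()
    extraction = pd.Timestamp(params.extraction_date).to_numpy()

    named = [d for d in catalogue if d.name != ANY_MENTAL_DISORDER]
    idx_rows = []
    event_rows = []
    for d in named:
        h = params.disorder_hazards.get(d.name, 0.0)
        fshare = params.disorder_female_share.get(d.name, 0.5)
        h_sex = np.where(female, 2 * fshare * h, 2 * (1 - fshare) * h)
        u = rng.random(n)       # drawn unconditionally to keep streams aligned
        wait = np.where(h_sex > 0, -np.log1p(-u) / np.where(h_sex > 0, h_sex, 1.0), np.inf)
        wait = np.where(wait > 200.0, np.inf, wait)  # beyond any horizon; avoids ns overflow
        # Calendrical onset anniversary so case identification and the
        # generative model agree exactly at the boundary.
        onset = _dates.add_years(pd.Series(birth), d.earliest_onset_age).to_numpy().astype("datetime64[ns]")
        clock0 = np.maximum(np.maximum(onset, res_start), reg_start)
        with np.errstate(invalid="ignore"):
            diag = _floor_day(clock0 + np.where(
                np.isfinite(wait), wait * 365.2425 * 86400e9, np.nan
            ).astype("timedelta64[ns]"))
        registered = (~np.isnat(diag)) & (diag < np.minimum(res_end, extraction))
        sel = np.flatnonzero(registered)
        if len(sel) == 0:
            continue
        pids = civil["person_id"].to_numpy()[sel]
        dates = diag[sel]
        idx_rows.append(pd.DataFrame({"person_id": pids, "disorder": d.name, "index_date": dates}))

        # Index event plus a few repeat contacts.
        n_extra = rng_extra.poisson(params.extra_contacts_rate, len(sel))
        total = 1 + n_extra
        rep = np.repeat(np.arange(len(sel)), total)
        is_index = np.concatenate([[True] + [False] * e for e in n_extra])
        gaps = rng_extra.exponential(2.0, len(rep)) * 365.2425 * 86400e9
        ev_dates = np.where(is_index, dates[rep], dates[rep] + gaps.astype("timedelta64[ns]"))
        keep = ev_dates < np.minimum(res_end[sel][rep], extraction)
        codes = _draw_codes(d, rng_extra, len(rep))
        contact = rng_extra.choice(
            np.array(["inpatient", "outpatient", "emergency"]), size=len(rep), p=[0.25, 0.65, 0.10]
        )
        event_rows.append(pd.DataFrame({
            "person_id": pids[rep][keep],
            "event_date": ev_dates[keep],
            "icd10_code": codes[keep],
            "contact_type": contact[keep],
        }))

    index_dates = (
        pd.concat(idx_rows, ignore_index=True)
        if idx_rows
        else pd.DataFrame({"person_id": pd.Series(dtype=str), "disorder": pd.Series(dtype=str),
                           "index_date": pd.Series(dtype="datetime64[ns]")})
    )
    psychiatric = (
        pd.concat(event_rows, ignore_index=True)
        if event_rows
        else pd.DataFrame({"person_id": pd.Series(dtype=str),
                           "event_date": pd.Series(dtype="datetime64[ns]"),
                           "icd10_code": pd.Series(dtype=str),
                           "contact_type": pd.Series(dtype=str)})
    )
    psychiatric["event_date"] = pd.to_datetime(psychiatric["event_date"]).dt.normalize()
    index_dates["index_date"] = pd.to_datetime(index_dates["index_date"]).dt.normalize()
    psychiatric = psychiatric.sort_values(
        ["person_id", "event_date", "icd10_code"], kind="stable"
    ).reset_index(drop=True)
    return index_dates, psychiatric


def _draw_codes(d: DisorderDefinition, rng, size: int) -> np.ndarray:
    prefixes = np.asarray(d.icd10_codes)
    picked = prefixes[rng.integers(0, len(prefixes), size)]
    sub = rng.integers(0, 10, size)
    out = np.array([
        p if "." in p else f"{p}.{s}" for p, s in zip(picked, sub)
    ])
    return out


def _residency_grid(params, civil, res_start, res_end) -> pd.DataFrame:
    """Person-year rows for cost-data years overlapping residency."""
    y_lo = params.cost_start_year
    y_hi = params.horizon_year
    start = np.maximum(res_start, pd.Timestamp(y_lo, 1, 1).to_numpy())
    end = np.minimum(res_end, pd.Timestamp(y_hi + 1, 1, 1).to_numpy())
    ok = np.flatnonzero(start < end)
    s, e = start[ok], end[ok]
    y0 = s.astype("datetime64[Y]").astype(int) + 1970
    y1 = (e - np.timedelta64(1, "D")).astype("datetime64[Y]").astype(int) + 1970
    counts = y1 - y0 + 1
    rep = np.repeat(ok, counts)
    offs = np.concatenate([np.arange(c) for c in counts]) if len(counts) else np.array([], dtype=int)
    years = y0[np.repeat(np.arange(len(ok)), counts)] + offs
    ys = pd.to_datetime(pd.DataFrame({"year": years, "month": 1, "day": 1})).to_numpy()
    ye = pd.to_datetime(pd.DataFrame({"year": years + 1, "month": 1, "day": 1})).to_numpy()
    frac = _dates.overlap_days(res_start[rep], res_end[rep], ys, ye) / _dates.days_in_year(years)
    grid = pd.DataFrame({
        "pix": rep,
        "person_id": civil["person_id"].to_numpy()[rep],
        "year": years,
        "res_frac": frac,
    })
    grid = grid[grid["res_frac"] > 0].reset_index(drop=True)
    july1 = pd.to_datetime(pd.DataFrame({"year": grid["year"], "month": 7, "day": 1}))
    grid["age"] = (july1.to_numpy() - civil["birth_date"].to_numpy()[grid["pix"]]) \
        / np.timedelta64(1, "D") / 365.25
    return grid


def _baseline_costs(params: SimulationParams, grid: pd.DataFrame) -> pd.DataFrame:
    """Zero-inflated lognormal baseline costs and profiled income, 2017 Euro."""
    b = params.baseline
    if params.cost_stream:
        rng = np.random.default_rng([int(params.seed), 4, int(params.cost_stream)])
    else:
        rng = _stage_rng(params.seed, 4)
    m = len(grid)
    age = grid["age"].to_numpy()
    frac = grid["res_frac"].to_numpy()
    out = grid[["person_id", "pix", "year", "res_frac", "age"]].copy()

    def zil(p, mu, sigma, scale=None):
        mask = rng.random(m) < p
        amt = np.exp(rng.normal(mu, sigma, m))
        if scale is not None:
            amt = amt * scale
        return np.where(mask, amt, 0.0) * frac

    out["psych_cost"] = zil(b.p_psych, b.psych_mu, b.psych_sigma)
    out["somatic_cost"] = zil(
        b.p_somatic, b.somatic_mu, b.somatic_sigma,
        scale=np.exp(b.somatic_age_slope * (age - 40.0)),
    )
    rx = zil(b.p_rx, b.rx_mu, b.rx_sigma)
    oop_frac = rng.uniform(b.oop_frac_low, b.oop_frac_high, m)
    out["rx_service"] = rx
    out["rx_oop"] = rx * oop_frac
    out["primary_care_cost"] = zil(b.p_primary, b.primary_mu, b.primary_sigma)
    out["provider_type"] = np.asarray(PROVIDER_TYPES, dtype=object)[
        rng.choice(len(PROVIDER_TYPES), m, p=[0.55, 0.12, 0.05, 0.15, 0.08, 0.02, 0.03])
    ]

    # Work-life income profile with a persistent person effect.
    work = np.clip((age - 16.0) / 12.0, 0.0, 1.0)
    work = np.where(age >= 67, 0.05, np.where(age >= 60, work * (1 - 0.85 * (age - 60) / 7.0), work))
    n_persons = int(grid["pix"].max()) + 1 if m else 0
    perm = np.exp(rng.normal(0.0, b.income_person_sigma, n_persons)) if n_persons else np.array([])
    employed = rng.random(m) < b.employment_rate
    year_noise = np.exp(rng.normal(0.0, b.income_year_sigma, m))
    out["income"] = np.where(
        employed, b.income_mean * work * perm[grid["pix"].to_numpy()] * year_noise, 0.0
    ) * frac

    # Transfer components by age rules.
    u = {c: rng.random(m) for c in TRANSFER_COLUMNS}
    t = {}
    t["old_age_pension"] = np.where(age >= 67, 13000.0, 0.0)
    t["child_youth_benefits"] = np.where(age < 18, 1500.0, 0.0)
    t["state_educational_grants"] = np.where((age >= 18) & (age < 26) & (u["state_educational_grants"] < 0.35), 3200.0, 0.0)
    t["unemployment_benefits"] = np.where((age >= 18) & (age < 65) & ~employed & (u["unemployment_benefits"] < 0.5), 9000.0, 0.0)
    t["housing_benefits"] = np.where((age >= 18) & (u["housing_benefits"] < 0.12), 2500.0, 0.0)
    t["social_assistance"] = np.where((age >= 18) & (age < 65) & (u["social_assistance"] < 0.05), 7000.0, 0.0)
    t["disability_pension"] = np.where((age >= 30) & (age < 67) & (u["disability_pension"] < 0.015), 14000.0, 0.0)
    t["flexi_job"] = np.where((age >= 30) & (age < 67) & (u["flexi_job"] < 0.01), 10000.0, 0.0)
    t["early_retirement"] = np.where((age >= 60) & (age < 67) & (u["early_retirement"] < 0.15), 15000.0, 0.0)
    for c in TRANSFER_COLUMNS:
        spread = np.exp(rng.normal(0.0, b.transfer_sigma, m))
        out[c] = t[c] * spread * frac
    return out


def _inject_effects(params, catalogue, civil, res_start, res_end, index_dates, table):
    """Add decaying disorder effects to case person-years; return ground truth."""
    empty = pd.DataFrame({
        "person_id": pd.Series(dtype=str), "disorder": pd.Series(dtype=str),
        "year": pd.Series(dtype=int), "psych_cost": pd.Series(dtype=float),
        "somatic_cost": pd.Series(dtype=float), "transfers_total": pd.Series(dtype=float),
        "income_decrement": pd.Series(dtype=float),
    })
    if index_dates.empty:
        return table, empty

    pix_by_person = pd.Series(np.arange(len(civil)), index=civil["person_id"])
    cases = index_dates.copy()
    cases["pix"] = cases["person_id"].map(pix_by_person).to_numpy()

    # Case x resident-year rows from the diagnosis year onward.
    cy = cases.merge(table[["pix", "year"]].assign(row=np.arange(len(table))), on="pix")
    cy = cy[cy["year"] >= cy["index_date"].dt.year].reset_index(drop=True)
    if cy.empty:
        return table, empty

    ystart = pd.to_datetime(pd.DataFrame({"year": cy["year"], "month": 1, "day": 1})).to_numpy()
    yend = pd.to_datetime(pd.DataFrame({"year": cy["year"] + 1, "month": 1, "day": 1})).to_numpy()
    diy = _dates.days_in_year(cy["year"].to_numpy())
    rs = res_start[cy["pix"].to_numpy()]
    re_ = res_end[cy["pix"].to_numpy()]

    decay = np.array([params.effects.get(d, DisorderEffect()).decay for d in cy["disorder"]])
    max_k = params.horizon_year - params.register_start_year + 1
    ann = {}
    idx_series = pd.Series(cy["index_date"].to_numpy())
    for k in range(max_k + 1):
        ann[k] = _dates.add_years(idx_series, k).to_numpy().astype("datetime64[ns]")
    weight = np.zeros(len(cy))
    for k in range(max_k):
        a = np.maximum.reduce([ystart, rs, ann[k]])
        bnd = np.minimum.reduce([yend, re_, ann[k + 1]])
        o = np.maximum((bnd - a) / np.timedelta64(1, "D"), 0.0) / diy
        weight = weight + (decay**k) * o

    eff = {
        name: params.effects.get(name, DisorderEffect())
        for name in set(cy["disorder"])
    }
    e_psych = np.array([eff[d].excess_psych_cost for d in cy["disorder"]])
    e_som = np.array([eff[d].excess_somatic_cost for d in cy["disorder"]])
    e_inc = np.array([eff[d].income_decrement for d in cy["disorder"]])
    e_tra = np.array([eff[d].transfer_increment for d in cy["disorder"]])

    inj = pd.DataFrame({
        "row": cy["row"].to_numpy(),
        "person_id": cy["person_id"], "disorder": cy["disorder"], "year": cy["year"],
        "psych_cost": e_psych * weight, "somatic_cost": e_som * weight,
        "transfers_total": e_tra * weight, "income_target": e_inc * weight,
    })
    inj = inj[(inj[["psych_cost", "somatic_cost", "transfers_total", "income_target"]].sum(axis=1)) > 0]

    per_row = inj.groupby("row")[["psych_cost", "somatic_cost", "transfers_total", "income_target"]].sum()
    rows = per_row.index.to_numpy()
    table.loc[rows, "psych_cost"] = table.loc[rows, "psych_cost"] + per_row["psych_cost"].to_numpy()
    table.loc[rows, "somatic_cost"] = table.loc[rows, "somatic_cost"] + per_row["somatic_cost"].to_numpy()
    table.loc[rows, "disability_pension"] = table.loc[rows, "disability_pension"] + 0.6 * per_row["transfers_total"].to_numpy()
    table.loc[rows, "social_assistance"] = table.loc[rows, "social_assistance"] + 0.4 * per_row["transfers_total"].to_numpy()

    # Income floor: the decrement cannot take income below zero; realised
    # decrements are allocated to disorders proportionally to their targets.
    base_income = table.loc[rows, "income"].to_numpy()
    target = per_row["income_target"].to_numpy()
    realised = np.minimum(base_income, target)
    table.loc[rows, "income"] = base_income - realised
    scale = np.where(target > 0, realised / np.where(target > 0, target, 1.0), 0.0)
    scale_by_row = pd.Series(scale, index=rows)
    inj = inj.assign(income_decrement=inj["income_target"] * inj["row"].map(scale_by_row).to_numpy())
    injections = inj[[
        "person_id", "disorder", "year",
        "psych_cost", "somatic_cost", "transfers_total", "income_decrement",
    ]].reset_index(drop=True)
    return table, injections


def simulate_registers(
    params: SimulationParams, catalogue=None
) -> tuple[RegisterBundle, GroundTruth]:
    """Generate a register bundle plus the exact injected ground truth.

    Identical ``params`` (including the seed) produce byte-identical bundles;
    all cost, diagnosis and income rows lie within each person's
    alive-and-resident interval.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    unknown = set(params.disorder_hazards) - {d.name for d in catalogue}
    if unknown:
        raise ConfigError(f"hazards given for unknown disorder(s): {sorted(unknown)}")

    civil, res_start, res_end = _simulate_demography(params)
    index_dates, psychiatric = _simulate_diagnoses(params, catalogue, civil, res_start, res_end)
    grid = _residency_grid(params, civil, res_start, res_end)
    table = _baseline_costs(params, grid)
    table, injections = _inject_effects(
        params, catalogue, civil, res_start, res_end, index_dates, table
    )

    # EUR 2017 -> nominal local currency for the register files.
    defl = params.deflators
    inv = 1.0 / defl.factors(table["year"].to_numpy()) if len(table) else np.array([])
    money = ["psych_cost", "somatic_cost", "rx_service", "rx_oop",
             "primary_care_cost", "income", *TRANSFER_COLUMNS]
    nominal = table.copy()
    for c in money:
        nominal[c] = table[c].to_numpy() * inv

    drg_parts = []
    for cat, col in (("psych_drg", "psych_cost"), ("somatic_drg", "somatic_cost")):
        sel = nominal[nominal[col] > 0]
        drg_parts.append(pd.DataFrame({
            "person_id": sel["person_id"], "year": sel["year"],
            "category": cat, "amount_nominal": sel[col],
        }))
    drg = pd.concat(drg_parts, ignore_index=True).sort_values(
        ["person_id", "year", "category"], kind="stable"
    ).reset_index(drop=True)

    rx_sel = nominal[nominal["rx_service"] > 0]
    prescriptions = pd.DataFrame({
        "person_id": rx_sel["person_id"], "year": rx_sel["year"],
        "service_nominal": rx_sel["rx_service"],
        "out_of_pocket_nominal": rx_sel["rx_oop"],
    }).sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)

    pc_sel = nominal[nominal["primary_care_cost"] > 0]
    primary_care = pd.DataFrame({
        "person_id": pc_sel["person_id"], "year": pc_sel["year"],
        "provider_type": pc_sel["provider_type"],
        "amount_nominal": pc_sel["primary_care_cost"],
    }).sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)

    income = nominal[["person_id", "year", "income", *TRANSFER_COLUMNS]].rename(
        columns={"income": "personal_income"}
    ).sort_values(["person_id", "year"], kind="stable").reset_index(drop=True)

    bundle = RegisterBundle(
        civil=civil,
        psychiatric=psychiatric,
        drg_costs=drg,
        prescriptions=prescriptions,
        primary_care=primary_care,
        income=income,
    ).validate()

    counts = index_dates.groupby("disorder").size().to_dict()
    counts[ANY_MENTAL_DISORDER] = int(index_dates["person_id"].nunique())
    truth = GroundTruth(
        params=params,
        index_dates=index_dates.sort_values(["disorder", "person_id"], kind="stable").reset_index(drop=True),
        injections=injections,
        case_counts=counts,
    )
    return bundle, truth


def denominators_from_bundle(bundle: RegisterBundle, reference_date="2017-01-01") -> PopulationDenominators:
    return PopulationDenominators.from_civil(bundle.civil, reference_date)


def expected_estimands(
    bundle: RegisterBundle,
    truth: GroundTruth,
    config: StudyConfig,
    catalogue=None,
    cohort_sets=None,
    min_index_date=None,
) -> pd.DataFrame:
    """Expected excess estimands by direct enumeration of the injections.

    For every disorder (and the 'any' aggregate) and component, sums the
    injected amounts over the case person-years the pipeline observes and
    divides by case person-years (per-case annual) or by the study-period
    year fractions (nationwide annual).

    When ``cohort_sets`` (a :class:`~mindcost.cohort.MatchedCohort`) is
    given, the enumeration also subtracts the control side: controls
    diagnosed after the index date carry their own injected effects, which
    shrink the measured case-control gap (incidence-density matching leaves
    them in place by design).  With it, the returned value is the exact
    expectation of the matched excess estimator over the baseline noise.

    ``min_index_date`` restricts the enumeration to cases first diagnosed on
    or after that date (the restriction the years-after-diagnosis analyses
    use).  Standard errors are the between-case spread of injected per-case
    means; they exclude the control-side sampling noise of the matched
    estimator, so they are a lower bound on its Monte-Carlo error.

    Income is reported as a negative value (cases earn less), matching the
    pipeline's sign convention.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    windows = cohort.followup_windows(bundle.civil, config)
    from .costing import person_year_grid  # local import to avoid a cycle

    grid = person_year_grid(windows, config)
    py = grid.groupby(["person_id", "year"])["person_years"].sum()

    idx = truth.index_dates
    any_idx = idx.groupby("person_id", as_index=False)["index_date"].min()
    any_idx["disorder"] = ANY_MENTAL_DISORDER
    all_cases = pd.concat([idx, any_idx[["person_id", "disorder", "index_date"]]], ignore_index=True)
    lo, hi = config.case_window
    all_cases = all_cases[
        (all_cases["index_date"].dt.year >= lo) & (all_cases["index_date"].dt.year <= hi)
    ]
    if min_index_date is not None:
        all_cases = all_cases[all_cases["index_date"] >= pd.Timestamp(min_index_date)]

    components = ("psych_cost", "somatic_cost", "healthcare_cost", "income", "transfers_total")
    inj = truth.injections
    # Injected amounts per person-year summed over disorders: a case carries
    # every disorder they have (comorbidity), and a control's contamination
    # comes from every disorder they develop after the index date.  Using the
    # person-level totals on both sides makes the enumeration the exact
    # expectation of the matched excess estimator for each cohort.
    inj_person_year = inj.groupby(["person_id", "year"], as_index=False)[
        ["psych_cost", "somatic_cost", "transfers_total", "income_decrement"]
    ].sum()

    contamination = None
    if cohort_sets is not None:
        ctrl = cohort_sets.controls.merge(
            py.reset_index().rename(columns={"person_id": "control_id"}),
            on="control_id",
        )
        ctrl = ctrl.merge(
            inj_person_year.rename(columns={"person_id": "control_id"}),
            on=["control_id", "year"], how="left",
        ).fillna(0.0)
        per_set_year = ctrl.groupby(["set_id", "year"])[
            ["psych_cost", "somatic_cost", "transfers_total", "income_decrement"]
        ].mean().reset_index()
        contamination = per_set_year.merge(
            cohort_sets.sets[["set_id", "disorder", "case_id"]], on="set_id"
        ).rename(columns={"case_id": "person_id"})

    F = config.total_year_fraction
    out_rows = []
    for disorder, cases in all_cases.groupby("disorder"):
        case_years = cases[["person_id"]].merge(
            py.reset_index(), on="person_id", how="inner"
        )
        p_tot = case_years["person_years"].sum()
        if p_tot <= 0:
            continue
        merged = case_years.merge(inj_person_year, on=["person_id", "year"], how="left").fillna(0.0)
        if contamination is not None:
            con = contamination[contamination["disorder"] == disorder]
            merged = merged.merge(
                con[["person_id", "year", "psych_cost", "somatic_cost",
                     "transfers_total", "income_decrement"]],
                on=["person_id", "year"], how="left", suffixes=("", "_ctrl"),
            ).fillna(0.0)
            for c in ("psych_cost", "somatic_cost", "transfers_total", "income_decrement"):
                merged[c] = merged[c] - merged[f"{c}_ctrl"]
        merged["healthcare_cost"] = merged["psych_cost"] + merged["somatic_cost"]
        merged["income"] = -merged["income_decrement"]
        for comp in components:
            per_case = merged.groupby("person_id").agg(d=(comp, "sum"), p=("person_years", "sum"))
            total = per_case["d"].sum()
            r = total / p_tot
            resid = per_case["d"] - r * per_case["p"]
            se = float(np.sqrt((resid**2).sum()) / p_tot)
            out_rows.append((disorder, comp, "per_case_annual", r, se, len(per_case), float(p_tot)))
            out_rows.append((disorder, comp, "nationwide_annual", total / F, se * p_tot / F,
                             len(per_case), float(p_tot)))
    return pd.DataFrame(
        out_rows,
        columns=["disorder", "component", "measure", "expected", "se", "n_cases", "case_person_years"],
    )


def conditional_mc_se(
    params: SimulationParams,
    catalogue,
    config: StudyConfig,
    cohort_sets,
    deflators: DeflatorTable | None = None,
    components=("healthcare_cost", "income", "transfers_total"),
    stratifiers=("overall", "sex", "age_band"),
    n_reps: int = 30,
) -> pd.DataFrame:
    """Monte-Carlo standard error of the stratum excess estimators.

    Holds the population, diagnosis history and matched sets fixed and
    redraws the baseline cost/income stage ``n_reps`` times (via
    ``cost_stream``), recomputing the per-case-annual excess for every
    (disorder, stratum, component).  The across-replication standard
    deviation is the estimator's Monte-Carlo error conditional on the
    cohort -- the right yardstick for null- and parameter-recovery checks,
    where a single-realisation plug-in variance estimate is itself noisy
    under heavy-tailed cost distributions.

    Returns columns: disorder, stratifier, stratum, component, mc_se, n_reps.
    """
    from . import estimation
    from .costing import build_panels

    if deflators is None:
        deflators = params.deflators
    windows = None  # derived from the first replicate's civil register (identical every rep)

    samples: dict[tuple, list] = {}
    for rep in range(1, n_reps + 1):
        rep_params = params.model_copy(update={"cost_stream": rep})
        bundle, _ = simulate_registers(rep_params, catalogue)
        if windows is None:
            windows = cohort.followup_windows(bundle.civil, config)
        panels = build_panels(bundle, windows, deflators, config)
        table = estimation.set_year_table(cohort_sets, panels, bundle.civil, components)
        rows = table.data[table.data["has_controls"]]
        for stratifier in stratifiers:
            strata = estimation._strata(rows, stratifier)
            base = pd.DataFrame({
                "disorder": rows["disorder"], "stratum": strata,
                "p": rows["case_py"].to_numpy(),
            })
            for comp in components:
                base[comp] = rows[f"exc_{comp}"].to_numpy()
            sums = base.groupby(["disorder", "stratum"], as_index=False).sum()
            for _, r in sums.iterrows():
                if r["p"] <= 0:
                    continue
                for comp in components:
                    key = (r["disorder"], stratifier, r["stratum"], comp)
                    samples.setdefault(key, []).append(r[comp] / r["p"])
    out = [
        (dis, stratifier, stratum, comp, float(np.std(vals, ddof=1)), len(vals))
        for (dis, stratifier, stratum, comp), vals in samples.items()
    ]
    return pd.DataFrame(
        out, columns=["disorder", "stratifier", "stratum", "component", "mc_se", "n_reps"]
    )
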