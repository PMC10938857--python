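"""Follow-up windows, case identification and incidence-density matching.

A case is a person's first qualifying hospital diagnosis of a disorder
(inpatient, outpatient or emergency contact) inside the case window; each
case is matched with up to 10 controls of the same sex, birthdate within
+/- two calendar months, alive and resident on the index date and free of
the index disorder at that date.  Controls are sampled uniformly at random
with per-case seeded substreams, so the matched sets do not depend on input
row order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _dates
from .catalogue import DisorderDefinition, as_mapping, normalise_code
from .config import StudyConfig
from .errors import ConfigError

log = logging.getLogger(__name__)

_FAR_FUTURE = pd.Timestamp("2200-01-01")
_FAR_PAST = pd.Timestamp("1800-01-01")


def followup_windows(civil: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Per-person follow-up interval [start, end), omitting degenerate windows.

    start = max(study start, birth, immigration);
    end   = min(death, 95th birthday, emigration, study end).
    """
    start = pd.Series(pd.Timestamp(config.followup_start), index=civil.index)
    start = np.maximum(start, civil["birth_date"])
    start = np.maximum(start, civil["immigration_date"].fillna(_FAR_PAST))

    end = pd.Series(pd.Timestamp(config.followup_end), index=civil.index)
    end = np.minimum(end, civil["death_date"].fillna(_FAR_FUTURE))
    end = np.minimum(end, civil["emigration_date"].fillna(_FAR_FUTURE))
    end = np.minimum(end, _dates.add_years(civil["birth_date"], config.censor_age))

    out = pd.DataFrame({"person_id": civil["person_id"], "start": start, "end": end})
    degenerate = out["start"] >= out["end"]
    if degenerate.any():
        log.debug("%d person(s) have no follow-up time", int(degenerate.sum()))
    return out[~degenerate].reset_index(drop=True)


def _qualifying_events(
    psychiatric: pd.DataFrame, civil: pd.DataFrame, disorder: DisorderDefinition
) -> pd.DataFrame:
    """Events matching the disorder's code prefixes at or above its onset age."""
    codes = psychiatric["icd10_code"].map(normalise_code)
    mask = np.zeros(len(psychiatric), dtype=bool)
    for prefix in disorder.icd10_codes:
        mask |= codes.str.startswith(normalise_code(prefix)).to_numpy()
    ev = psychiatric[mask]
    if ev.empty:
        return ev
    birth = civil.set_index("person_id")["birth_date"]
    ev_birth = ev["person_id"].map(birth)
    onset_floor = _dates.add_years(ev_birth, disorder.earliest_onset_age)
    return ev[(ev["event_date"].to_numpy() >= onset_floor.to_numpy())]


def first_qualifying_date(
    psychiatric: pd.DataFrame, civil: pd.DataFrame, disorder: DisorderDefinition
) -> pd.Series:
    """Earliest qualifying event date per person (index: person_id)."""
    ev = _qualifying_events(psychiatric, civil, disorder)
    if ev.empty:
        return pd.Series(dtype="datetime64[ns]", name="index_date")
    return ev.groupby("person_id")["event_date"].min().rename("index_date")


def identify_cases(
    psychiatric: pd.DataFrame,
    civil: pd.DataFrame,
    disorder: DisorderDefinition | str,
    config: StudyConfig,
    catalogue=None,
) -> pd.DataFrame:
    """One CaseRecord per person with a first qualifying diagnosis in the case window.

    Events below the disorder's earliest onset age are ignored; the index
    date is the earliest remaining event.  A person whose first qualifying
    event falls outside the case-window years is not a case.
    """
    if isinstance(disorder, str):
        if catalogue is None:
            raise ConfigError("a catalogue is required when the disorder is given by name")
        mapping = as_mapping(catalogue)
        if disorder not in mapping:
            raise ConfigError(f"unknown disorder name {disorder!r}")
        disorder = mapping[disorder]
    first = first_qualifying_date(psychiatric, civil, disorder)
    if not first.empty:
        lo, hi = config.case_window
        first = first[(first.dt.year >= lo) & (first.dt.year <= hi)]
    out = first.reset_index()
    if out.empty:
        out = pd.DataFrame({"person_id": pd.Series(dtype=str),
                            "index_date": pd.Series(dtype="datetime64[ns]")})
    out.insert(1, "disorder", disorder.name)
    return out.sort_values(["index_date", "person_id"], kind="stable").reset_index(drop=True)


def identify_all_cases(psychiatric, civil, catalogue, config) -> pd.DataFrame:
    """Cases for every catalogue disorder; a person may appear once per disorder."""
    parts = [identify_cases(psychiatric, civil, d, config) for d in catalogue]
    out = pd.concat(parts, ignore_index=True)
    return out


@dataclass
class MatchedCohort:
    """Matched sets (one per case) and the long case-control link table."""

    sets: pd.DataFrame      # set_id, disorder, case_id, index_date, n_eligible, n_controls
    controls: pd.DataFrame  # set_id, control_id
    target_controls: int = 10

    @property
    def deficient(self) -> pd.DataFrame:
        return self.sets[self.sets["n_controls"] < self.target_controls]


def case_substream(seed: int, disorder: str, person_id: str) -> np.random.Generator:
    """Deterministic per-case RNG keyed by (seed, disorder, case person id)."""
    return np.random.default_rng(
        [int(seed), zlib.crc32(disorder.encode()), zlib.crc32(str(person_id).encode())]
    )


def match_controls(
    cases: pd.DataFrame,
    civil: pd.DataFrame,
    psychiatric: pd.DataFrame,
    catalogue,
    config: StudyConfig,
) -> MatchedCohort:
    """Attach up to ``controls_per_case`` controls to every case.

    Eligibility at the case's index date: same sex, birthdate within the
    calendar-month tolerance, alive and resident, no qualifying index-disorder
    diagnosis on or before the index date, and not the case itself.  Sets with
    fewer controls than requested are kept and logged as deficient; an empty
    eligible pool yields a 0-control set, not an error.
    """
    mapping = as_mapping(catalogue)
    unknown = set(cases["disorder"]) - set(mapping)
    if unknown:
        raise ConfigError(f"unknown disorder name(s) in cases: {sorted(unknown)}")

    civil_sorted = civil.sort_values(["birth_date", "person_id"], kind="stable")
    ids_all = civil_sorted["person_id"].to_numpy()
    birth_all = civil_sorted["birth_date"].to_numpy().astype("datetime64[ns]")
    imm_all = civil_sorted["immigration_date"].fillna(_FAR_PAST).to_numpy().astype("datetime64[ns]")
    death_all = civil_sorted["death_date"].fillna(_FAR_FUTURE).to_numpy().astype("datetime64[ns]")
    emig_all = civil_sorted["emigration_date"].fillna(_FAR_FUTURE).to_numpy().astype("datetime64[ns]")
    sex_all = civil_sorted["sex"].to_numpy()

    pools = {}
    for sex in ("female", "male"):
        sel = np.flatnonzero(sex_all == sex)
        pools[sex] = {
            "ids": ids_all[sel], "birth": birth_all[sel], "imm": imm_all[sel],
            "death": death_all[sel], "emig": emig_all[sel], "sel": sel,
        }

    disorders = sorted(set(cases["disorder"]))
    fq_by_disorder: dict[str, dict[str, np.ndarray]] = {}
    for name in disorders:
        fq = first_qualifying_date(psychiatric, civil, mapping[name])
        aligned = pd.Series(ids_all).map(fq).to_numpy().astype("datetime64[ns]")
        aligned = np.where(np.isnat(aligned), np.datetime64(_FAR_FUTURE, "ns"), aligned)
        fq_by_disorder[name] = {sex: aligned[pools[sex]["sel"]] for sex in pools}

    sex_by_person = civil.set_index("person_id")["sex"]
    birth_by_person = civil.set_index("person_id")["birth_date"]

    # Calendar-month tolerance bounds for every case at once.
    ordered = cases.sort_values(["disorder", "index_date", "person_id"], kind="stable").reset_index(drop=True)
    case_birth = ordered["person_id"].map(birth_by_person)
    lo_bounds = _dates.add_months(case_birth, -config.birthdate_tolerance_months).to_numpy()
    hi_bounds = _dates.add_months(case_birth, config.birthdate_tolerance_months).to_numpy()

    k = config.controls_per_case
    ever_rule = config.control_history_rule == "ever"
    far_future = np.datetime64(_FAR_FUTURE, "ns")

    set_rows = []
    control_rows = []
    for i in range(len(ordered)):
        name = ordered.at[i, "disorder"]
        pid = ordered.at[i, "person_id"]
        idx_date = np.datetime64(ordered.at[i, "index_date"], "ns")
        sex = sex_by_person[pid]
        pool = pools[sex]
        j0 = np.searchsorted(pool["birth"], lo_bounds[i], side="left")
        j1 = np.searchsorted(pool["birth"], hi_bounds[i], side="right")
        sl = slice(j0, j1)
        fq = fq_by_disorder[name][sex][sl]
        eligible = (
            (pool["imm"][sl] <= idx_date)
            & (pool["death"][sl] > idx_date)
            & (pool["emig"][sl] > idx_date)
            & (pool["birth"][sl] <= idx_date)
            & ((fq == far_future) if ever_rule else (fq > idx_date))
            & (pool["ids"][sl] != pid)
        )
        elig_ids = pool["ids"][sl][eligible]
        n_elig = len(elig_ids)
        if n_elig > k:
            rng = case_substream(config.seed, name, pid)
            chosen = elig_ids[np.sort(rng.choice(n_elig, size=k, replace=False))]
        else:
            chosen = elig_ids
        set_rows.append((i, name, pid, ordered.at[i, "index_date"], n_elig, len(chosen)))
        control_rows.extend((i, c) for c in chosen)

    sets = pd.DataFrame(
        set_rows,
        columns=["set_id", "disorder", "case_id", "index_date", "n_eligible", "n_controls"],
    )
    controls = pd.DataFrame(control_rows, columns=["set_id", "control_id"])
    n_deficient = int((sets["n_controls"] < k).sum())
    if n_deficient:
        log.warning(
            "%d of %d matched sets are deficient (< %d eligible controls)",
            n_deficient, len(sets), k,
        )
    return MatchedCohort(sets=sets, controls=controls, target_controls=k)


def match_single_case(case_row: pd.Series, civil, psychiatric, catalogue, config) -> MatchedCohort:
    """Convenience wrapper matching one case against a candidate pool."""
    return match_controls(pd.DataFrame([case_row]), civil, psychiatric, catalogue, config)
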