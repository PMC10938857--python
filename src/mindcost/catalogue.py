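"""Disorder definitions: ICD-10 code sets and assumed earliest onset ages.

The bundled catalogue covers the 18 hospital-diagnosed mental disorder types
used in Danish register studies (alcohol-use disorder ... conduct disorders)
plus an "any mental disorder" aggregate defined as the union of the 18 code
sets.  The exact code lists and onset ages used on the real registers are a
study-specific choice; the ones shipped here are standard F-chapter prefixes
with plausible onset ages and are explicitly meant to be overridden via a
user catalogue file (YAML) when the real definitions are available.

ICD-10 matching is by code prefix after normalisation (upper-case, dots
stripped), so the prefix ``F32`` matches ``F32.1`` and the Danish dialect's
sub-codes cannot defeat matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import CatalogueError

ANY_MENTAL_DISORDER = "any mental disorder"

DISORDER_NAMES = (
    "alcohol-use disorder",
    "opioid-use disorder",
    "cannabis-use disorder",
    "cocaine-use disorder",
    "amphetamine-use disorder",
    "other drug-use disorders",
    "schizophrenia",
    "bipolar disorder",
    "major depressive disorder",
    "dysthymia",
    "anxiety disorders",
    "anorexia nervosa",
    "bulimia nervosa",
    "personality disorders",
    "intellectual disabilities",
    "autism spectrum disorders",
    "ADHD",
    "conduct disorders",
)


@dataclass(frozen=True)
class DisorderDefinition:
    """One disorder type: a name, ICD-10 code prefixes and an onset floor.

    Diagnoses recorded before the assumed earliest onset age are treated as
    administrative noise and ignored when identifying cases.
    """

    name: str
    icd10_codes: tuple[str, ...]
    earliest_onset_age: int

    def __post_init__(self):
        if not self.icd10_codes:
            raise CatalogueError(f"disorder {self.name!r} has an empty ICD-10 code set")
        if self.earliest_onset_age < 0:
            raise CatalogueError(f"disorder {self.name!r} has a negative onset age")


def normalise_code(code: str) -> str:
    return str(code).strip().upper().replace(".", "")


def code_matches(code: str, prefixes: Iterable[str]) -> bool:
    """True when ``code`` falls under any of the catalogue prefixes."""
    norm = normalise_code(code)
    return any(norm.startswith(normalise_code(p)) for p in prefixes)


# (codes, earliest onset age); placeholder-but-plausible, configurable.
_DEFAULT_SPECS: dict[str, tuple[tuple[str, ...], int]] = {
    "alcohol-use disorder": (("F10",), 10),
    "opioid-use disorder": (("F11",), 10),
    "cannabis-use disorder": (("F12",), 10),
    "cocaine-use disorder": (("F14",), 10),
    "amphetamine-use disorder": (("F15",), 10),
    "other drug-use disorders": (("F13", "F16", "F18", "F19"), 10),
    "schizophrenia": (("F20",), 10),
    "bipolar disorder": (("F30", "F31"), 10),
    "major depressive disorder": (("F32", "F33"), 6),
    "dysthymia": (("F34.1",), 6),
    "anxiety disorders": (("F40", "F41"), 3),
    "anorexia nervosa": (("F50.0", "F50.1"), 5),
    "bulimia nervosa": (("F50.2", "F50.3"), 8),
    "personality disorders": (("F60", "F61"), 15),
    "intellectual disabilities": (("F70", "F71", "F72", "F73", "F78", "F79"), 0),
    "autism spectrum disorders": (("F84",), 0),
    "ADHD": (("F90",), 3),
    "conduct disorders": (("F91",), 2),
}


def any_aggregate(definitions: Sequence[DisorderDefinition]) -> DisorderDefinition:
    """'Any mental disorder' = union of the component code sets, minimum onset age."""
    codes: set[str] = set()
    for d in definitions:
        codes.update(d.icd10_codes)
    onset = min(d.earliest_onset_age for d in definitions)
    return DisorderDefinition(ANY_MENTAL_DISORDER, tuple(sorted(codes)), onset)


def default_catalogue(include_any: bool = True) -> list[DisorderDefinition]:
    """The bundled catalogue: 18 named disorders (+ optional 'any' aggregate)."""
    defs = [
        DisorderDefinition(name, codes, onset)
        for name, (codes, onset) in _DEFAULT_SPECS.items()
    ]
    if include_any:
        defs.append(any_aggregate(defs))
    return defs


def _check(defs: Sequence[DisorderDefinition]) -> list[DisorderDefinition]:
    names = [d.name for d in defs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise CatalogueError(f"duplicate disorder names in catalogue: {sorted(dupes)}")
    return list(defs)


def load_catalogue(path: str | Path) -> list[DisorderDefinition]:
    """Read a catalogue from YAML: a list of {name, icd10_codes, earliest_onset_age}."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise CatalogueError(f"{path}: expected a YAML list of disorder definitions")
    defs = []
    for i, item in enumerate(raw):
        try:
            defs.append(
                DisorderDefinition(
                    name=str(item["name"]),
                    icd10_codes=tuple(str(c) for c in item["icd10_codes"]),
                    earliest_onset_age=int(item["earliest_onset_age"]),
                )
            )
        except KeyError as exc:
            raise CatalogueError(f"{path}: entry {i} is missing key {exc}") from exc
    return _check(defs)


def write_catalogue(defs: Sequence[DisorderDefinition], path: str | Path) -> None:
    payload = [
        {
            "name": d.name,
            "icd10_codes": list(d.icd10_codes),
            "earliest_onset_age": d.earliest_onset_age,
        }
        for d in defs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)


def as_mapping(defs: Sequence[DisorderDefinition]) -> dict[str, DisorderDefinition]:
    return {d.name: d for d in _check(defs)}
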