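"""Core record container and age stratification.

A discharge abstract is reduced to the fields the rule machinery needs:
hospital, patient age, and the set of ICD-10 diagnosis codes (up to 25 per
admission).  Disease patterns are strongly age-dependent, so mining runs
within five age strata; the 5-19 stratum is carried through data handling
but never mined (too few admissions with codeable disease patterns).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

#: Canonical age strata as (label, low, high); high is inclusive,
#: ``None`` means unbounded.  Boundaries are closed on both printed ends.
AGE_GROUPS: tuple[tuple[str, int, Optional[int]], ...] = (
    ("0-4", 0, 4),
    ("5-19", 5, 19),
    ("20-44", 20, 44),
    ("45-64", 45, 64),
    ("65+", 65, None),
)

#: Strata in which rules are mined.
MINED_AGE_GROUPS: tuple[str, ...] = ("0-4", "20-44", "45-64", "65+")

MAX_CODES_PER_RECORD = 25

_BOUNDS = {label: (lo, hi) for label, lo, hi in AGE_GROUPS}


def age_bounds(label: str) -> tuple[int, Optional[int]]:
    try:
        return _BOUNDS[label]
    except KeyError:
        raise ValueError(f"unknown age group: {label!r}") from None


def age_group_of(age: int) -> str:
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    for label, lo, hi in AGE_GROUPS:
        if age >= lo and (hi is None or age <= hi):
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def in_age_group(age: int, label: str) -> bool:
    lo, hi = age_bounds(label)
    return age >= lo and (hi is None or age <= hi)


@dataclass(frozen=True)
class DischargeRecord:
    """One hospital admission: identifier, hospital, age, diagnosis codes.

    Codes are stored in canonical dotted four-character form (``"I21.0"``,
    ``"P07"``); set semantics — a code repeated on the abstract counts once.
    """

    record_id: int
    hospital_id: str
    age: int
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"record {self.record_id}: negative age")
        if not 1 <= len(self.codes) <= MAX_CODES_PER_RECORD:
            raise ValueError(
                f"record {self.record_id}: expected 1-{MAX_CODES_PER_RECORD} "
                f"codes, got {len(self.codes)}"
            )


def records_in_group(records: Iterable[DischargeRecord],
                     label: str) -> list[DischargeRecord]:
    lo, hi = age_bounds(label)
    return [r for r in records
            if r.age >= lo and (hi is None or r.age <= hi)]


def hospital_volumes(records: Iterable[DischargeRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in records:
        counts[r.hospital_id] = counts.get(r.hospital_id, 0) + 1
    return counts
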