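"""Data model, I/O and validation for activity taxonomies and time-use diaries.

A diary day is an ordered list of (activity, minutes) events covering
exactly 24 h at a 5-min resolution.  Activities resolve through an
:class:`ActivityTaxonomy` to a macrodomain, a superdomain, a MET value,
a posture and a sleep flag.  A small stand-in taxonomy (~30 activities,
with placeholder MET values in plausible compendium ranges) ships with
the package; real analyses should supply their own taxonomy file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coda import Composition
from .hierarchy import (
    DAY_MINUTES,
    DAY_TYPES,
    MACRODOMAINS,
    MACRODOMAIN_TO_SUPERDOMAIN,
    POSTURES,
    PROPER_MACRODOMAINS,
    RESOLUTION_MIN,
    SLEEP_SUPERDOMAIN,
    SUPERDOMAINS,
)

__all__ = [
    "ActivityEntry",
    "ActivityTaxonomy",
    "DiaryDay",
    "CovariateRecord",
    "TaxonomyError",
    "parse_taxonomy",
    "bundled_taxonomy",
    "validate_day",
    "aggregate",
    "load_diaries",
    "diaries_to_frame",
    "load_covariates",
    "covariates_to_frame",
]

TAXONOMY_COLUMNS = (
    "activity_code",
    "macrodomain",
    "superdomain",
    "met",
    "posture",
    "is_sleep",
)


class TaxonomyError(ValueError):
    """Schema or hierarchy violation in a taxonomy table."""


@dataclass(frozen=True)
class ActivityEntry:
    macrodomain: str
    superdomain: str
    met: float
    posture: str
    is_sleep: bool


@dataclass(frozen=True)
class ActivityTaxonomy:
    """Mapping from activity codes to the fixed domain hierarchy."""

    entries: Mapping[str, ActivityEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise TaxonomyError("taxonomy has no activities")
        for code, e in self.entries.items():
            if e.superdomain not in SUPERDOMAINS:
                raise TaxonomyError(
                    f"{code}: unknown superdomain {e.superdomain!r}"
                )
            expected = MACRODOMAIN_TO_SUPERDOMAIN.get(e.macrodomain)
            if expected is None:
                raise TaxonomyError(
                    f"{code}: unknown macrodomain {e.macrodomain!r}"
                )
            if expected != e.superdomain:
                raise TaxonomyError(
                    f"{code}: macrodomain {e.macrodomain!r} belongs to "
                    f"superdomain {expected!r}, not {e.superdomain!r}"
                )
            if e.posture not in POSTURES:
                raise TaxonomyError(f"{code}: unknown posture {e.posture!r}")
            if e.met < 0.9:
                raise TaxonomyError(f"{code}: MET {e.met} below resting floor")
            if e.is_sleep and e.superdomain != SLEEP_SUPERDOMAIN:
                raise TaxonomyError(f"{code}: sleep activity outside Sleep")
            if e.is_sleep and e.posture != "sit_lie":
                raise TaxonomyError(f"{code}: sleep must have posture sit_lie")
            if e.superdomain == SLEEP_SUPERDOMAIN and not e.is_sleep:
                raise TaxonomyError(f"{code}: Sleep activity not flagged is_sleep")

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> ActivityEntry:
        try:
            return self.entries[code]
        except KeyError:
            raise KeyError(f"activity code {code!r} not in taxonomy") from None

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def macrodomains(self) -> tuple[str, ...]:
        present = {e.macrodomain for e in self.entries.values()}
        return tuple(m for m in MACRODOMAINS if m in present)

    @property
    def proper_macrodomains(self) -> tuple[str, ...]:
        present = {e.macrodomain for e in self.entries.values()}
        return tuple(m for m in PROPER_MACRODOMAINS if m in present)

    @property
    def superdomains(self) -> tuple[str, ...]:
        present = {e.superdomain for e in self.entries.values()}
        return tuple(s for s in SUPERDOMAINS if s in present)

    def codes_in_superdomain(self, superdomain: str) -> tuple[str, ...]:
        return tuple(
            c for c, e in self.entries.items() if e.superdomain == superdomain
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "activity_code": code,
                "macrodomain": e.macrodomain,
                "superdomain": e.superdomain,
                "met": e.met,
                "posture": e.posture,
                "is_sleep": e.is_sleep,
            }
            for code, e in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=list(TAXONOMY_COLUMNS))


def parse_taxonomy(source) -> ActivityTaxonomy:
    """Read a taxonomy from a CSV path/buffer or a DataFrame.

    The table must carry the columns ``activity_code, macrodomain,
    superdomain, met, posture, is_sleep``; every macrodomain must sit
    under its fixed superdomain.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise TaxonomyError(f"taxonomy table missing columns: {missing}")
    if df.empty:
        raise TaxonomyError("taxonomy table is empty")
    if df["activity_code"].duplicated().any():
        dupes = df.loc[df["activity_code"].duplicated(), "activity_code"]
        raise TaxonomyError(f"duplicate activity codes: {sorted(set(dupes))}")
    is_sleep = df["is_sleep"]
    if is_sleep.dtype == object:
        is_sleep = is_sleep.astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if is_sleep.isna().any():
            raise TaxonomyError("is_sleep must be boolean")
    entries = {
        str(row.activity_code): ActivityEntry(
            macrodomain=str(row.macrodomain),
            superdomain=str(row.superdomain),
            met=float(row.met),
            posture=str(row.posture),
            is_sleep=bool(sleep),
        )
        for row, sleep in zip(df.itertuples(index=False), is_sleep)
    }
    return ActivityTaxonomy(entries)


def bundled_taxonomy() -> ActivityTaxonomy:
    """The stand-in taxonomy shipped with the package.

    MET values are placeholders in plausible compendium ranges, not
    published compendium entries; replace the taxonomy file for any
    substantive energy analysis.
    """
    ref = importlib.resources.files("termtide.data").joinpath("taxonomy.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return parse_taxonomy(fh)


# ---------------------------------------------------------------------------
# diaries


@dataclass(frozen=True)
class DiaryDay:
    """One recalled 24-h day: ordered (activity_code, minutes) events."""

    child_id: str
    day_type: str
    events: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "events",
            tuple((str(c), float(d)) for c, d in self.events),
        )

    @property
    def total_minutes(self) -> float:
        return float(sum(d for _, d in self.events))


@dataclass(frozen=True)
class CovariateRecord:
    """Per-child covariates; ``parent_education`` and ``irsd`` may be missing."""

    child_id: str
    sex: str
    age: float
    weight: float
    zbmi_category: str
    parent_education: str | None = None
    irsd: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if not (5.0 <= self.age <= 18.0):
            raise ValueError(f"age {self.age} outside [5, 18]")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.zbmi_category not in ("normal_or_under", "overweight", "obese"):
            raise ValueError(f"unknown zBMI category {self.zbmi_category!r}")
        if self.parent_education is not None and self.parent_education not in (
            "university",
            "post_secondary",
            "high_school",
        ):
            raise ValueError(f"unknown education {self.parent_education!r}")


def validate_day(
    day: DiaryDay, tax: ActivityTaxonomy, strict: bool = True
) -> list[str]:
    """Return a list of invariant violations (empty iff the day is valid).

    With ``strict=True`` event durations must be multiples of 5 min and
    at least 5 min (the diary resolution); ``strict=False`` relaxes the
    grid to whole minutes for synthetic stress tests.
    """
    violations: list[str] = []
    if day.day_type not in DAY_TYPES:
        violations.append(f"unknown day_type {day.day_type!r}")
    if not day.events:
        violations.append("day has no events")
    total = day.total_minutes
    if not np.isclose(total, DAY_MINUTES, atol=1e-9):
        violations.append(f"total {total:g} != {DAY_MINUTES:g} min")
    resolution = RESOLUTION_MIN if strict else 1
    for code, dur in day.events:
        if code not in tax:
            violations.append(f"unresolved activity {code!r}")
        if dur < resolution:
            violations.append(f"event {code!r} shorter than {resolution} min")
        elif dur % resolution:
            violations.append(
                f"event {code!r} duration {dur:g} not a multiple of {resolution} min"
            )
    return violations


def aggregate(
    day: DiaryDay,
    tax: ActivityTaxonomy,
    level: str = "superdomain",
    strict: bool = True,
) -> Composition:
    """Sum a valid day's event minutes per domain at the requested level.

    Returns an 8-part (superdomain) or 16-part (macrodomain-level,
    including the three undivided superdomains) composition in fixed
    order; domains without events get 0 minutes.
    """
    problems = validate_day(day, tax, strict=strict)
    if problems:
        raise ValueError(f"invalid day {day.child_id}/{day.day_type}: {problems}")
    if level == "superdomain":
        parts = SUPERDOMAINS
        key = lambda e: e.superdomain
    elif level == "macrodomain":
        parts = MACRODOMAINS
        key = lambda e: e.macrodomain
    else:
        raise ValueError("level must be 'superdomain' or 'macrodomain'")
    minutes = dict.fromkeys(parts, 0.0)
    for code, dur in day.events:
        minutes[key(tax[code])] += dur
    return Composition(parts, np.array([minutes[p] for p in parts]), DAY_MINUTES)


# ---------------------------------------------------------------------------
# tabular I/O (long-format CSV)

DIARY_COLUMNS = ("child_id", "day_type", "activity_code", "duration_min")


def load_diaries(source) -> list[DiaryDay]:
    """Read long-format diaries (CSV path/buffer or DataFrame).

    Expected columns: ``child_id, day_type, activity_code, duration_min``;
    events for one child-day must be contiguous rows (their order is kept).
    """
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in DIARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"diary table missing columns: {missing}")
    days: list[DiaryDay] = []
    # duplicate days of one type are delimited by a day_index column when
    # present; without it all rows of a (child, type) pair form one day
    if "day_index" in df.columns:
        group_cols = ["child_id", "day_type", "day_index"]
    else:
        group_cols = ["child_id", "day_type"]
    for keys, g in df.groupby(group_cols, sort=False):
        child_id, day_type = str(keys[0]), str(keys[1])
        events = tuple(
            (str(r.activity_code), float(r.duration_min))
            for r in g.itertuples(index=False)
        )
        days.append(DiaryDay(child_id, day_type, events))
    return days


def diaries_to_frame(days: Iterable[DiaryDay]) -> pd.DataFrame:
    """Long-format frame for a list of days (adds ``day_index`` to keep
    duplicate days of one type distinct on round-trip)."""
    rows = []
    counter: dict[tuple[str, str], int] = {}
    for day in days:
        idx = counter.get((day.child_id, day.day_type), 0)
        counter[(day.child_id, day.day_type)] = idx + 1
        for code, dur in day.events:
            rows.append(
                {
                    "child_id": day.child_id,
                    "day_type": day.day_type,
                    "day_index": idx,
                    "activity_code": code,
                    "duration_min": dur,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["child_id", "day_type", "day_index", "activity_code", "duration_min"],
    )


COVARIATE_COLUMNS = (
    "child_id",
    "sex",
    "age",
    "weight",
    "zbmi_category",
    "parent_education",
    "irsd",
)


def load_covariates(source) -> list[CovariateRecord]:
    """Read per-child covariates (CSV path/buffer or DataFrame)."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    records = []
    for r in df.itertuples(index=False):
        education = None if pd.isna(r.parent_education) else str(r.parent_education)
        irsd = None if pd.isna(r.irsd) else float(r.irsd)
        records.append(
            CovariateRecord(
                child_id=str(r.child_id),
                sex=str(r.sex),
                age=float(r.age),
                weight=float(r.weight),
                zbmi_category=str(r.zbmi_category),
                parent_education=education,
                irsd=irsd,
            )
        )
    return records


def covariates_to_frame(records: Iterable[CovariateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "child_id": r.child_id,
                "sex": r.sex,
                "age": r.age,
                "weight": r.weight,
                "zbmi_category": r.zbmi_category,
                "parent_education": r.parent_education,
                "irsd": r.irsd,
            }
            for r in records
        ],
        columns=list(COVARIATE_COLUMNS),
    )
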