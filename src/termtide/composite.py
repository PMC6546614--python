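"""Composite-day construction: one in-term and one holiday profile per child.

Each child contributes one school day, one in-term weekend day and one
holiday day (a uniform random pick when several days of a type were
recalled).  The in-term composite is the 5:2 weekday:weekend weighted
average of the school and weekend compositions in raw minutes; the
holiday profile is the selected holiday day unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coda import Composition
from .diary import ActivityTaxonomy, DiaryDay, aggregate
from .hierarchy import DAY_TYPES, SUPERDOMAINS

__all__ = [
    "PairedProfile",
    "EligibilityError",
    "select_analysis_days",
    "interm_composite",
    "build_profiles",
    "profiles_to_frame",
    "profiles_from_frame",
]

DEFAULT_WEIGHTS = (5.0, 2.0)


class EligibilityError(ValueError):
    """Raised when a child lacks a required day type."""


@dataclass(frozen=True)
class PairedProfile:
    """Per child: the in-term composite and the holiday composition."""

    child_id: str
    interm: Composition
    holiday: Composition

    def __post_init__(self) -> None:
        if self.interm.parts != self.holiday.parts:
            raise ValueError("profile compositions must share part order")
        if self.interm.total != self.holiday.total:
            raise ValueError("profile compositions must share closure constant")


def select_analysis_days(
    days: Sequence[DiaryDay], seed: int
) -> dict[str, DiaryDay]:
    """Pick exactly one day per type for one child.

    When a child recalled several days of one type, one is chosen
    uniformly at random, reproducibly under ``seed``.
    """
    if not days:
        raise EligibilityError("no days supplied")
    child_ids = {d.child_id for d in days}
    if len(child_ids) != 1:
        raise ValueError(f"days from several children: {sorted(child_ids)}")
    by_type: dict[str, list[DiaryDay]] = {t: [] for t in DAY_TYPES}
    for d in days:
        if d.day_type not in by_type:
            raise ValueError(f"unknown day_type {d.day_type!r}")
        by_type[d.day_type].append(d)
    missing = [t for t, ds in by_type.items() if not ds]
    if missing:
        raise EligibilityError(f"no {'/'.join(missing)} day")
    rng = np.random.default_rng(seed)
    # one draw per type, in fixed type order, so the selection for one
    # type does not depend on how many duplicates another type has
    return {
        t: by_type[t][int(rng.integers(len(by_type[t])))] for t in DAY_TYPES
    }


def interm_composite(
    school: Composition,
    weekend: Composition,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
) -> Composition:
    """Weighted raw-minute average of school and weekend compositions.

    With the default 5:2 weights each part is (5*school + 2*weekend)/7;
    the result is a convex combination, so closure is preserved.
    """
    if school.parts != weekend.parts:
        raise ValueError("compositions must share part order")
    if school.total != weekend.total:
        raise ValueError("compositions must share closure constant")
    w_school, w_weekend = float(weights[0]), float(weights[1])
    if w_school < 0 or w_weekend < 0 or w_school + w_weekend <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    total_w = w_school + w_weekend
    values = (w_school * school.values + w_weekend * weekend.values) / total_w
    return Composition(school.parts, values, school.total)


def build_profiles(
    days: Iterable[DiaryDay],
    tax: ActivityTaxonomy,
    seed: int = 0,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    strict: bool = True,
) -> tuple[list[PairedProfile], pd.DataFrame]:
    """Build one :class:`PairedProfile` per eligible child.

    Children missing a day type are excluded, not imputed; the second
    return value reports every excluded child with the reason.  Selection
    among duplicate days is reproducible: each child uses a substream
    derived from ``seed`` and its position in sorted child order.
    """
    by_child: dict[str, list[DiaryDay]] = {}
    for d in days:
        by_child.setdefault(d.child_id, []).append(d)
    profiles: list[PairedProfile] = []
    excluded: list[dict[str, str]] = []
    for idx, child_id in enumerate(sorted(by_child)):
        child_seed = np.random.SeedSequence([seed, idx]).generate_state(1)[0]
        try:
            chosen = select_analysis_days(by_child[child_id], int(child_seed))
        except EligibilityError as err:
            excluded.append({"child_id": child_id, "reason": str(err)})
            continue
        school = aggregate(chosen["school"], tax, "superdomain", strict=strict)
        weekend = aggregate(
            chosen["weekend_in_term"], tax, "superdomain", strict=strict
        )
        holiday = aggregate(chosen["holiday"], tax, "superdomain", strict=strict)
        profiles.append(
            PairedProfile(
                child_id=child_id,
                interm=interm_composite(school, weekend, weights),
                holiday=holiday,
            )
        )
    report = pd.DataFrame(excluded, columns=["child_id", "reason"])
    return profiles, report


def profiles_to_frame(profiles: Iterable[PairedProfile]) -> pd.DataFrame:
    """Long-by-period frame: child_id, period, then one column per part."""
    rows = []
    for p in profiles:
        rows.append(
            {"child_id": p.child_id, "period": "interm", **dict(zip(p.interm.parts, p.interm.values))}
        )
        rows.append(
            {"child_id": p.child_id, "period": "holiday", **dict(zip(p.holiday.parts, p.holiday.values))}
        )
    return pd.DataFrame(
        rows, columns=["child_id", "period", *SUPERDOMAINS]
    )


def profiles_from_frame(df: pd.DataFrame) -> list[PairedProfile]:
    """Inverse of :func:`profiles_to_frame`."""
    parts = tuple(c for c in df.columns if c not in ("child_id", "period"))
    profiles = []
    for child_id, g in df.groupby("child_id", sort=False):
        if sorted(g["period"]) != ["holiday", "interm"]:
            raise ValueError(f"child {child_id}: need one interm and one holiday row")
        comps = {
            period: Composition(
                parts,
                g.loc[g["period"] == period, list(parts)].iloc[0].to_numpy(dtype=float),
            )
            for period in ("interm", "holiday")
        }
        profiles.append(
            PairedProfile(str(child_id), comps["interm"], comps["holiday"])
        )
    return profiles
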