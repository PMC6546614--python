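"""Factorial energy expenditure and the holiday energy-balance projection.

TDEE (MET·min/day) is the sum over diary events of duration × MET; PAL
is TDEE expressed as average METs over 24 h (TDEE/1440).  Intensity
bands follow the usual cut-points — sedentary time requires ≤1.5 METs
while awake and sitting or lying; light is below 3 METs (including
awake standing/ambulatory time at ≤1.5 METs, which the posture clause
excludes from sedentary); moderate is 3–5.9; vigorous is ≥6.  Basal
metabolic rate comes from the Schofield weight-based equations, whose
coefficients are shipped as a replaceable data table.

The fat-gain projection converts a percentage TDEE decrement into a
daily energy deficit (pct/100 × BMR × PAL, rounded to the nearest
10 kJ), accumulates it over the holiday period and divides by the
energy density of body fat (default 37 kJ/g).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .diary import ActivityTaxonomy, DiaryDay, validate_day
from .hierarchy import DAY_MINUTES

__all__ = [
    "EnergyProfile",
    "EnergyProjection",
    "tdee",
    "pal",
    "band_minutes",
    "schofield_bmr",
    "fat_projection",
    "energy_table",
]

BANDS = ("SED", "LPA", "MPA", "VPA")

#: Energy density of adipose tissue, kJ per gram.
FAT_ENERGY_DENSITY_KJ_G = 37.0


@dataclass(frozen=True)
class EnergyProfile:
    """Per day: factorial TDEE, PAL and intensity-band minutes."""

    tdee_met_min: float
    pal: float
    band_minutes: dict[str, float]


@dataclass(frozen=True)
class EnergyProjection:
    """Holiday energy-deficit arithmetic, before/after reporting rounding."""

    bmr_kj: float
    pal: float
    pct_decrement: float
    deficit_kj_day: float
    period_days: float
    period_kj: float
    fat_g: float
    fat_energy_density: float


def _check_valid(day: DiaryDay, tax: ActivityTaxonomy, strict: bool) -> None:
    problems = validate_day(day, tax, strict=strict)
    if problems:
        raise ValueError(f"invalid day {day.child_id}/{day.day_type}: {problems}")


def tdee(day: DiaryDay, tax: ActivityTaxonomy, strict: bool = True) -> float:
    """Total daily energy expenditure in MET·min: Σ duration × MET."""
    _check_valid(day, tax, strict)
    return float(sum(dur * tax[code].met for code, dur in day.events))


def pal(tdee_met_min: float, ndigits: int | None = 2) -> float:
    """Physical activity level: TDEE averaged over 1440 min (in METs)."""
    if tdee_met_min < 0:
        raise ValueError("TDEE must be non-negative")
    value = tdee_met_min / DAY_MINUTES
    return round(value, ndigits) if ndigits is not None else value


def band_minutes(
    day: DiaryDay, tax: ActivityTaxonomy, strict: bool = True
) -> dict[str, float]:
    """Minutes of awake time per intensity band.

    SED: MET ≤ 1.5 while sitting/lying; LPA: any other awake activity
    below 3 METs; MPA: [3, 6); VPA: ≥ 6.  Sleep falls in no band, so
    bands partition awake time.
    """
    _check_valid(day, tax, strict)
    out = dict.fromkeys(BANDS, 0.0)
    for code, dur in day.events:
        e = tax[code]
        if e.is_sleep:
            continue
        if e.met >= 6.0:
            out["VPA"] += dur
        elif e.met >= 3.0:
            out["MPA"] += dur
        elif e.met <= 1.5 and e.posture == "sit_lie":
            out["SED"] += dur
        else:
            out["LPA"] += dur
    return out


def energy_profile(
    day: DiaryDay, tax: ActivityTaxonomy, strict: bool = True
) -> EnergyProfile:
    t = tdee(day, tax, strict=strict)
    return EnergyProfile(t, pal(t), band_minutes(day, tax, strict=strict))


def energy_table(
    days: Iterable[DiaryDay], tax: ActivityTaxonomy, strict: bool = True
) -> pd.DataFrame:
    """Per child-day energy summary: tdee_met_min, pal, SED/LPA/MPA/VPA."""
    rows = []
    for day in days:
        prof = energy_profile(day, tax, strict=strict)
        rows.append(
            {
                "child_id": day.child_id,
                "day_type": day.day_type,
                "tdee_met_min": prof.tdee_met_min,
                "pal": prof.pal,
                **{b.lower(): prof.band_minutes[b] for b in BANDS},
            }
        )
    return pd.DataFrame(
        rows,
        columns=["child_id", "day_type", "tdee_met_min", "pal", "sed", "lpa", "mpa", "vpa"],
    )


# ---------------------------------------------------------------------------
# Schofield BMR


def _load_schofield(source=None) -> pd.DataFrame:
    if source is None:
        ref = importlib.resources.files("termtide.data").joinpath("schofield.csv")
        with ref.open("r", encoding="utf-8") as fh:
            return pd.read_csv(fh)
    if isinstance(source, pd.DataFrame):
        return source
    return pd.read_csv(source)


def schofield_bmr(
    sex: str, age_years: float, weight_kg: float, coefficients=None
) -> float:
    """Basal metabolic rate in kJ/day from the Schofield weight equations.

    Coefficients (MJ/day per kg and MJ/day intercept, by sex and age
    band) are data, not code; pass a frame or CSV with columns
    ``sex, age_min, age_max, slope_mj_per_kg, intercept_mj`` to replace
    the published defaults (3–10 y and 10–18 y bands).
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    table = _load_schofield(coefficients)
    rows = table[
        (table["sex"] == sex)
        & (table["age_min"] <= age_years)
        & (age_years < table["age_max"])
    ]
    if rows.empty:
        # allow the upper edge of the oldest band (age exactly 18)
        rows = table[(table["sex"] == sex) & (table["age_max"] == age_years)]
    if rows.empty:
        raise ValueError(f"no Schofield age band covers age {age_years}")
    row = rows.iloc[0]
    mj = row["slope_mj_per_kg"] * weight_kg + row["intercept_mj"]
    return float(mj * 1000.0)


# ---------------------------------------------------------------------------
# fat projection


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def fat_projection(
    bmr_kj: float,
    pal: float,
    pct_decrement: float,
    period_days: float = 42.0,
    fat_energy_density: float = FAT_ENERGY_DENSITY_KJ_G,
) -> EnergyProjection:
    """Project fat gain from an uncompensated holiday TDEE decrement.

    The daily deficit is pct/100 × BMR × PAL, rounded to the nearest
    10 kJ before multiplying by the period length (so the period total is
    an exact multiple of the reported daily figure); the fat mass is the
    period total divided by the energy density of fat, reported to two
    significant figures.
    """
    if bmr_kj <= 0 or pal <= 0 or period_days <= 0 or fat_energy_density <= 0:
        raise ValueError("all projection inputs must be positive")
    if not (0.0 < pct_decrement < 100.0):
        raise ValueError("pct_decrement must lie in (0, 100)")
    deficit = round((pct_decrement / 100.0) * bmr_kj * pal / 10.0) * 10.0
    period_kj = deficit * period_days
    fat_g = _round_sig(period_kj / fat_energy_density, 2)
    return EnergyProjection(
        bmr_kj=bmr_kj,
        pal=pal,
        pct_decrement=pct_decrement,
        deficit_kj_day=deficit,
        period_days=period_days,
        period_kj=period_kj,
        fat_g=fat_g,
        fat_energy_density=fat_energy_density,
    )
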