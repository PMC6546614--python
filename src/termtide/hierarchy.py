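"""Fixed activity hierarchy for 24-h use-of-time diaries.

Activities roll up into macrodomains, which roll up into eight
superdomains.  Three superdomains (Passive Transport, Quiet Time, Sleep)
are not subdivided; at the macrodomain level they appear under their own
name, so macrodomain aggregation always rolls up exactly to the
superdomain aggregation.
"""

from __future__ import annotations

# Fixed reporting order for the eight superdomains (used for compositions).
SUPERDOMAINS: tuple[str, ...] = (
    "Domestic/Social",
    "Passive Transport",
    "Physical Activity",
    "Quiet Time",
    "School-related",
    "Screen Time",
    "Self-care",
    "Sleep",
)

# macrodomain -> superdomain; the three undivided superdomains map to
# themselves.  13 proper macrodomains + 3 pass-through entries.
MACRODOMAIN_TO_SUPERDOMAIN: dict[str, str] = {
    "Social": "Domestic/Social",
    "Chores/Work": "Domestic/Social",
    "Passive Transport": "Passive Transport",
    "Sport": "Physical Activity",
    "Play": "Physical Activity",
    "Active Transport": "Physical Activity",
    "Quiet Time": "Quiet Time",
    "Classroom": "School-related",
    "Study/Homework/Music": "School-related",
    "Reading": "School-related",
    "TV": "Screen Time",
    "Computer": "Screen Time",
    "Videogames": "Screen Time",
    "Eating": "Self-care",
    "Grooming": "Self-care",
    "Sleep": "Sleep",
}

# Macrodomain reporting order (groups follow the superdomain order).
MACRODOMAINS: tuple[str, ...] = tuple(MACRODOMAIN_TO_SUPERDOMAIN)

#: Macrodomains that are proper subdivisions of a superdomain (there are 13).
PROPER_MACRODOMAINS: tuple[str, ...] = tuple(
    m for m, s in MACRODOMAIN_TO_SUPERDOMAIN.items() if m != s
)

#: The superdomain whose activities are asleep rather than awake.
SLEEP_SUPERDOMAIN = "Sleep"

POSTURES: tuple[str, ...] = ("sit_lie", "stand", "ambulatory")

DAY_TYPES: tuple[str, ...] = ("school", "weekend_in_term", "holiday")

#: Closure constant for daily compositions, in minutes.
DAY_MINUTES = 1440.0

#: Diary time resolution in minutes.
RESOLUTION_MIN = 5
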