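"""The holiday energy-balance worked example.

Chains the published period TDEE means through PAL, the percentage TDEE
decrement and the fat-gain projection for a six-week holiday.
"""

from termtide import fat_projection, pal, pct_decrement, schofield_bmr

interm_tdee, holiday_tdee = 2405.0, 2282.0  # MET·min/day
pal_value = pal(interm_tdee)
pct = pct_decrement(interm_tdee, holiday_tdee)
bmr = 6334.0  # kJ/day, Schofield prediction for this cohort
print(f"PAL (in-term) = {pal_value} METs, TDEE decrement = {pct}%")
print(f"Schofield check, 13.4 y / 50 kg male: {schofield_bmr('male', 13.4, 50):.0f} kJ/day")

proj = fat_projection(bmr, pal_value, pct, period_days=42, fat_energy_density=37)
print(
    f"Daily deficit {proj.deficit_kj_day:.0f} kJ -> {proj.period_kj:,.0f} kJ "
    f"over {proj.period_days:.0f} days -> {proj.fat_g:.0f} g body fat"
)
print(
    "\nIf the lower holiday expenditure is not matched by lower intake, the "
    "uncompensated surplus corresponds to roughly this much stored fat."
)
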