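"""Test the period effect and its moderation by covariates.

Builds per-child ilr-coordinate differences (holiday minus in-term),
runs the paired Hotelling T² for the overall period effect, and a Wilks
MANOVA for moderation by parental education and IRSD tertiles (imputing
the few missing IRSD values by predictive mean matching first).
"""

import numpy as np
import pandas as pd

from termtide import (
    build_profiles,
    bundled_taxonomy,
    irsd_tertiles,
    moderation_test,
    paired_differences,
    pmm_impute,
    time_effect_test,
)
from termtide.diary import covariates_to_frame
from termtide.simulate import default_config, generate_population

pop = generate_population(default_config(n_children=366, seed=29))
profiles, _ = build_profiles(pop.diaries, bundled_taxonomy(), seed=29)
Dm = paired_differences(profiles)

res = time_effect_test(Dm)
print(f"Period effect: T2 = {res.statistic:.1f}, F({res.df1:.0f}, {res.df2:.0f}) = "
      f"{res.F:.1f}, p = {res.p:.2e}")

cov = covariates_to_frame(pop.covariates).set_index("child_id")
cov = cov.loc[Dm.index]
edu = moderation_test(Dm, cov["parent_education"])
print(f"Education moderation: Wilks = {edu.statistic:.3f}, F = {edu.F:.2f}, p = {edu.p:.2f}")

irsd = cov["irsd"].to_numpy(dtype=float)
predictors = np.column_stack(
    [pd.Categorical(cov["parent_education"]).codes, pd.Categorical(cov["zbmi_category"]).codes]
).astype(float)
irsd = pmm_impute(irsd, predictors, k_donors=5, seed=29)
ses = moderation_test(Dm, irsd_tertiles(irsd))
print(f"IRSD-tertile moderation: Wilks = {ses.statistic:.3f}, F = {ses.F:.2f}, p = {ses.p:.2f}")
print(
    "\nA large, significant period effect with non-significant moderation "
    "reflects the generating model: the holiday shift is common to all groups."
)
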