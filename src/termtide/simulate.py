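"""Synthetic diary populations with the structure the analysis assumes.

Children are simulated on the logistic-normal model the inference
machinery presumes: each child has a latent between-child effect in ilr
space, each recalled day adds within-child noise around a day-type
centre, and the resulting composition is apportioned onto the 5-min
diary grid and split into taxonomy activities.  Day-type centres default
to the published school-term/holiday mean time-use pattern; the school
and in-term weekend centres are chosen so their 5:2 blend reproduces the
in-term composite means exactly.

Configured centres are arithmetic-mean targets: the generator applies a
deterministic fixed-point correction in ilr space so the population
arithmetic mean of each day type matches its configured centre (a raw
logistic-normal centre would undershoot small, dispersed parts).  A
configurable fraction of holiday days drops School-related time
entirely, producing the structural zeros that exercise zero
replacement.

The module also hosts the simulation harnesses used to validate the
pipeline: parameter recovery, type-I-error calibration, moderation-null
calibration and a power curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .coda import closure, ilr, ilr_inv, multiplicative_replacement, pivot_basis
from .composite import build_profiles, profiles_to_frame
from .coda import difference_table
from .diary import ActivityTaxonomy, CovariateRecord, DiaryDay, bundled_taxonomy
from .hierarchy import DAY_MINUTES, DAY_TYPES, RESOLUTION_MIN, SUPERDOMAINS
from .inference import moderation_test, time_effect_test

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "SimulatedPopulation",
    "default_config",
    "null_config",
    "generate_population",
    "round_to_grid",
    "recovery_experiment",
    "null_rejection_experiment",
    "moderation_null_experiment",
    "power_curve",
]

D = len(SUPERDOMAINS)
_SCHOOL_IDX = SUPERDOMAINS.index("School-related")

# Published mean (SD) min/day per superdomain, in fixed part order:
# Domestic/Social, Passive Transport, Physical Activity, Quiet Time,
# School-related, Screen Time, Self-care, Sleep.
INTERM_MEANS = np.array([75.0, 52.0, 143.0, 77.0, 216.0, 201.0, 99.0, 576.0])
HOLIDAY_MEANS = np.array([110.0, 64.0, 136.0, 80.0, 76.0, 259.0, 99.0, 616.0])
HOLIDAY_SDS = np.array([131.0, 85.0, 127.0, 86.0, 109.0, 174.0, 39.0, 108.0])

# A plausible in-term weekend day (design choice, min/day, sums to 1440);
# the school centre is derived so that (5*school + 2*weekend)/7 equals the
# closed in-term composite means.
WEEKEND_CENTRE = np.array([110.0, 64.0, 170.0, 85.0, 40.0, 270.0, 99.0, 602.0])

#: Fraction of children reporting any School-related time on holidays (78/366).
HOLIDAY_SCHOOL_PROB = 78.0 / 366.0


def _default_centres() -> dict[str, np.ndarray]:
    interm = closure(INTERM_MEANS, DAY_MINUTES)
    weekend = closure(WEEKEND_CENTRE, DAY_MINUTES)
    school = (7.0 * interm - 2.0 * weekend) / 5.0
    if np.any(school <= 0):
        raise ValueError("derived school centre has non-positive parts")
    return {
        "school": school,
        "weekend_in_term": weekend,
        "holiday": closure(HOLIDAY_MEANS, DAY_MINUTES),
    }


def _default_sds() -> tuple[np.ndarray, np.ndarray]:
    """ilr-space SD vectors calibrated to the printed holiday dispersion.

    Per-part log-scale SDs are derived from the printed holiday
    mean/SD ratios (log-normal moment matching); a diagonal ilr
    covariance under the pivot basis is then fitted by non-negative
    least squares so the implied per-part log variances roughly match.
    The total is split evenly between between-child and within-child
    variance (the source data publish no decomposition).
    """
    cv = HOLIDAY_SDS / HOLIDAY_MEANS
    lam2 = np.log1p(cv**2)  # per-part log variance targets
    V = pivot_basis(D).V
    A = V**2  # diag ilr cov -> per-part clr variance
    # floor each coordinate variance at 0.02 so every log-contrast varies
    # (a degenerate coordinate would make the difference covariance singular)
    d = optimize.lsq_linear(A, lam2, bounds=(0.02, np.inf)).x
    between = np.sqrt(d / 2.0)
    within = np.sqrt(d / 2.0)
    return between, within


@dataclass(frozen=True)
class CovariateSpec:
    """Distributional spec for the per-child covariate table."""

    female_prob: float = 0.53
    age_range: tuple[float, float] = (9.0, 16.0)
    # weight ~ intercept + slope*age + N(0, sd), floored at 25 kg
    weight_intercept: float = 2.0
    weight_slope: float = 3.6
    weight_sd: float = 8.0
    zbmi_probs: tuple[float, float, float] = (259 / 363, 76 / 363, 28 / 363)
    education_probs: tuple[float, float, float] = (162 / 363, 140 / 363, 61 / 363)
    irsd_mean: float = 1003.0
    irsd_sd: float = 68.0
    n_missing_irsd: int = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw a diary population reproducibly."""

    n_children: int = 366
    seed: int = 0
    day_type_centres: dict[str, np.ndarray] = field(default_factory=_default_centres)
    between_child_sd: np.ndarray = field(default_factory=lambda: _default_sds()[0])
    within_child_sd: np.ndarray = field(default_factory=lambda: _default_sds()[1])
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    duplicate_day_prob: float = 0.25
    # probability that a holiday day contains NO School-related time
    holiday_school_dropout: float = 1.0 - HOLIDAY_SCHOOL_PROB
    # mean number of extra activities per superdomain when splitting events
    event_rate: float = 0.7

    def validate(self) -> None:
        if self.n_children < 2:
            raise ValueError("need at least two children")
        if set(self.day_type_centres) != set(DAY_TYPES):
            raise ValueError(f"centres must cover day types {DAY_TYPES}")
        for t, c in self.day_type_centres.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (D,) or np.any(c <= 0):
                raise ValueError(f"{t}: centre must be {D} strictly positive parts")
            if not np.isclose(c.sum(), DAY_MINUTES, atol=1e-6):
                raise ValueError(f"{t}: centre must be closed to {DAY_MINUTES}")
        for name, sd in (
            ("between_child_sd", self.between_child_sd),
            ("within_child_sd", self.within_child_sd),
        ):
            sd = np.asarray(sd, dtype=float)
            if sd.shape != (D - 1,) or np.any(sd < 0):
                raise ValueError(f"{name} must be {D - 1} non-negative values")
        cov = self.covariates
        for name, probs in (
            ("zbmi_probs", cov.zbmi_probs),
            ("education_probs", cov.education_probs),
        ):
            if not np.isclose(sum(probs), 1.0, atol=1e-9):
                raise ValueError(f"{name} must sum to 1")
        if not 0.0 <= self.duplicate_day_prob <= 1.0:
            raise ValueError("duplicate_day_prob must be a probability")
        if not 0.0 <= self.holiday_school_dropout < 1.0:
            raise ValueError("holiday_school_dropout must lie in [0, 1)")


@dataclass(frozen=True)
class SimulatedPopulation:
    diaries: list[DiaryDay]
    covariates: list[CovariateRecord]
    truth: dict


def default_config(n_children: int = 366, seed: int = 0, **kwargs) -> SimulationConfig:
    """The study-emulating defaults (published centres, calibrated noise)."""
    cfg = SimulationConfig(n_children=n_children, seed=seed, **kwargs)
    cfg.validate()
    return cfg


def null_config(n_children: int = 100, seed: int = 0, **kwargs) -> SimulationConfig:
    """A no-period-effect configuration: identical centres for every day
    type (the common centre is the closed in-term pattern) and no
    holiday-specific dropout, so the three day types are exchangeable."""
    centre = closure(INTERM_MEANS, DAY_MINUTES)
    cfg = SimulationConfig(
        n_children=n_children,
        seed=seed,
        day_type_centres={t: centre.copy() for t in DAY_TYPES},
        holiday_school_dropout=0.0,
        **kwargs,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# grid rounding


def round_to_grid(x: np.ndarray, grid: float = float(RESOLUTION_MIN)) -> np.ndarray:
    """Largest-remainder apportionment of rows onto a minute grid.

    Each row must sum to a multiple of ``grid`` (1440 here); the result
    is non-negative multiples of ``grid`` with the row total preserved
    exactly, and no entry moves by more than ``grid``.
    """
    x = np.asarray(x, dtype=float)
    was_1d = x.ndim == 1
    x = np.atleast_2d(x)
    units = x / grid
    total_units = np.rint(units.sum(axis=1)).astype(int)
    if not np.allclose(units.sum(axis=1), total_units, atol=1e-6):
        raise ValueError("row totals must be multiples of the grid")
    base = np.floor(units).astype(int)
    short = total_units - base.sum(axis=1)
    rem = units - base
    # give one extra unit to the `short` largest remainders per row
    order = np.argsort(-rem, axis=1, kind="stable")
    bump = np.zeros_like(base)
    cols = np.arange(x.shape[1])[None, :] < short[:, None]
    np.put_along_axis(bump, order, cols.astype(int), axis=1)
    out = (base + bump) * grid
    return out[0] if was_1d else out


# ---------------------------------------------------------------------------
# mean-corrected ilr centres


def _drop_school(comps: np.ndarray) -> np.ndarray:
    out = comps.copy()
    out[..., _SCHOOL_IDX] = 0.0
    return closure(out, DAY_MINUTES)


_CENTRE_CACHE: dict[tuple, dict[str, np.ndarray]] = {}


def _corrected_ilr_centres(
    cfg: SimulationConfig, n_draws: int = 131072, n_iter: int = 40
) -> dict[str, np.ndarray]:
    """Find ilr centres whose simulated arithmetic means hit the targets.

    Uses a fixed internal stream (independent of ``cfg.seed``) and common
    random numbers across fixed-point iterations, so the correction is a
    deterministic function of the configuration alone (and is cached on
    it — replicated runs that differ only in seed share the correction).
    """
    key = (
        n_draws,
        n_iter,
        float(cfg.holiday_school_dropout),
        tuple(np.asarray(cfg.day_type_centres[t], float).tobytes() for t in DAY_TYPES),
        np.asarray(cfg.between_child_sd, float).tobytes(),
        np.asarray(cfg.within_child_sd, float).tobytes(),
    )
    cached = _CENTRE_CACHE.get(key)
    if cached is not None:
        return {t: v.copy() for t, v in cached.items()}
    V = pivot_basis(D).V
    total_sd = np.sqrt(
        np.asarray(cfg.between_child_sd, float) ** 2
        + np.asarray(cfg.within_child_sd, float) ** 2
    )
    half = np.random.default_rng(202399).standard_normal((n_draws // 2, D - 1))
    eps = np.concatenate([half, -half]) * total_sd  # antithetic pairs
    out: dict[str, np.ndarray] = {}
    for day_type in DAY_TYPES:
        target = closure(np.asarray(cfg.day_type_centres[day_type], float), DAY_MINUTES)
        mu = ilr(target, V)
        p_drop = cfg.holiday_school_dropout if day_type == "holiday" else 0.0
        for _ in range(n_iter):
            comps = ilr_inv(mu + eps, V, DAY_MINUTES)
            mean = comps.mean(axis=0)
            if p_drop > 0:
                mean = (1.0 - p_drop) * mean + p_drop * _drop_school(comps).mean(axis=0)
            mu = mu + ilr(target, V) - ilr(closure(mean, DAY_MINUTES), V)
        out[day_type] = mu
    _CENTRE_CACHE[key] = {t: v.copy() for t, v in out.items()}
    return out


# ---------------------------------------------------------------------------
# population generation


def _sample_day_compositions(
    cfg: SimulationConfig,
    mu: dict[str, np.ndarray],
    rng: np.random.Generator,
    day_children: np.ndarray,
    day_types: list[str],
) -> np.ndarray:
    """Rounded superdomain compositions for an arbitrary day roster."""
    V = pivot_basis(D).V
    n = cfg.n_children
    between = np.asarray(cfg.between_child_sd, float)
    within = np.asarray(cfg.within_child_sd, float)
    child_eff = rng.standard_normal((n, D - 1)) * between
    noise = rng.standard_normal((len(day_types), D - 1)) * within
    centres = np.stack([mu[t] for t in day_types])
    z = centres + child_eff[day_children] + noise
    comps = ilr_inv(z, V, DAY_MINUTES)
    if cfg.holiday_school_dropout > 0:
        holiday = np.array([t == "holiday" for t in day_types])
        drop = holiday & (rng.random(len(day_types)) < cfg.holiday_school_dropout)
        if drop.any():
            comps[drop] = _drop_school(comps[drop])
    return round_to_grid(comps)


def _split_events(
    minutes: np.ndarray,
    tax: ActivityTaxonomy,
    rng: np.random.Generator,
    event_rate: float,
) -> tuple[tuple[str, float], ...]:
    """Split a rounded superdomain composition into ≥5-min activity events."""
    events: list[tuple[str, float]] = []
    for s_idx, sname in enumerate(SUPERDOMAINS):
        m = float(minutes[s_idx])
        if m <= 0:
            continue
        codes = tax.codes_in_superdomain(sname)
        if not codes:
            raise ValueError(f"taxonomy has no activities for {sname!r}")
        max_k = int(min(len(codes), m // RESOLUTION_MIN))
        k = int(min(1 + rng.poisson(event_rate), max_k))
        chosen = rng.choice(len(codes), size=k, replace=False)
        weights = rng.dirichlet(np.ones(k))
        # scalar largest-remainder onto the 5-min grid (hot path)
        units = m / RESOLUTION_MIN * weights
        base = np.floor(units).astype(int)
        short = int(round(m / RESOLUTION_MIN)) - int(base.sum())
        if short:
            base[np.argsort(-(units - base), kind="stable")[:short]] += 1
        for c, mm in zip(chosen, base * RESOLUTION_MIN):
            if mm > 0:
                events.append((codes[int(c)], float(mm)))
    return tuple(events)


def _sample_covariates(
    cfg: SimulationConfig, rng: np.random.Generator, child_ids: list[str]
) -> list[CovariateRecord]:
    spec = cfg.covariates
    n = len(child_ids)
    sex = np.where(rng.random(n) < spec.female_prob, "female", "male")
    age = rng.uniform(*spec.age_range, size=n)
    weight = np.maximum(
        spec.weight_intercept
        + spec.weight_slope * age
        + rng.normal(0.0, spec.weight_sd, size=n),
        25.0,
    )
    zbmi = rng.choice(
        ["normal_or_under", "overweight", "obese"], size=n, p=spec.zbmi_probs
    )
    education = rng.choice(
        ["university", "post_secondary", "high_school"],
        size=n,
        p=spec.education_probs,
    )
    irsd = rng.normal(spec.irsd_mean, spec.irsd_sd, size=n)
    missing = (
        rng.choice(n, size=min(spec.n_missing_irsd, n), replace=False)
        if spec.n_missing_irsd
        else np.array([], dtype=int)
    )
    records = []
    for i, cid in enumerate(child_ids):
        records.append(
            CovariateRecord(
                child_id=cid,
                sex=str(sex[i]),
                age=float(age[i]),
                weight=float(weight[i]),
                zbmi_category=str(zbmi[i]),
                parent_education=str(education[i]),
                irsd=None if i in missing else float(irsd[i]),
            )
        )
    return records


def generate_population(
    cfg: SimulationConfig, tax: ActivityTaxonomy | None = None
) -> SimulatedPopulation:
    """Draw a full diary population (diaries + covariates + truth).

    Every child receives one day of each type (plus, with probability
    ``duplicate_day_prob``, one extra day of a random type), so all
    children are eligible for profile construction.  Deterministic under
    ``cfg.seed``.
    """
    cfg.validate()
    if tax is None:
        tax = bundled_taxonomy()
    rng = np.random.default_rng(cfg.seed)
    mu = _corrected_ilr_centres(cfg)
    n = cfg.n_children
    child_ids = [f"c{i:04d}" for i in range(n)]

    day_children: list[int] = []
    day_types: list[str] = []
    extra = rng.random(n) < cfg.duplicate_day_prob
    extra_type = rng.integers(0, len(DAY_TYPES), size=n)
    for i in range(n):
        for t in DAY_TYPES:
            day_children.append(i)
            day_types.append(t)
        if extra[i]:
            day_children.append(i)
            day_types.append(DAY_TYPES[int(extra_type[i])])
    comps = _sample_day_compositions(
        cfg, mu, rng, np.asarray(day_children), day_types
    )

    diaries = [
        DiaryDay(
            child_ids[ci],
            t,
            _split_events(comps[j], tax, rng, cfg.event_rate),
        )
        for j, (ci, t) in enumerate(zip(day_children, day_types))
    ]
    covariates = _sample_covariates(cfg, rng, child_ids)

    centres = {
        t: np.asarray(cfg.day_type_centres[t], float) for t in DAY_TYPES
    }
    interm_target = (5.0 * centres["school"] + 2.0 * centres["weekend_in_term"]) / 7.0
    truth = {
        "parts": list(SUPERDOMAINS),
        "day_type_means": {t: centres[t].tolist() for t in DAY_TYPES},
        "interm_mean": interm_target.tolist(),
        "expected_differences": dict(
            zip(SUPERDOMAINS, (centres["holiday"] - interm_target).tolist())
        ),
        "seed": cfg.seed,
        "n_children": n,
    }
    return SimulatedPopulation(diaries, covariates, truth)


# ---------------------------------------------------------------------------
# simulation harnesses


def _rep_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] & 0x7FFFFFFF)


def recovery_experiment(
    cfg: SimulationConfig | None = None,
    n_reps: int = 50,
    seed: int = 0,
    tax: ActivityTaxonomy | None = None,
) -> pd.DataFrame:
    """Parameter recovery through the full diary pipeline.

    Each replicate draws a population, builds composite profiles from the
    event-level diaries and recomputes the period-difference table; the
    report compares the mean recovered holiday-minus-in-term differences
    with the differences implied by the configured centres.
    """
    if cfg is None:
        cfg = default_config()
    if tax is None:
        tax = bundled_taxonomy()
    diffs = []
    truth = None
    for rep in range(n_reps):
        rep_cfg = replace(cfg, seed=_rep_seed(seed, rep))
        pop = generate_population(rep_cfg, tax)
        truth = pop.truth
        profiles, _ = build_profiles(pop.diaries, tax, seed=_rep_seed(seed, 10_000 + rep))
        table = difference_table(profiles_to_frame(profiles))
        diffs.append(table["difference"].reindex(list(SUPERDOMAINS)).to_numpy())
    diffs = np.stack(diffs)
    configured = np.array([truth["expected_differences"][s] for s in SUPERDOMAINS])
    recovered = diffs.mean(axis=0)
    rep_sd = diffs.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(D)
    return pd.DataFrame(
        {
            "configured_difference": configured,
            "recovered_difference": recovered,
            "bias": recovered - configured,
            "rep_sd": rep_sd,
            "mc_se": rep_sd / np.sqrt(n_reps),
        },
        index=pd.Index(SUPERDOMAINS, name="domain"),
    )


def _fast_profiles(
    cfg: SimulationConfig,
    mu: dict[str, np.ndarray],
    rng: np.random.Generator,
    weights: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (interm, holiday) composition matrices, one day per type.

    Skips event splitting (the tests consume superdomain compositions
    only) but keeps the 5-min rounding and holiday dropout.
    """
    n = cfg.n_children
    day_children = np.tile(np.arange(n), 3)
    day_types = (
        ["school"] * n + ["weekend_in_term"] * n + ["holiday"] * n
    )
    comps = _sample_day_compositions(cfg, mu, rng, day_children, day_types)
    school, weekend, holiday = comps[:n], comps[n : 2 * n], comps[2 * n :]
    w1, w2 = float(weights[0]), float(weights[1])
    interm = (w1 * school + w2 * weekend) / (w1 + w2)
    return interm, holiday


def _difference_matrix(
    interm: np.ndarray, holiday: np.ndarray, V: np.ndarray
) -> np.ndarray:
    interm = multiplicative_replacement(interm, DAY_MINUTES)
    holiday = multiplicative_replacement(holiday, DAY_MINUTES)
    return ilr(holiday, V) - ilr(interm, V)


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a proportion."""
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def null_rejection_experiment(
    cfg_null: SimulationConfig | None = None,
    alpha: float = 0.05,
    n_reps: int = 2000,
    seed: int = 0,
    weights: tuple[float, float] = (1.0, 0.0),
    mode: str = "full",
) -> dict:
    """Empirical type-I error of the period-effect test under the null.

    Uses single-day profiles by default (composite weights (1, 0)): with
    identical day-type centres the raw-minute 5:2 composite is not an
    exact null (averaging two days shifts the expected ilr coordinates, a
    convexity effect of the composite construction), so calibration is
    assessed on the exact paired-day null.
    """
    if cfg_null is None:
        cfg_null = null_config()
    cfg_null.validate()
    centres = np.stack(
        [np.asarray(cfg_null.day_type_centres[t], float) for t in DAY_TYPES]
    )
    if not np.allclose(centres, centres[0]):
        raise ValueError("null config must have identical centres for all day types")
    mu = _corrected_ilr_centres(cfg_null)
    V = pivot_basis(D).V
    rejections = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(_rep_seed(seed, rep))
        interm, holiday = _fast_profiles(cfg_null, mu, rng, weights)
        res = time_effect_test(_difference_matrix(interm, holiday, V), mode=mode)
        rejections += res.p < alpha
    lo, hi = _binomial_ci(rejections, n_reps)
    return {
        "alpha": alpha,
        "n_reps": n_reps,
        "rejection_rate": rejections / n_reps,
        "ci_low": lo,
        "ci_high": hi,
    }


def moderation_null_experiment(
    cfg: SimulationConfig | None = None,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
    group_probs: Sequence[float] = (162 / 363, 140 / 363, 61 / 363),
    weights: tuple[float, float] = (5.0, 2.0),
) -> dict:
    """Moderation-test rejection rate when the period effect is homogeneous.

    Groups (e.g. parental-education categories) are assigned
    independently of the simulated time-use change, so the one-way MANOVA
    on difference vectors should reject at ≈ alpha.
    """
    if cfg is None:
        cfg = default_config()
    cfg.validate()
    mu = _corrected_ilr_centres(cfg)
    V = pivot_basis(D).V
    g = len(group_probs)
    rejections = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(_rep_seed(seed, rep))
        interm, holiday = _fast_profiles(cfg, mu, rng, weights)
        groups = rng.choice(g, size=cfg.n_children, p=list(group_probs))
        # guarantee the minimum group size the test requires
        while np.bincount(groups, minlength=g).min() < 2:
            groups = rng.choice(g, size=cfg.n_children, p=list(group_probs))
        res = moderation_test(_difference_matrix(interm, holiday, V), groups)
        rejections += res.p < alpha
    lo, hi = _binomial_ci(rejections, n_reps)
    return {
        "alpha": alpha,
        "n_reps": n_reps,
        "rejection_rate": rejections / n_reps,
        "ci_low": lo,
        "ci_high": hi,
    }


def power_curve(
    effect_norms: Sequence[float],
    cfg: SimulationConfig | None = None,
    alpha: float = 0.05,
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical power of the period-effect test vs effect size.

    The effect is a shift of the holiday ilr centre along the direction
    (1, ..., 1)/sqrt(7), of the given Aitchison norm; effect 0 is the
    exact null.  Uses the same seed schedule for every effect size so the
    curve is smooth in the effect.
    """
    if cfg is None:
        cfg = null_config()
    cfg.validate()
    mu = _corrected_ilr_centres(cfg)
    V = pivot_basis(D).V
    direction = np.ones(D - 1) / np.sqrt(D - 1)
    rows = []
    for eta in effect_norms:
        mu_eff = dict(mu)
        mu_eff["holiday"] = mu["holiday"] + float(eta) * direction
        rejections = 0
        for rep in range(n_reps):
            rng = np.random.default_rng(_rep_seed(seed, rep))
            interm, holiday = _fast_profiles(cfg, mu_eff, rng, (1.0, 0.0))
            res = time_effect_test(_difference_matrix(interm, holiday, V))
            rejections += res.p < alpha
        rows.append({"effect_norm": float(eta), "power": rejections / n_reps})
    return pd.DataFrame(rows)
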