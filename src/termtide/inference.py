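"""Repeated-measures compositional inference and covariate imputation.

The period effect on the 8-part day composition is tested on per-child
ilr-coordinate differences (holiday − in-term).  For two time points the
multivariate time effect is exactly the paired Hotelling T² on the
7-vector of differences ("full" mode); "interaction_only" applies the
same test after a successive-difference contrast, asking whether the
change is uniform across coordinates (the time × coordinate
interaction).  Moderation by categorical covariates (parental
education, area-SES tertiles, weight status) is a one-way MANOVA on the
difference vectors using Wilks' Λ with Rao's F approximation.

Missing numeric covariates are completed by predictive mean matching:
an OLS fit on complete cases, with each missing entry receiving the
observed value of a donor whose fitted prediction is nearest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coda import IlrBasis, ilr, multiplicative_replacement, pivot_basis
from .composite import PairedProfile

__all__ = [
    "TestResult",
    "paired_differences",
    "time_effect_test",
    "moderation_test",
    "pmm_impute",
    "irsd_tertiles",
]


@dataclass(frozen=True)
class TestResult:
    """A multivariate test: statistic, F approximation, df and p-value."""

    statistic_name: str
    statistic: float
    F: float
    df1: float
    df2: float
    p: float

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if self.statistic_name == "Wilks_Lambda" and not (
            0.0 <= self.statistic <= 1.0 + 1e-12
        ):
            raise ValueError("Wilks lambda must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "statistic": self.statistic,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
        }


def paired_differences(
    profiles: Sequence[PairedProfile],
    basis: IlrBasis | None = None,
    zero_delta: float = 0.65,
    zero_dl: float = 5.0,
) -> pd.DataFrame:
    """Per-child ilr-coordinate differences, holiday minus in-term.

    Zeros are replaced multiplicatively in each composition before the
    ilr map.  Returns a frame indexed by child_id with columns
    ``ilr1..ilr{D-1}``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    parts = profiles[0].interm.parts
    if basis is None:
        basis = pivot_basis(len(parts), parts)
    total = profiles[0].interm.total
    interm = np.stack([p.interm.values for p in profiles])
    holiday = np.stack([p.holiday.values for p in profiles])
    interm = multiplicative_replacement(interm, total, dl=zero_dl, delta=zero_delta)
    holiday = multiplicative_replacement(holiday, total, dl=zero_dl, delta=zero_delta)
    diff = ilr(holiday, basis.V) - ilr(interm, basis.V)
    return pd.DataFrame(
        diff,
        index=pd.Index([p.child_id for p in profiles], name="child_id"),
        columns=[f"ilr{i + 1}" for i in range(diff.shape[1])],
    )


def _as_matrix(Dm) -> np.ndarray:
    X = Dm.to_numpy(dtype=float) if isinstance(Dm, pd.DataFrame) else np.asarray(Dm, dtype=float)
    if X.ndim != 2:
        raise ValueError("difference matrix must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("difference matrix must be finite with no missing entries")
    return X


def _successive_difference_contrast(p: int) -> np.ndarray:
    C = np.zeros((p - 1, p))
    for i in range(p - 1):
        C[i, i] = 1.0
        C[i, i + 1] = -1.0
    return C


def time_effect_test(Dm, mode: str = "full") -> TestResult:
    """Paired Hotelling T² for the period effect on ilr differences.

    ``full`` tests H0: mean difference vector = 0 on all D−1 coordinates.
    ``interaction_only`` first applies the successive-difference contrast
    across coordinates, testing whether the change is uniform over
    coordinates (the time × coordinate-number interaction).
    """
    X = _as_matrix(Dm)
    if mode == "interaction_only":
        X = X @ _successive_difference_contrast(X.shape[1]).T
    elif mode != "full":
        raise ValueError("mode must be 'full' or 'interaction_only'")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p ({n} <= {p})")
    mean = X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    if np.allclose(mean, 0.0):
        t2 = 0.0  # no shift at all (covers the degenerate all-zero matrix)
    else:
        try:
            sol = np.linalg.solve(S, mean)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular covariance of differences; collect more children or "
                "aggregate to fewer parts"
            ) from err
        t2 = float(n * mean @ sol)
    F = t2 * (n - p) / (p * (n - 1.0))
    pval = float(stats.f.sf(F, p, n - p))
    return TestResult("Hotelling_T2", t2, F, p, n - p, pval)


def moderation_test(Dm, groups: Sequence) -> TestResult:
    """One-way MANOVA of difference vectors across groups (Wilks' Λ).

    Tests whether the holiday-minus-in-term change differs between the
    supplied groups (e.g. parental-education categories, IRSD tertiles or
    weight status), using Rao's F approximation of Wilks' Λ.
    """
    X = _as_matrix(Dm)
    labels = np.asarray(pd.Categorical(list(groups)).codes)
    if len(labels) != X.shape[0]:
        raise ValueError("groups must align with rows of the difference matrix")
    if np.any(labels < 0):
        raise ValueError("groups contain missing labels")
    n, p = X.shape
    uniq = np.unique(labels)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least two groups")
    counts = np.array([(labels == u).sum() for u in uniq])
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")
    if n - g <= p:
        raise ValueError(f"need n - g > p ({n} - {g} <= {p})")
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for u in uniq:
        sub = X[labels == u]
        centred = sub - sub.mean(axis=0)
        W += centred.T @ centred
        dm = sub.mean(axis=0) - grand
        B += len(sub) * np.outer(dm, dm)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError(
            "singular within-group scatter; collect more children per group"
        )
    lam = float(min(np.exp(logdet_w - logdet_t), 1.0))
    df1 = p * (g - 1)
    denom = p * p + (g - 1) ** 2 - 5
    t = np.sqrt((p * p * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    m = n - 1 - (p + g) / 2.0
    df2 = m * t - df1 / 2.0 + 1.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * (df2 / df1)
    pval = float(stats.f.sf(F, df1, df2))
    return TestResult("Wilks_Lambda", lam, float(F), float(df1), float(df2), pval)


# ---------------------------------------------------------------------------
# predictive mean matching


def pmm_impute(
    target: Sequence[float],
    predictors: np.ndarray,
    k_donors: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Complete a numeric vector by predictive mean matching.

    An ordinary least-squares model (with intercept) is fit on complete
    cases; each missing entry receives the observed target value of one
    of the ``k_donors`` complete cases whose fitted prediction is nearest
    to its own, chosen uniformly under ``seed``.  Imputed values are
    therefore always values observed elsewhere in ``target``.
    """
    y = np.asarray(target, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("target and predictors must have equal length")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be complete")
    missing = ~np.isfinite(y)
    if not missing.any():
        return y.copy()
    obs = ~missing
    n_obs = int(obs.sum())
    n_coef = X.shape[1] + 1
    if n_obs < max(k_donors, n_coef):
        raise ValueError(
            f"need at least max(k_donors, n_predictors+1) = "
            f"{max(k_donors, n_coef)} complete cases, have {n_obs}"
        )
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design[obs], y[obs], rcond=None)
    fitted = design @ beta
    rng = np.random.default_rng(seed)
    out = y.copy()
    obs_idx = np.flatnonzero(obs)
    for i in np.flatnonzero(missing):
        dist = np.abs(fitted[obs_idx] - fitted[i])
        donors = obs_idx[np.argsort(dist, kind="stable")[:k_donors]]
        out[i] = y[rng.choice(donors)]
    return out


def irsd_tertiles(irsd: Sequence[float]) -> np.ndarray:
    """Sample-quantile tertiles of an area-SES index (1 = most disadvantaged).

    Cut-points are the 1/3 and 2/3 sample quantiles; values equal to a
    cut-point go to the lower tertile.
    """
    x = np.asarray(irsd, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("IRSD must be complete (impute first)")
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    return np.where(x <= q1, 1, np.where(x <= q2, 2, 3))
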