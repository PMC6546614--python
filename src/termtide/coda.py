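"""Compositional geometry for daily time-use budgets.

A day is treated as a composition: a vector of non-negative parts
(minutes per activity domain) carrying only relative information, closed
to 1440 min.  This module provides closure, multiplicative zero
replacement, the isometric log-ratio (ilr) transformation under a
pivot (sequential binary partition) basis and its inverse, compositional
means, the period-difference summary table, and the percentage TDEE
decrement between periods.

Array-level functions operate on the last axis and broadcast, so they
can be used both on a single composition and on whole populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hierarchy import DAY_MINUTES, RESOLUTION_MIN

__all__ = [
    "Composition",
    "IlrBasis",
    "closure",
    "close",
    "replace_zeros",
    "pivot_basis",
    "ilr",
    "ilr_inv",
    "ilr_transform",
    "ilr_inverse",
    "aitchison_distance",
    "compositional_mean",
    "difference_table",
    "pct_decrement",
]


@dataclass(frozen=True)
class Composition:
    """A closed vector of named non-negative parts (min/day)."""

    parts: tuple[str, ...]
    values: np.ndarray
    total: float = DAY_MINUTES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != len(self.parts):
            raise ValueError("values must be 1-D and match part names")
        if np.any(values < 0):
            raise ValueError("composition parts must be non-negative")
        if not np.isclose(values.sum(), self.total, atol=1e-9, rtol=1e-12):
            raise ValueError(
                f"parts sum to {values.sum():.6f}, expected {self.total}"
            )

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.parts.index(part)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.parts))


# ---------------------------------------------------------------------------
# closure and zero replacement


def closure(x: np.ndarray, kappa: float = DAY_MINUTES) -> np.ndarray:
    """Rescale non-negative vectors (last axis) to sum to ``kappa``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("closure requires non-negative parts")
    totals = x.sum(axis=-1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("cannot close an all-zero composition")
    return kappa * x / totals


def close(
    x: Sequence[float] | np.ndarray,
    kappa: float = DAY_MINUTES,
    parts: Sequence[str] | None = None,
) -> Composition:
    """Close a single vector and wrap it as a :class:`Composition`."""
    values = closure(np.asarray(x, dtype=float), kappa)
    if parts is None:
        parts = tuple(f"part{i + 1}" for i in range(values.shape[-1]))
    return Composition(tuple(parts), values, kappa)


def multiplicative_replacement(
    x: np.ndarray,
    kappa: float = DAY_MINUTES,
    dl: float = float(RESOLUTION_MIN),
    delta: float = 0.65,
) -> np.ndarray:
    """Replace zero parts by ``delta * dl`` and rescale the rest.

    Zero parts are imputed at a fraction ``delta`` of the detection limit
    ``dl`` (the 5-min diary resolution by default); non-zero parts are
    multiplied by ``1 - imputed_total / kappa`` so the closure constant is
    preserved and all ratios between originally non-zero parts are
    untouched.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.all(x <= 0, axis=-1)):
        raise ValueError("each composition needs at least one positive part")
    imputed = delta * dl
    zero = x == 0
    imputed_total = imputed * zero.sum(axis=-1, keepdims=True)
    if np.any(imputed_total >= kappa):
        raise ValueError("imputed total exceeds the closure constant")
    out = np.where(zero, imputed, x * (1.0 - imputed_total / kappa))
    return out


def replace_zeros(
    x: Composition, delta: float = 0.65, dl: float = float(RESOLUTION_MIN)
) -> Composition:
    """Multiplicative simple replacement of zero parts of a composition."""
    values = multiplicative_replacement(x.values, x.total, dl=dl, delta=delta)
    return Composition(x.parts, values, x.total)


# ---------------------------------------------------------------------------
# ilr transformation


@dataclass(frozen=True)
class IlrBasis:
    """Orthonormal log-contrast basis: a (D, D-1) matrix V.

    Columns are orthonormal and orthogonal to the all-ones vector, so
    ``z = V.T @ clr(x)`` is an isometry from the D-part simplex onto
    R^(D-1).
    """

    V: np.ndarray
    parts: tuple[str, ...] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        object.__setattr__(self, "V", V)
        D = V.shape[0]
        if V.shape != (D, D - 1):
            raise ValueError("basis must have shape (D, D-1)")
        if not np.allclose(V.T @ V, np.eye(D - 1), atol=1e-10):
            raise ValueError("basis columns must be orthonormal")
        if not np.allclose(V.sum(axis=0), 0.0, atol=1e-10):
            raise ValueError("basis columns must be log-contrasts (sum to 0)")

    @property
    def n_parts(self) -> int:
        return self.V.shape[0]


def pivot_basis(D: int, parts: Sequence[str] | None = None) -> IlrBasis:
    """Sequential-binary-partition (pivot) ilr basis for ``D`` parts.

    Coordinate k contrasts part k against the geometric mean of parts
    k+1..D, scaled by sqrt((D-k)/(D-k+1)) so the basis is orthonormal.
    """
    if D < 2:
        raise ValueError("need at least two parts")
    V = np.zeros((D, D - 1))
    for k in range(D - 1):
        r = D - k - 1  # number of parts in the denominator group
        scale = np.sqrt(r / (r + 1.0))
        V[k, k] = scale
        V[k + 1 :, k] = -scale / r
    return IlrBasis(
        V,
        tuple(parts) if parts is not None else None,
        description="pivot (sequential binary partition)",
    )


def ilr(x: np.ndarray, V: np.ndarray) -> np.ndarray:
    """ilr coordinates ``V.T @ log(x / g(x))`` along the last axis."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(
            "ilr requires strictly positive parts; apply replace_zeros first"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=-1, keepdims=True)
    return clr @ V


def ilr_inv(
    z: np.ndarray, V: np.ndarray, kappa: float = DAY_MINUTES
) -> np.ndarray:
    """Inverse ilr: close ``exp(V @ z)`` to ``kappa`` (last axis)."""
    z = np.asarray(z, dtype=float)
    return closure(np.exp(z @ V.T), kappa)


def ilr_transform(x: Composition, basis: IlrBasis) -> np.ndarray:
    """ilr coordinates (length D-1) of a single composition."""
    if basis.n_parts != len(x.parts):
        raise ValueError("basis size does not match composition")
    return ilr(x.values, basis.V)


def ilr_inverse(
    z: np.ndarray, basis: IlrBasis, kappa: float = DAY_MINUTES
) -> Composition:
    """Back-transform ilr coordinates into a composition."""
    values = ilr_inv(np.asarray(z, dtype=float), basis.V, kappa)
    parts = basis.parts or tuple(
        f"part{i + 1}" for i in range(basis.n_parts)
    )
    return Composition(tuple(parts), values, kappa)


def aitchison_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Aitchison distance: Euclidean distance between clr images."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lx = np.log(x)
    ly = np.log(y)
    dx = lx - lx.mean(axis=-1, keepdims=True)
    dy = ly - ly.mean(axis=-1, keepdims=True)
    return np.sqrt(((dx - dy) ** 2).sum(axis=-1))


def compositional_mean(X: Iterable[Composition]) -> Composition:
    """Closed geometric mean of compositions (the compositional centre).

    Equals the ilr-inverse of the arithmetic mean of ilr coordinates in
    any orthonormal basis.
    """
    comps = list(X)
    if not comps:
        raise ValueError("compositional_mean of an empty collection")
    parts, total = comps[0].parts, comps[0].total
    mat = np.stack([c.values for c in comps])
    if np.any(mat <= 0):
        raise ValueError("compositional_mean requires strictly positive parts")
    centre = closure(np.exp(np.log(mat).mean(axis=0)), total)
    return Composition(parts, centre, total)


# ---------------------------------------------------------------------------
# reporting


def _profiles_frame(profiles: Iterable) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {"child_id": p.child_id, "period": "interm", **dict(zip(p.interm.parts, p.interm.values))}
        )
        rows.append(
            {"child_id": p.child_id, "period": "holiday", **dict(zip(p.holiday.parts, p.holiday.values))}
        )
    return pd.DataFrame(rows)


def difference_table(
    data, round_to: int | None = None
) -> pd.DataFrame:
    """Arithmetic mean (SD) per period and holiday-minus-in-term difference.

    ``data`` is either a wide frame with columns ``child_id``, ``period``
    (values ``interm``/``holiday``) and one column per variable, or an
    iterable of paired profiles.  Returns one row per variable with
    columns ``interm_mean``, ``interm_sd``, ``holiday_mean``,
    ``holiday_sd`` and ``difference`` (holiday minus in-term).  Means and
    differences are rounded to ``round_to`` decimals when given (SDs
    likewise); differences are computed from the unrounded means.
    """
    if not isinstance(data, pd.DataFrame):
        data = _profiles_frame(data)
    value_cols = [c for c in data.columns if c not in ("child_id", "period")]
    if not value_cols:
        raise ValueError("no value columns to summarise")
    bad = set(data["period"]) - {"interm", "holiday"}
    if bad:
        raise ValueError(f"unknown period labels: {sorted(bad)}")
    grouped = data.groupby("period")[value_cols]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    out = pd.DataFrame(
        {
            "interm_mean": mean.loc["interm"],
            "interm_sd": sd.loc["interm"],
            "holiday_mean": mean.loc["holiday"],
            "holiday_sd": sd.loc["holiday"],
        }
    )
    out["difference"] = out["holiday_mean"] - out["interm_mean"]
    out.index.name = "domain"
    if round_to is not None:
        out = out.round(round_to)
    return out


def pct_decrement(
    interm_tdee: float,
    holiday_tdee: float,
    denominator: str = "holiday",
    ndigits: int | None = 1,
) -> float:
    """Percent by which in-term TDEE exceeds holiday TDEE.

    Computed as ``100 * (interm - holiday) / holiday`` by default; pass
    ``denominator="interm"`` for the in-term-based variant.  Rounded to
    one decimal for reporting (``ndigits=None`` disables rounding).
    """
    if interm_tdee <= 0 or holiday_tdee <= 0:
        raise ValueError("TDEE values must be positive")
    denom = {"holiday": holiday_tdee, "interm": interm_tdee}.get(denominator)
    if denom is None:
        raise ValueError("denominator must be 'holiday' or 'interm'")
    pct = 100.0 * (interm_tdee - holiday_tdee) / denom
    return round(pct, ndigits) if ndigits is not None else pct
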