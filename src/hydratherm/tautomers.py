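"""Tautomer-mixture affinity analysis.

A cationized base present as a mixture of tautomers exhibits an effective
metal-ion affinity (MIA) equal to the population-weighted sum of the
tautomer MIAs. Water binding energy correlates (negatively) with MIA across
bases, so regressing binding energy on MIA and inverting the line at an
observed binding energy yields the effective MIA of the mixture — the test
for whether a base behaves as its canonical tautomer or as a mixture.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Sequence

import numpy as np

from .exceptions import DomainError, FitError, InsufficientDataError

__all__ = [
    "TautomerSet",
    "CorrelationModel",
    "weighted_mia",
    "fit_correlation",
    "infer_effective_mia",
    "mixture_feasible_set",
]

_SIMPLEX_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class TautomerSet:
    """Tautomer labels, metal-ion affinities (kJ/mol) and mole fractions."""

    labels: tuple[str, ...]
    mias: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        mias = tuple(float(m) for m in self.mias)
        fractions = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "mias", mias)
        object.__setattr__(self, "fractions", fractions)
        if not (len(labels) == len(mias) == len(fractions)):
            raise DomainError("labels, mias and fractions must have equal length")
        if len(labels) == 0:
            raise DomainError("empty tautomer set")
        if any(f < 0 for f in fractions):
            raise DomainError(f"fractions must be non-negative: {fractions}")
        if abs(sum(fractions) - 1.0) > _SIMPLEX_TOL:
            raise DomainError(f"fractions must sum to 1, got {sum(fractions)!r}")


@dataclasses.dataclass(frozen=True)
class CorrelationModel:
    """OLS line of water binding energy (kJ/mol) against MIA (kJ/mol)."""

    slope: float
    intercept: float
    point_labels: tuple[str, ...]
    residuals: tuple[float, ...]
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.residuals) != len(self.point_labels):
            raise DomainError("one residual per point required")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict(self, mia: float) -> float:
        return self.intercept + self.slope * mia


def weighted_mia(t: TautomerSet) -> float:
    """Population-weighted effective MIA, ``sum(x_i * MIA_i)``."""
    return float(np.dot(t.fractions, t.mias))


def fit_correlation(
    points: Sequence[tuple[str, float, float]]
) -> CorrelationModel:
    """Ordinary least squares of binding energy on MIA.

    ``points`` are (label, MIA kJ/mol, binding energy -dH kJ/mol) triples.
    """
    if len(points) < 3:
        raise InsufficientDataError(
            f"need at least 3 points for a correlation, got {len(points)}"
        )
    labels = tuple(p[0] for p in points)
    x = np.array([p[1] for p in points], dtype=float)
    y = np.array([p[2] for p in points], dtype=float)
    x_bar, y_bar = x.mean(), y.mean()
    s_xx = float(((x - x_bar) ** 2).sum())
    if s_xx <= 0:
        raise FitError("all MIA values equal: singular design")
    slope = float(((x - x_bar) * (y - y_bar)).sum() / s_xx)
    intercept = float(y_bar - slope * x_bar)
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y_bar) ** 2).sum())
    if ss_tot > 0:
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    else:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    return CorrelationModel(
        slope=slope,
        intercept=intercept,
        point_labels=labels,
        residuals=tuple(resid.tolist()),
        r_squared=r2,
    )


def infer_effective_mia(binding: float, model: CorrelationModel) -> float:
    """Invert the correlation line at an observed binding energy."""
    if abs(model.slope) < 1e-6:
        raise FitError(f"slope {model.slope!r} too close to zero to invert")
    return (binding - model.intercept) / model.slope


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    # lexicographic enumeration of non-negative integer vectors summing to total
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def mixture_feasible_set(
    target_mia: float,
    tol: float,
    mias: Sequence[float],
    grid_step: float,
) -> list[tuple[float, ...]]:
    """All simplex-grid fraction vectors whose weighted MIA hits the target.

    Enumerates mole-fraction vectors on the simplex grid of step
    ``grid_step`` (which must divide 1 evenly) and keeps those with
    ``|sum(x_i * MIA_i) - target_mia| <= tol``. Ordering is lexicographic;
    an empty result is a valid outcome. The inversion is underdetermined,
    so a feasible *set* — never a unique composition — is returned.
    """
    if len(mias) < 2:
        raise DomainError("need at least two tautomers")
    if tol < 0:
        raise DomainError("tol must be non-negative")
    if grid_step <= 0 or grid_step > 1:
        raise DomainError("grid_step must lie in (0, 1]")
    steps = 1.0 / grid_step
    if abs(steps - round(steps)) > 1e-9:
        raise DomainError(f"grid_step {grid_step!r} must divide 1 evenly")
    m = int(round(steps))
    mia_arr = np.asarray(mias, dtype=float)
    feasible: list[tuple[float, ...]] = []
    for comp in _compositions(m, len(mias)):
        x = np.array(comp, dtype=float) / m
        if abs(float(x @ mia_arr) - target_mia) <= tol:
            feasible.append(tuple(x.tolist()))
    return feasible
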