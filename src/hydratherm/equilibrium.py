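"""Equilibrium constants from peak areas and water partial pressures.

``K = I_n * P_o / (I_{n-1} * P)`` with ``P_o = 1000 mbar``, so K is
dimensionless and independent of detector gain.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np

from .constants import STANDARD_PRESSURE_MBAR
from .exceptions import DomainError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "HydrationStepMeasurement",
    "EquilibriumSeries",
    "equilibrium_constant",
    "build_series",
]


@dataclasses.dataclass(frozen=True)
class HydrationStepMeasurement:
    """Paired product/reactant intensities for one hydration step.

    ``n`` is the product hydration number; ``I_n``/``I_nm1`` are the product
    and reactant peak areas with Poisson sigmas. ``eq_passed`` records the
    outcome of the residence-time equilibrium check when available.
    """

    species: str
    n: int
    I_n: float
    sigma_In: float
    I_nm1: float
    sigma_Inm1: float
    water_pressure: float
    temperature: float
    eq_passed: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.I_nm1 <= 0:
            raise DomainError("reactant intensity I_nm1 must be positive")
        if self.I_n < 0:
            raise DomainError("product intensity I_n must be non-negative")
        if self.sigma_In < 0 or self.sigma_Inm1 < 0:
            raise DomainError("intensity sigmas must be non-negative")
        if self.water_pressure <= 0:
            raise DomainError("water_pressure must be positive")
        if self.temperature <= 0:
            raise DomainError("temperature must be positive")
        if self.n < 1:
            raise DomainError("product hydration number n must be >= 1")


@dataclasses.dataclass(frozen=True)
class EquilibriumSeries:
    """(T, K, sigma_K) points for one hydration step of one species.

    Replicate temperatures are allowed; the van't Hoff fit, not this
    container, weights them.
    """

    species: str
    n: int
    points: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple(
            (float(t), float(k), float(s)) for t, k, s in self.points
        )
        object.__setattr__(self, "points", pts)
        for t, k, s in pts:
            if t <= 0:
                raise DomainError(f"temperature must be positive, got {t}")
            if k <= 0:
                raise DomainError(f"equilibrium constant must be positive, got {k}")
            if s < 0:
                raise DomainError(f"sigma_K must be non-negative, got {s}")

    def __len__(self) -> int:
        return len(self.points)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = np.asarray(self.points, dtype=float)
        return a[:, 0], a[:, 1], a[:, 2]


def equilibrium_constant(
    m: HydrationStepMeasurement, pressure_rel_sigma: float = 0.02
) -> tuple[float, float]:
    """Equilibrium constant and first-order propagated uncertainty.

    ``pressure_rel_sigma`` is the relative uncertainty assigned to the water
    partial pressure reading (capacitance-manometer class, default 2%).
    """
    if pressure_rel_sigma < 0:
        raise DomainError("pressure_rel_sigma must be non-negative")
    k = m.I_n * STANDARD_PRESSURE_MBAR / (m.I_nm1 * m.water_pressure)
    d_dIn = STANDARD_PRESSURE_MBAR / (m.I_nm1 * m.water_pressure)
    var = (
        (d_dIn * m.sigma_In) ** 2
        + (k / m.I_nm1 * m.sigma_Inm1) ** 2
        + (k * pressure_rel_sigma) ** 2
    )
    return float(k), float(np.sqrt(var))


def build_series(
    measurements: Sequence[HydrationStepMeasurement],
    require_eq_pass: bool = False,
    pressure_rel_sigma: float = 0.02,
) -> EquilibriumSeries:
    """Aggregate measurements of one (species, n) step into a K(T) series.

    With ``require_eq_pass`` set, measurements whose equilibrium check failed
    are excluded (and logged). Replicates at one temperature are all kept.
    Points are ordered by temperature (stable sort).
    """
    if not measurements:
        raise InsufficientDataError("no measurements supplied")
    keys = {(m.species, m.n) for m in measurements}
    if len(keys) != 1:
        raise DomainError(f"measurements mix species/steps: {sorted(keys)}")

    kept = []
    for m in measurements:
        if require_eq_pass and m.eq_passed is False:
            logger.info(
                "excluding %s n=%d at T=%.1f K: equilibrium check failed",
                m.species, m.n, m.temperature,
            )
            continue
        kept.append(m)
    if not kept:
        raise InsufficientDataError("all measurements excluded by equilibrium check")

    kept.sort(key=lambda m: m.temperature)
    species, n = next(iter(keys))
    points = []
    for m in kept:
        k, s = equilibrium_constant(m, pressure_rel_sigma=pressure_rel_sigma)
        points.append((m.temperature, k, s))
    return EquilibriumSeries(species=species, n=n, points=tuple(points))
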