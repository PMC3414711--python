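"""Synthetic pulsed-ion-beam data generator.

Emulates the statistical structure of drift-cell hydration measurements:
sequential water-attachment kinetics obeying detailed balance, pulsed
injection with a Gaussian arrival-time spread, Poisson counting noise, and
multiplicatively perturbed equilibrium-constant series. All stochastic
operations are pure functions of (inputs, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.linalg import expm
from scipy.special import erf

from .constants import STANDARD_PRESSURE_MBAR
from .equilibrium import EquilibriumSeries
from .exceptions import ConfigurationError, DomainError
from .reduction import ATDRecord
from .thermo import vant_hoff_k

__all__ = [
    "CellConditions",
    "KineticScheme",
    "SimulatedDataset",
    "equilibrium_ratio_from_thermo",
    "build_rate_matrix",
    "stationary_distribution",
    "simulate_atds",
    "simulate_k_series",
]


@dataclasses.dataclass(frozen=True)
class CellConditions:
    """Reaction-cell and injection-timing parameters.

    Pressures in mbar, times in microseconds. Defaults mirror a ~10 mbar
    N2 drift cell with a 90 us injection pulse at 1 ms repetition.
    """

    temperature: float
    carrier_pressure: float = 10.0
    water_pressure: float = 0.10
    drift_time_mean: float = 500.0
    injection_pulse_width: float = 90.0
    repetition_period: float = 1000.0
    n_pulses: int = 5000
    arrival_sigma: float = 30.0  # Gaussian arrival-time spread, us

    def __post_init__(self) -> None:
        positive = {
            "temperature": self.temperature,
            "carrier_pressure": self.carrier_pressure,
            "water_pressure": self.water_pressure,
            "drift_time_mean": self.drift_time_mean,
            "injection_pulse_width": self.injection_pulse_width,
            "repetition_period": self.repetition_period,
            "n_pulses": self.n_pulses,
            "arrival_sigma": self.arrival_sigma,
        }
        for name, value in positive.items():
            if value <= 0:
                raise DomainError(f"{name} must be positive, got {value!r}")
        if self.water_pressure >= self.carrier_pressure:
            raise DomainError("water_pressure must be below carrier_pressure")
        if self.injection_pulse_width >= self.repetition_period:
            raise DomainError("injection_pulse_width must be below repetition_period")


@dataclasses.dataclass(frozen=True)
class KineticScheme:
    """Sequential hydration kinetics for states n = 0..max_n.

    ``forward_pseudo_rates[i]`` is the pseudo-first-order attachment rate for
    the step (i -> i+1) in 1/us (water concentration absorbed). Reverse rates
    follow from detailed balance against ``true_thermo``, the ground-truth
    (dH kJ/mol, dS J/(mol K)) per step used by recovery tests.
    """

    max_n: int
    forward_pseudo_rates: tuple[float, ...]
    true_thermo: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.forward_pseudo_rates)
        thermo = tuple((float(h), float(s)) for h, s in self.true_thermo)
        object.__setattr__(self, "forward_pseudo_rates", rates)
        object.__setattr__(self, "true_thermo", thermo)
        if self.max_n < 1:
            raise ConfigurationError("max_n must be >= 1")
        if len(rates) != self.max_n or len(thermo) != self.max_n:
            raise ConfigurationError(
                "forward_pseudo_rates and true_thermo must have max_n entries"
            )
        if any(r <= 0 for r in rates):
            raise ConfigurationError("forward pseudo-rates must be positive")


@dataclasses.dataclass(frozen=True)
class SimulatedDataset:
    """ATDs plus the ground truth and seed that generated them."""

    atds: tuple[ATDRecord, ...]
    ground_truth: KineticScheme
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "atds", tuple(self.atds))


def equilibrium_ratio_from_thermo(
    dh_kj: float, ds_j: float, conditions: CellConditions
) -> float:
    """Equilibrium intensity ratio ``r_n = I_n/I_{n-1} = K_n * P / P_o``."""
    k = vant_hoff_k(dh_kj, ds_j, conditions.temperature)
    return k * conditions.water_pressure / STANDARD_PRESSURE_MBAR


def step_ratios(scheme: KineticScheme, conditions: CellConditions) -> np.ndarray:
    """Equilibrium ratios r_1..r_max_n for every step of the scheme."""
    return np.array(
        [
            equilibrium_ratio_from_thermo(dh, ds, conditions)
            for dh, ds in scheme.true_thermo
        ]
    )


def build_rate_matrix(
    scheme: KineticScheme, conditions: CellConditions
) -> np.ndarray:
    """Master-equation generator Q (dp/dt = Q p) over states 0..max_n.

    Off-diagonals carry the forward pseudo-rates and the detailed-balance
    reverse rates ``nu_rev = nu_fwd / r_n``; columns sum to zero.
    """
    ratios = step_ratios(scheme, conditions)
    if not np.all(np.isfinite(ratios)) or np.any(ratios <= 0):
        raise ConfigurationError(f"non-finite or non-positive step ratios: {ratios}")
    size = scheme.max_n + 1
    q = np.zeros((size, size))
    for i, (kf, r) in enumerate(zip(scheme.forward_pseudo_rates, ratios)):
        kr = kf / r
        q[i + 1, i] += kf
        q[i, i + 1] += kr
        q[i, i] -= kf
        q[i + 1, i + 1] -= kr
    return q


def stationary_distribution(
    scheme: KineticScheme, conditions: CellConditions
) -> np.ndarray:
    """Stationary populations from the detailed-balance product form.

    ``p_n / p_{n-1} = r_n`` exactly; tests cross-check this against a
    null-space solve of the rate matrix.
    """
    ratios = step_ratios(scheme, conditions)
    unnorm = np.concatenate([[1.0], np.cumprod(ratios)])
    return unnorm / unnorm.sum()


def _pulse_shape(
    times: np.ndarray, center: float, width: float, sigma: float
) -> np.ndarray:
    """Injection boxcar convolved with a Gaussian, normalized to unit sum."""
    a = (times - (center - width / 2.0)) / (sigma * np.sqrt(2.0))
    b = (times - (center + width / 2.0)) / (sigma * np.sqrt(2.0))
    shape = 0.5 * (erf(a) - erf(b))
    total = shape.sum()
    if total <= 0:
        raise ConfigurationError("pulse shape has zero mass on the time grid")
    return shape / total


def simulate_atds(
    scheme: KineticScheme,
    conditions: CellConditions,
    seed: int,
    species_prefix: str = "ion",
    poisson: bool = True,
) -> SimulatedDataset:
    """Simulate one accumulated ATD per hydration state.

    Populations start in n = 0 and evolve under the rate matrix for the mean
    drift time; every state shares the injection-pulse arrival shape. The
    expected count in each 1 us channel is ``n_pulses * p_n * shape``;
    observed counts are Poisson draws (or the expectation itself when
    ``poisson`` is false, for noise-free pipeline checks).
    """
    if conditions.n_pulses < 1:
        raise DomainError("n_pulses must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, conditions.repetition_period, 1.0)
    q = build_rate_matrix(scheme, conditions)
    p0 = np.zeros(scheme.max_n + 1)
    p0[0] = 1.0
    populations = expm(q * conditions.drift_time_mean) @ p0
    shape = _pulse_shape(
        times,
        center=conditions.drift_time_mean,
        width=conditions.injection_pulse_width,
        sigma=conditions.arrival_sigma,
    )
    atds = []
    for n, p_n in enumerate(populations):
        expected = conditions.n_pulses * p_n * shape
        counts = rng.poisson(expected).astype(float) if poisson else expected
        atds.append(
            ATDRecord(
                species_label=f"{species_prefix}(H2O){n}",
                hydration_n=n,
                temperature=conditions.temperature,
                water_pressure=conditions.water_pressure,
                times=times,
                counts=counts,
            )
        )
    return SimulatedDataset(atds=tuple(atds), ground_truth=scheme, seed=seed)


def simulate_k_series(
    dh_kj: float,
    ds_j: float,
    temperatures: Sequence[float],
    relative_noise: float,
    seed: int,
    species: str = "synthetic",
    n: int = 1,
) -> EquilibriumSeries:
    """Generate a K(T) series with multiplicative log-normal noise.

    ``K_obs = K_true * exp(relative_noise * Z)`` with standard-normal Z, so
    ln K carries additive noise of the stated relative magnitude; the sigma
    column is set to ``relative_noise * K_obs`` consistently.
    """
    temps = np.asarray(temperatures, dtype=float)
    if temps.size == 0:
        raise DomainError("temperatures must be non-empty")
    if np.any(temps <= 0):
        raise DomainError("temperatures must be positive")
    if relative_noise < 0:
        raise DomainError("relative_noise must be non-negative")
    rng = np.random.default_rng(seed)
    k_true = vant_hoff_k(dh_kj, ds_j, temps)
    k_true = np.atleast_1d(k_true)
    if relative_noise > 0:
        k_obs = k_true * np.exp(relative_noise * rng.standard_normal(temps.size))
    else:
        k_obs = k_true
    sigma = relative_noise * k_obs
    points = tuple(zip(temps.tolist(), k_obs.tolist(), sigma.tolist()))
    return EquilibriumSeries(species=species, n=n, points=points)
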