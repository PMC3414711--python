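"""Reduction of raw arrival-time distributions (ATDs) to peak areas.

An ATD is a histogram of ion counts versus arrival time recorded on a
multichannel scaler with a 1 microsecond dwell time per channel. The peak
area of a species' ATD is its ion intensity ``I_n``; downstream stages form
equilibrium constants from intensity ratios. This module integrates peaks
with Poisson counting uncertainties and implements the equilibrium-attainment
test: the product/reactant intensity ratio must be independent of ion
residence time.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .exceptions import DomainError, InsufficientDataError

__all__ = [
    "ATDRecord",
    "PeakArea",
    "EquilibriumCheck",
    "default_window",
    "integrate_atd",
    "ratio_vs_residence_time",
]


@dataclasses.dataclass(frozen=True)
class ATDRecord:
    """One arrival-time histogram for one ion species.

    ``times`` are channel centers in microseconds on a uniform 1 us grid;
    ``counts`` are non-negative accumulated ion counts per channel. Float
    counts are accepted so noise-free expected histograms can flow through
    the same reduction path.
    """

    species_label: str
    hydration_n: int
    temperature: float
    water_pressure: float
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        if times.ndim != 1 or counts.ndim != 1:
            raise DomainError("times and counts must be 1-D arrays")
        if times.size != counts.size:
            raise DomainError("times and counts must have equal length")
        if times.size < 2:
            raise DomainError("an ATD needs at least two channels")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise DomainError("times must be strictly increasing")
        if not np.allclose(dt, 1.0, atol=1e-9):
            raise DomainError("channel spacing must be uniform at 1 us")
        if np.any(counts < 0):
            raise DomainError("counts must be non-negative")
        if self.hydration_n < 0:
            raise DomainError("hydration_n must be >= 0")
        if self.temperature <= 0 or self.water_pressure <= 0:
            raise DomainError("temperature and water_pressure must be positive")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


@dataclasses.dataclass(frozen=True)
class PeakArea:
    """Baseline-corrected peak area with Poisson uncertainty."""

    area: float
    sigma: float
    window: tuple[float, float]
    baseline_rate: float

    def __post_init__(self) -> None:
        if self.area < 0 or self.sigma < 0:
            raise DomainError("area and sigma must be non-negative")


@dataclasses.dataclass(frozen=True)
class EquilibriumCheck:
    """Result of the ratio-versus-residence-time test.

    ``passed`` is true when the fitted slope of the product/reactant ratio
    against residence time is consistent with zero at the 2-sigma level.
    """

    slope: float
    slope_sigma: float
    ratio_mean: float
    passed: bool
    n_bins_used: int


def default_window(atd: ATDRecord, n_sigma: float = 3.0) -> tuple[float, float]:
    """Integration window ``mode +/- n_sigma * sigma_hat``.

    ``sigma_hat`` is a moment estimate of the peak width taken over the whole
    trace with counts as weights. An all-zero trace yields the full range.
    """
    counts = atd.counts
    total = counts.sum()
    if total <= 0:
        return (float(atd.times[0]), float(atd.times[-1]))
    mode = float(atd.times[int(np.argmax(counts))])
    mean = float((counts * atd.times).sum() / total)
    var = float((counts * (atd.times - mean) ** 2).sum() / total)
    width = np.sqrt(var) if var > 0 else 1.0
    lo = max(float(atd.times[0]), mode - n_sigma * width)
    hi = min(float(atd.times[-1]), mode + n_sigma * width)
    if hi <= lo:  # single hot channel
        lo, hi = mode - 0.5, mode + 0.5
    return (lo, hi)


def integrate_atd(
    atd: ATDRecord,
    window: tuple[float, float] | None = None,
    baseline_channels: int = 50,
) -> PeakArea:
    """Integrate an ATD peak over ``window`` with constant-baseline correction.

    The baseline rate is estimated from up to ``baseline_channels`` channels
    immediately preceding the window (fewer if the window starts near the
    trace edge; zero available channels means no correction). The area is
    the in-window sum minus baseline, floored at zero; the uncertainty
    combines the Poisson variance of the in-window sum with the propagated
    variance of the baseline estimate.
    """
    if window is None:
        window = default_window(atd)
    lo, hi = float(window[0]), float(window[1])
    if hi < lo:
        raise DomainError(f"empty window {window!r}")
    if hi < atd.times[0] or lo > atd.times[-1]:
        raise DomainError(
            f"window {window!r} outside ATD time range "
            f"[{atd.times[0]}, {atd.times[-1]}]"
        )
    mask = (atd.times >= lo) & (atd.times <= hi)
    n_window = int(mask.sum())
    if n_window == 0:
        raise DomainError(f"window {window!r} contains no channels")

    first = int(np.argmax(mask))
    n_base = min(int(baseline_channels), first)
    baseline_rate = 0.0
    baseline_correction = 0.0
    baseline_var = 0.0
    if n_base > 0:
        base_counts = atd.counts[first - n_base : first]
        base_sum = float(base_counts.sum())
        baseline_rate = base_sum / n_base
        baseline_correction = baseline_rate * n_window
        # var(mean) = sum(counts)/n^2 for Poisson channels
        baseline_var = (n_window**2) * base_sum / (n_base**2)

    raw = float(atd.counts[mask].sum())
    area = max(raw - baseline_correction, 0.0)
    sigma = float(np.sqrt(raw + baseline_var))
    return PeakArea(area=area, sigma=sigma, window=(lo, hi), baseline_rate=baseline_rate)


def ratio_vs_residence_time(
    product: ATDRecord,
    reactant: ATDRecord,
    n_bins: int = 8,
    count_floor: float = 10.0,
    window: tuple[float, float] | None = None,
) -> EquilibriumCheck:
    """Test that the product/reactant intensity ratio is time-independent.

    The peak region (default: the reactant's integration window) is split
    into ``n_bins`` equal time bins; per-bin count ratios carry Poisson
    errors and a weighted straight line of ratio vs. bin-center time is
    fitted. Equilibrium is accepted when ``|slope| <= 2 * slope_sigma``.
    Bins whose reactant sum falls below ``count_floor`` (or whose product
    sum is zero, making the ratio error undefined) are excluded.
    """
    if n_bins < 3:
        raise DomainError("n_bins must be >= 3")
    if product.times.size != reactant.times.size or not np.allclose(
        product.times, reactant.times
    ):
        raise DomainError("product and reactant must share the same time axis")
    if window is None:
        window = default_window(reactant)
    lo, hi = float(window[0]), float(window[1])
    edges = np.linspace(lo, hi, n_bins + 1)

    centers, ratios, sigmas = [], [], []
    for i in range(n_bins):
        left, right = edges[i], edges[i + 1]
        if i < n_bins - 1:
            m = (reactant.times >= left) & (reactant.times < right)
        else:
            m = (reactant.times >= left) & (reactant.times <= right)
        r_sum = float(reactant.counts[m].sum())
        p_sum = float(product.counts[m].sum())
        if r_sum < count_floor or p_sum <= 0:
            continue
        ratio = p_sum / r_sum
        sigma = ratio * np.sqrt(1.0 / p_sum + 1.0 / r_sum)
        centers.append(0.5 * (left + right))
        ratios.append(ratio)
        sigmas.append(sigma)

    if len(ratios) < 3:
        raise InsufficientDataError(
            f"only {len(ratios)} usable bins (need >= 3); "
            "raise counts or widen the window"
        )

    t = np.asarray(centers)
    y = np.asarray(ratios)
    w = 1.0 / np.asarray(sigmas) ** 2
    w_sum = w.sum()
    t_bar = float((w * t).sum() / w_sum)
    tc = t - t_bar
    s_tt = float((w * tc**2).sum())
    slope = float((w * tc * y).sum() / s_tt)
    slope_sigma = float(np.sqrt(1.0 / s_tt))
    ratio_mean = float((w * y).sum() / w_sum)
    passed = abs(slope) <= 2.0 * slope_sigma
    return EquilibriumCheck(
        slope=slope,
        slope_sigma=slope_sigma,
        ratio_mean=ratio_mean,
        passed=passed,
        n_bins_used=len(ratios),
    )
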