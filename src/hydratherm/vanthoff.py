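"""Weighted van't Hoff fits: ln K vs 1/T -> dH, dS, dG(298).

The fit solves ``y = a + b x`` with ``y = ln K``, ``x = 1/T`` and weights
``1/sigma(ln K)^2``; then ``dH = -R b`` and ``dS = R a``. The abscissa is
centered about its weighted mean internally and the intercept un-centered
afterwards, which keeps the normal equations well conditioned.

Uncertainty convention: with sigma weights, parameter sigmas come from the
unscaled weighted covariance (measurement errors taken at face value) and
the reduced chi-square is reported alongside; with uniform weights the
covariance is scaled by the residual variance as in ordinary least squares.
"""

from __future__ import annotations

import dataclasses
import math
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Sequence

import numpy as np

from .constants import GAS_CONSTANT, REPORT_TEMPERATURE
from .equilibrium import EquilibriumSeries
from .exceptions import DomainError, FitError

__all__ = ["ThermoResult", "vant_hoff_fit", "gibbs", "format_value", "format_table"]


@dataclasses.dataclass(frozen=True)
class ThermoResult:
    """Fitted step thermochemistry. Association values are stored signed
    (negative dH/dS); report formatting negates them."""

    species: str
    n: int
    dH: float          # kJ/mol
    dH_sigma: float
    dS: float          # J/(mol K)
    dS_sigma: float
    cov_dH_dS: float   # (kJ/mol)*(J/(mol K))
    dG298: float       # kJ/mol at REPORT_TEMPERATURE
    dG298_sigma: float
    n_points: int
    red_chi2: float

    def __post_init__(self) -> None:
        if self.dH_sigma < 0 or self.dS_sigma < 0 or self.dG298_sigma < 0:
            raise DomainError("parameter sigmas must be non-negative")
        if self.n_points < 2:
            raise DomainError("a fit needs at least two points")


def _gibbs_components(
    dh: float, ds: float, t: float, s_dh: float, s_ds: float, cov: float
) -> tuple[float, float]:
    dg = dh - t * ds / 1000.0
    var = s_dh**2 + (t / 1000.0) ** 2 * s_ds**2 - 2.0 * (t / 1000.0) * cov
    return dg, math.sqrt(max(var, 0.0))


def vant_hoff_fit(series: EquilibriumSeries, weights: str = "sigma") -> ThermoResult:
    """Fit a K(T) series, returning dH, dS with uncertainties and covariance.

    ``weights='sigma'`` uses ``w = 1/sigma(ln K)^2`` with
    ``sigma(ln K) = sigma_K / K``; ``weights='uniform'`` ignores the sigma
    column. Series whose sigma column contains non-positive entries fall
    back to uniform weighting.
    """
    if weights not in ("sigma", "uniform"):
        raise DomainError(f"unknown weights mode {weights!r}")
    t_arr, k_arr, s_arr = series.arrays()
    m = t_arr.size
    if m < 2:
        raise FitError("need at least two points to fit a line")
    if np.unique(t_arr).size < 2:
        raise FitError("all temperatures equal: singular design")

    x = 1.0 / t_arr
    y = np.log(k_arr)
    uniform = weights == "uniform" or np.any(s_arr <= 0)
    w = np.ones(m) if uniform else (k_arr / s_arr) ** 2

    w_sum = w.sum()
    x_bar = float((w * x).sum() / w_sum)
    xc = x - x_bar
    s_xx = float((w * xc**2).sum())
    if s_xx <= 0:
        raise FitError("degenerate abscissa: singular design")

    b = float((w * xc * y).sum() / s_xx)           # slope = -dH/R
    a_c = float((w * y).sum() / w_sum)             # intercept at x_bar
    resid = y - (a_c + b * xc)
    chi2 = float((w * resid**2).sum())
    dof = m - 2
    red_chi2 = chi2 / dof if dof > 0 else float("nan")

    var_b = 1.0 / s_xx
    var_ac = 1.0 / w_sum
    if uniform and dof > 0:
        var_b *= chi2 / dof
        var_ac *= chi2 / dof

    a = a_c - b * x_bar
    var_a = var_ac + x_bar**2 * var_b
    cov_ab = -x_bar * var_b

    dh = -GAS_CONSTANT * b / 1000.0
    dh_sigma = GAS_CONSTANT * math.sqrt(var_b) / 1000.0
    ds = GAS_CONSTANT * a
    ds_sigma = GAS_CONSTANT * math.sqrt(var_a)
    cov_dh_ds = -(GAS_CONSTANT**2) * cov_ab / 1000.0
    dg, dg_sigma = _gibbs_components(
        dh, ds, REPORT_TEMPERATURE, dh_sigma, ds_sigma, cov_dh_ds
    )
    return ThermoResult(
        species=series.species,
        n=series.n,
        dH=dh,
        dH_sigma=dh_sigma,
        dS=ds,
        dS_sigma=ds_sigma,
        cov_dH_dS=cov_dh_ds,
        dG298=dg,
        dG298_sigma=dg_sigma,
        n_points=m,
        red_chi2=red_chi2,
    )


def gibbs(result: ThermoResult, temperature: float) -> tuple[float, float]:
    """``dG = dH - T dS`` (kJ/mol) with propagated sigma including covariance."""
    if temperature <= 0:
        raise DomainError(f"temperature must be positive, got {temperature!r}")
    return _gibbs_components(
        result.dH,
        result.dS,
        temperature,
        result.dH_sigma,
        result.dS_sigma,
        result.cov_dH_dS,
    )


def format_value(value: float, sigma: float) -> str:
    """Render ``62.34 +/- 0.21`` as ``62.3(2)``.

    One decimal, round-half-even; the parenthetical is the uncertainty in
    units of the last displayed digit.
    """
    if sigma < 0:
        raise DomainError("sigma must be non-negative")
    shown = Decimal(repr(float(value))).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_EVEN
    )
    unc = Decimal(repr(float(sigma))).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_EVEN
    )
    return f"{shown}({int(unc * 10)})"


def format_table(results: Sequence[ThermoResult]) -> list[dict[str, str]]:
    """Report rows printing -dH, -dS, -dG(298) in the sign convention of
    association thermochemistry tables."""
    rows = []
    for r in results:
        rows.append(
            {
                "species": r.species,
                "n": str(r.n),
                "-dH_kJmol": format_value(-r.dH, r.dH_sigma),
                "-dS_JmolK": format_value(-r.dS, r.dS_sigma),
                "-dG298_kJmol": format_value(-r.dG298, r.dG298_sigma),
                "n_points": str(r.n_points),
                "red_chi2": f"{r.red_chi2:.3g}",
            }
        )
    return rows


def render_table(results: Sequence[ThermoResult]) -> str:
    """Fixed-width text rendering of :func:`format_table`."""
    rows = format_table(results)
    headers = ["species", "n", "-dH_kJmol", "-dS_JmolK", "-dG298_kJmol",
               "n_points", "red_chi2"]
    widths = {h: max(len(h), *(len(r[h]) for r in rows)) if rows else len(h)
              for h in headers}
    lines = ["  ".join(h.ljust(widths[h]) for h in headers)]
    for r in rows:
        lines.append("  ".join(r[h].ljust(widths[h]) for h in headers))
    return "\n".join(lines)
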