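"""Elementary thermodynamic relations shared by the simulator and the fits."""

from __future__ import annotations

import numpy as np

from .constants import GAS_CONSTANT
from .exceptions import DomainError


def vant_hoff_k(dh_kj: float, ds_j: float, temperature):
    """Equilibrium constant ``K = exp(-dH/RT + dS/R)``.

    Parameters
    ----------
    dh_kj : float
        Standard enthalpy change, kJ/mol (negative for association).
    ds_j : float
        Standard entropy change, J/(mol K).
    temperature : float or array
        Absolute temperature(s), K. Must be positive.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0.0):
        raise DomainError(f"temperature must be positive, got {temperature!r}")
    k = np.exp(-dh_kj * 1000.0 / (GAS_CONSTANT * t) + ds_j / GAS_CONSTANT)
    return float(k) if np.isscalar(temperature) else k


def gibbs_energy(dh_kj: float, ds_j: float, temperature: float) -> float:
    """``dG = dH - T*dS`` in kJ/mol (dS supplied in J/(mol K))."""
    if temperature <= 0.0:
        raise DomainError(f"temperature must be positive, got {temperature!r}")
    return dh_kj - temperature * ds_j / 1000.0
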