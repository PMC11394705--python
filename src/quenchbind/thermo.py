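"""Van't Hoff thermodynamics of binding.

Fits ln K_A = -dH/(R T) + dS/R across temperatures, evaluates
dG = dH - T dS, and classifies the dominant driving force from the signs
of dH and dS (hydrogen bond / van der Waals for both negative, hydrophobic
for both positive, electrostatic for dH < 0 with dS > 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import FitError, ValidationError

__all__ = [
    "GAS_CONSTANT_J_MOLK",
    "ThermoResult",
    "fit_vant_hoff",
    "gibbs_free_energy",
    "classify_forces",
    "analyze_thermodynamics",
    "celsius_to_kelvin",
]

#: Molar gas constant, J/(mol K).
GAS_CONSTANT_J_MOLK = 8.314


@dataclass(frozen=True)
class ThermoResult:
    delta_h_J_mol: float
    delta_s_J_molK: float
    delta_g_by_T: dict[float, float]  # temperature_K -> dG in J/mol
    force_label: str
    gas_constant_J_molK: float = GAS_CONSTANT_J_MOLK

    def __post_init__(self) -> None:
        for T, dg in self.delta_g_by_T.items():
            expected = self.delta_h_J_mol - T * self.delta_s_J_molK
            if dg != expected:
                raise ValidationError("delta_g_by_T inconsistent with dH - T*dS")


def celsius_to_kelvin(celsius: float, offset: float = 273.0) -> float:
    """Integer-Kelvin convention by default (30 C -> 303 K); pass
    ``offset=273.15`` for the exact thermodynamic scale."""
    return celsius + offset


def fit_vant_hoff(
    ka_by_T: Mapping[float, float],
    gas_constant: float = GAS_CONSTANT_J_MOLK,
) -> tuple[float, float]:
    """Least squares of ln K_A on 1/T; returns (dH, dS) in J/mol, J/(mol K).

    With exactly two temperatures this reduces to the exact two-point
    solution. ``ka_by_T`` may also be an iterable of (T, k_a) pairs;
    duplicate temperatures with conflicting K_A are rejected.
    """
    items = ka_by_T.items() if hasattr(ka_by_T, "items") else list(ka_by_T)
    seen: dict[float, float] = {}
    for T, ka in items:
        T = float(T)
        ka = float(ka)
        if T <= 0:
            raise ValidationError("temperatures must be > 0 K")
        if ka <= 0:
            raise ValidationError("binding constants must be > 0")
        if T in seen and seen[T] != ka:
            raise ValidationError(f"duplicate temperature {T} K with conflicting k_a")
        seen[T] = ka
    if len(seen) < 2:
        raise FitError("Van't Hoff fit needs >= 2 distinct temperatures")
    temps = np.array(sorted(seen))
    x = 1.0 / temps
    y = np.log([seen[T] for T in temps])
    slope, intercept = np.polyfit(x, y, 1)
    delta_h = -gas_constant * float(slope)
    delta_s = gas_constant * float(intercept)
    return delta_h, delta_s


def gibbs_free_energy(delta_h_J_mol: float, delta_s_J_molK: float, temperature_K: float) -> float:
    """dG = dH - T dS, all in J/mol."""
    if not (math.isfinite(delta_h_J_mol) and math.isfinite(delta_s_J_molK)):
        raise ValidationError("dH and dS must be finite")
    if not temperature_K > 0:
        raise ValidationError("temperature must be > 0 K")
    return delta_h_J_mol - temperature_K * delta_s_J_molK


def classify_forces(
    delta_h_J_mol: float,
    delta_s_J_molK: float,
    zero_tol_h: float = 0.0,
    zero_tol_s: float = 0.0,
) -> str:
    """Sign-based driving-force rule table.

    dH < 0, dS < 0 -> hydrogen-bond+van-der-Waals; dH > 0, dS > 0 ->
    hydrophobic; dH < 0, dS > 0 -> electrostatic. Values within the zero
    tolerances, and the uncovered dH > 0 / dS < 0 quadrant, are
    indeterminate.
    """
    if not (math.isfinite(delta_h_J_mol) and math.isfinite(delta_s_J_molK)):
        raise ValidationError("dH and dS must be finite")
    if abs(delta_h_J_mol) <= zero_tol_h or abs(delta_s_J_molK) <= zero_tol_s:
        return "indeterminate"
    if delta_h_J_mol < 0 and delta_s_J_molK < 0:
        return "hydrogen-bond+van-der-Waals"
    if delta_h_J_mol > 0 and delta_s_J_molK > 0:
        return "hydrophobic"
    if delta_h_J_mol < 0 and delta_s_J_molK > 0:
        return "electrostatic"
    return "indeterminate"


def analyze_thermodynamics(
    ka_by_T: Mapping[float, float],
    gas_constant: float = GAS_CONSTANT_J_MOLK,
) -> ThermoResult:
    """Full pipeline: Van't Hoff fit, per-temperature dG, force label."""
    delta_h, delta_s = fit_vant_hoff(ka_by_T, gas_constant=gas_constant)
    delta_g = {float(T): gibbs_free_energy(delta_h, delta_s, float(T)) for T in ka_by_T}
    return ThermoResult(
        delta_h_J_mol=delta_h,
        delta_s_J_molK=delta_s,
        delta_g_by_T=delta_g,
        force_label=classify_forces(delta_h, delta_s),
        gas_constant_J_molK=gas_constant,
    )
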