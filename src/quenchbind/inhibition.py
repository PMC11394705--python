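"""Enzyme-inhibition percentages and IC50 estimation from dose-response data.

Inhibition S = (A0 - A1)/A0 * 100. IC50 is estimated by a bounded
four-parameter logistic (4PL) fit by default, with monotone log-linear
interpolation available as a model-free cross-check, and an optional
case-resampling bootstrap confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .datamodel import DoseResponseTable
from .errors import FitError, ValidationError

__all__ = [
    "InhibitionCurve",
    "inhibition_rate",
    "fit_ic50",
    "four_parameter_logistic",
]


@dataclass(frozen=True)
class InhibitionCurve:
    conc_ug_ml: np.ndarray
    inhibition_pct: np.ndarray
    fitted_model: str  # "four-parameter-logistic" | "log-linear-interpolation"
    ic50: float
    ic50_ci: tuple[float, float] | None = None
    params: dict[str, float] = field(default_factory=dict)
    residual_rmse: float = float("nan")
    activation_flag: bool = False  # any negative inhibition observed


def inhibition_rate(a0: float, a1: float) -> float:
    """Percent inhibition (A0 - A1)/A0 * 100; negative values mean activation."""
    if not a0 > 0:
        raise ValidationError("a0 must be > 0")
    if a1 < 0:
        raise ValidationError("a1 must be >= 0")
    return (a0 - a1) / a0 * 100.0


def four_parameter_logistic(conc: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    """S = bottom + (top - bottom) / (1 + (ic50/conc)^hill)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / conc) ** hill)


def _inhibition_from_table(table: DoseResponseTable) -> np.ndarray:
    return np.array([inhibition_rate(a0, a1) for a0, a1 in zip(table.a0, table.a1)])


def _fit_4pl(conc: np.ndarray, inhib: np.ndarray) -> tuple[dict[str, float], float]:
    if conc.size < 4:
        raise FitError("4PL fit needs >= 4 concentrations")
    # bounds: bottom [-10, 50], top [50, 110], ic50 within a wide positive
    # range around the tested concentrations, hill > 0
    lo = [-10.0, 50.0, conc.min() / 1e3, 1e-6]
    hi = [50.0, 110.0, conc.max() * 1e3, 50.0]
    p0 = [0.0, 100.0, float(np.median(conc)), 1.0]
    try:
        popt, _ = curve_fit(
            four_parameter_logistic,
            conc,
            inhib,
            p0=p0,
            bounds=(lo, hi),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    params = dict(zip(("bottom", "top", "ic50", "hill"), map(float, popt)))
    resid = inhib - four_parameter_logistic(conc, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return params, rmse


def _interpolate_ic50(conc: np.ndarray, inhib: np.ndarray) -> float:
    """Log-linear interpolation at the first upward 50% crossing."""
    for i in range(conc.size - 1):
        lo_i, hi_i = inhib[i], inhib[i + 1]
        if lo_i <= 50.0 <= hi_i and hi_i > lo_i:
            t = (50.0 - lo_i) / (hi_i - lo_i)
            return float(10 ** (math.log10(conc[i]) + t * (math.log10(conc[i + 1]) - math.log10(conc[i]))))
    if inhib[0] >= 50.0 and conc.size >= 1 and np.all(inhib >= 50.0):
        raise FitError("all inhibition values above 50%: no crossing inside the tested range")
    raise FitError("inhibition never crosses 50% within the tested range")


def fit_ic50(
    table: DoseResponseTable,
    model: str = "4PL",
    n_boot: int = 0,
    seed: int | None = None,
) -> InhibitionCurve:
    """Estimate IC50 from a dose-response table.

    ``model`` is "4PL" (default) or "interpolation". ``n_boot`` > 0 adds a
    2.5-97.5% case-resampling bootstrap interval with the given seed.
    """
    conc = table.conc_ug_ml
    inhib = _inhibition_from_table(table)
    activation = bool(np.any(inhib < 0))

    if model == "4PL":
        params, rmse = _fit_4pl(conc, inhib)
        ic50 = params["ic50"]
        fitted_model = "four-parameter-logistic"
    elif model == "interpolation":
        ic50 = _interpolate_ic50(conc, inhib)
        params, rmse = {}, float("nan")
        fitted_model = "log-linear-interpolation"
    else:
        raise ValidationError(f"unknown model {model!r}")
    if not ic50 > 0:
        raise FitError("fitted IC50 is not positive")

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        estimates = []
        n = conc.size
        for _ in range(n_boot):
            idx = np.sort(rng.integers(0, n, size=n))
            c_b, y_b = conc[idx], inhib[idx]
            if np.unique(c_b).size < 4:
                continue
            try:
                if model == "4PL":
                    p_b, _ = _fit_4pl(np.unique(c_b), np.array([y_b[c_b == u].mean() for u in np.unique(c_b)]))
                    estimates.append(p_b["ic50"])
                else:
                    estimates.append(_interpolate_ic50(c_b, y_b))
            except FitError:
                continue
        if estimates:
            ci = (float(np.percentile(estimates, 2.5)), float(np.percentile(estimates, 97.5)))

    return InhibitionCurve(
        conc_ug_ml=conc,
        inhibition_pct=inhib,
        fitted_model=fitted_model,
        ic50=float(ic50),
        ic50_ci=ci,
        params=params,
        residual_rmse=rmse,
        activation_flag=activation,
    )
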