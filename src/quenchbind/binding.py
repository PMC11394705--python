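"""Quenching tables and binding fits.

From a titration series this module extracts per-concentration intensity
ratios, fits the linear Stern-Volmer model

    F0/F = 1 + K_SV [Q] = 1 + K_q tau0 [Q]

and the double-logarithmic binding model

    lg[(F0 - F)/F] = lg K_A + n lg[Q]

and classifies the quenching mechanism from the magnitude of K_q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import TitrationSeries
from .errors import FitError, ValidationError
from .spectral import locate_peak

__all__ = [
    "QuenchTable",
    "SternVolmerFit",
    "DoubleLogFit",
    "build_quench_table",
    "fit_stern_volmer",
    "classify_mechanism",
    "fit_double_log",
    "COLLISIONAL_QUENCH_LIMIT",
    "DEFAULT_TAU0_S",
]

#: Diffusion-limited maximum collisional quenching rate constant, L/(mol s).
COLLISIONAL_QUENCH_LIMIT = 2.0e10

#: Default average fluorophore lifetime, s.
DEFAULT_TAU0_S = 1e-8


@dataclass(frozen=True)
class QuenchTable:
    """Per-concentration quenching coordinates.

    ``lg_q`` and ``lg_ratio`` are NaN for the zero-concentration row and
    for rows where F >= F0 (no net quench; counted in ``n_excluded``).
    """

    quencher_conc_M: np.ndarray
    f0_over_f: np.ndarray
    lg_q: np.ndarray
    lg_ratio: np.ndarray
    temperature_K: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for name in ("quencher_conc_M", "f0_over_f", "lg_q", "lg_ratio"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quencher_conc_M": self.quencher_conc_M,
                "f0_over_f": self.f0_over_f,
                "lg_q": self.lg_q,
                "lg_ratio": self.lg_ratio,
            }
        )


@dataclass(frozen=True)
class SternVolmerFit:
    k_sv: float  # L/mol
    k_q: float  # L/(mol s); always k_sv / tau0_s
    intercept: float
    r2: float
    tau0_s: float
    mechanism: str  # "static-consistent" | "dynamic-consistent" | "undetermined"
    negative_slope: bool = False


@dataclass(frozen=True)
class DoubleLogFit:
    k_a: float  # L/mol; always 10**p_ka
    p_ka: float
    n: float
    r2: float


def build_quench_table(series: TitrationSeries, peak_policy: str = "fixed") -> QuenchTable:
    """Extract F0/F and double-log coordinates from a titration series.

    peak_policy "fixed" (default) reads every F at the zero-quencher peak
    wavelength, so peak drift does not contaminate the quench signal;
    "per-spectrum" reads each spectrum at its own peak.
    """
    if peak_policy not in ("fixed", "per-spectrum"):
        raise ValidationError(f"unknown peak_policy {peak_policy!r}")
    ref_peak = locate_peak(series.spectra[0])
    if ref_peak.peak_intensity_au == 0:
        raise ValidationError("zero-quencher spectrum has zero peak intensity")
    f_values = []
    for s in series.spectra:
        if peak_policy == "fixed":
            idx = int(np.argmin(np.abs(s.wavelengths_nm - ref_peak.peak_nm)))
            f = float(s.intensities_au[idx])
        else:
            f = locate_peak(s).peak_intensity_au
        if f == 0:
            raise ValidationError(
                f"zero intensity at [Q]={s.quencher_conc_M!r}: F0/F undefined"
            )
        f_values.append(f)
    f0 = f_values[0]
    concs = series.concentrations_M
    f = np.array(f_values)
    f0_over_f = f0 / f

    lg_q = np.full_like(concs, np.nan)
    lg_ratio = np.full_like(concs, np.nan)
    n_excluded = 0
    for i, (q, fi) in enumerate(zip(concs, f)):
        if q <= 0:
            continue
        lg_q[i] = math.log10(q)
        if fi < f0:
            lg_ratio[i] = math.log10((f0 - fi) / fi)
        else:
            n_excluded += 1
    return QuenchTable(
        quencher_conc_M=concs,
        f0_over_f=f0_over_f,
        lg_q=lg_q,
        lg_ratio=lg_ratio,
        temperature_K=series.temperature_K,
        n_excluded=n_excluded,
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and r^2 of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), min(r2, 1.0)


def fit_stern_volmer(
    table: QuenchTable,
    tau0_s: float = DEFAULT_TAU0_S,
    intercept_mode: str = "free",
) -> SternVolmerFit:
    """Fit F0/F against [Q] by ordinary least squares.

    ``intercept_mode`` "free" fits slope and intercept (the intercept is a
    linearity diagnostic); "fixed-at-1" regresses F0/F - 1 through the
    origin as the model strictly demands.
    """
    x = table.quencher_conc_M
    y = table.f0_over_f
    if x.size < 3:
        raise FitError("Stern-Volmer fit needs >= 3 points")
    if not np.any(x == 0):
        raise FitError("Stern-Volmer fit requires the [Q] = 0 reference point")
    if intercept_mode == "free":
        slope, intercept, r2 = _ols_line(x, y)
    elif intercept_mode == "fixed-at-1":
        denom = float(np.sum(x**2))
        slope = float(np.sum(x * (y - 1.0)) / denom)
        resid = y - (1.0 + slope * x)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / ss_tot)
        intercept = 1.0
    else:
        raise ValidationError(f"unknown intercept_mode {intercept_mode!r}")
    k_q = slope / tau0_s
    negative = slope < 0
    mechanism = "undetermined" if negative else classify_mechanism(k_q)
    return SternVolmerFit(
        k_sv=slope,
        k_q=k_q,
        intercept=intercept,
        r2=r2,
        tau0_s=tau0_s,
        mechanism=mechanism,
        negative_slope=negative,
    )


def classify_mechanism(k_q: float, limit: float = COLLISIONAL_QUENCH_LIMIT) -> str:
    """Static quenching iff K_q strictly exceeds the collisional limit."""
    if not math.isfinite(k_q):
        raise ValidationError("k_q must be finite")
    return "static-consistent" if k_q > limit else "dynamic-consistent"


def fit_double_log(table: QuenchTable) -> DoubleLogFit:
    """Fit lg[(F0-F)/F] against lg[Q]; intercept = lg K_A, slope = n."""
    usable = np.isfinite(table.lg_q) & np.isfinite(table.lg_ratio)
    if int(usable.sum()) < 3:
        raise FitError("double-log fit needs >= 3 usable rows")
    slope, intercept, r2 = _ols_line(table.lg_q[usable], table.lg_ratio[usable])
    return DoubleLogFit(k_a=10.0**intercept, p_ka=intercept, n=slope, r2=r2)
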