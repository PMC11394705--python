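"""Synthetic data generators with known ground truth.

Every generator is deterministic under a fixed seed. The titration
generator inverts the double-log binding law exactly — peak intensities
satisfy (F0 - F)/F = K_A [Q]^n before noise — so zero-noise closure tests
against the fitting stages are exact. Noise is additive Gaussian on
intensities, parameterized as a fraction of the unquenched peak height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    EEM,
    DoseResponseTable,
    EmissionSpectrum,
    SynchronousSpectrum,
    TitrationSeries,
)
from .errors import ValidationError
from .inhibition import four_parameter_logistic
from .thermo import GAS_CONSTANT_J_MOLK

__all__ = [
    "TitrationTruth",
    "ThermoTruth",
    "SyncBandTruth",
    "simulate_titration_series",
    "simulate_ka_by_temperature",
    "simulate_synchronous_pair",
    "simulate_dose_response",
    "simulate_eem",
]


@dataclass(frozen=True)
class TitrationTruth:
    """Generative parameters for one quenching titration.

    ``p_ka``/``n`` parameterize the static-quenching law; the emission band
    is Gaussian with the given center/width and an optional linear-in-[Q]
    center drift totalling ``peak_drift_nm`` at the top of the ladder.
    ``a_ex_schedule``/``a_em_schedule`` (per concentration) attenuate the
    clean series so that inner-filter correction recovers it exactly.
    """

    p_ka: float
    n: float
    f0_peak_au: float = 650.0
    peak_center_nm: float = 338.0
    peak_width_nm: float = 25.0
    peak_drift_nm: float = 0.0
    conc_ladder_M: tuple[float, ...] = (0.0, 4e-6, 8e-6, 1.2e-5, 1.6e-5, 2.0e-5)
    a_ex_schedule: tuple[float, ...] | None = None
    a_em_schedule: tuple[float, ...] | None = None
    noise_sd_fraction: float = 0.0
    seed: int = 0
    excitation_nm: float = 280.0
    temperature_K: float = 303.0
    grid_start_nm: float = 300.0
    grid_stop_nm: float = 450.0
    grid_step_nm: float = 1.0
    ife_base: float = math.e

    def __post_init__(self) -> None:
        if not math.isfinite(self.p_ka):
            raise ValidationError("p_ka must be finite")
        if not self.n > 0:
            raise ValidationError("n must be > 0")
        ladder = np.asarray(self.conc_ladder_M, dtype=float)
        if ladder.size < 2 or ladder[0] != 0.0:
            raise ValidationError("concentration ladder must start at 0 and have >= 2 entries")
        if not np.all(np.diff(ladder) > 0):
            raise ValidationError("concentration ladder must be strictly increasing")
        if self.noise_sd_fraction < 0:
            raise ValidationError("noise_sd_fraction must be >= 0")
        for name in ("a_ex_schedule", "a_em_schedule"):
            sched = getattr(self, name)
            if sched is not None and len(sched) != ladder.size:
                raise ValidationError(f"{name} must match the ladder length")


@dataclass(frozen=True)
class ThermoTruth:
    delta_h_J_mol: float
    delta_s_J_molK: float
    temperatures_K: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.temperatures_K) < 2:
            raise ValidationError("need >= 2 temperatures")


@dataclass(frozen=True)
class SyncBandTruth:
    """Band parameters for one synchronous channel: total fractional quench
    and center drift at the top of the shared concentration ladder."""

    delta_lambda_nm: float
    center_nm: float
    width_nm: float = 8.0
    f0_peak_au: float = 500.0
    quench_fraction: float = 0.5
    drift_nm: float = 0.0
    conc_ladder_M: tuple[float, ...] = (0.0, 4e-6, 8e-6, 1.2e-5, 1.6e-5, 2.0e-5)
    grid_start_nm: float = 265.0
    grid_stop_nm: float = 350.0
    grid_step_nm: float = 1.0
    temperature_K: float = 303.0
    noise_sd_fraction: float = 0.0


def _gaussian_band(grid: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-((grid - center) ** 2) / (2.0 * width**2))


def simulate_titration_series(truth: TitrationTruth) -> TitrationSeries:
    """Forward-simulate a quenching titration series.

    For each [Q] > 0 the clean peak intensity is F = F0 / (1 + K_A [Q]^n),
    the exact inversion of lg[(F0-F)/F] = p_ka + n lg[Q]. When absorbance
    schedules are given, the emitted intensities are divided by
    base^((a_ex+a_em)/2) so that inner-filter correction restores the
    clean values.
    """
    ladder = np.asarray(truth.conc_ladder_M, dtype=float)
    grid = np.arange(truth.grid_start_nm, truth.grid_stop_nm + truth.grid_step_nm / 2, truth.grid_step_nm)
    k_a = 10.0**truth.p_ka
    q_max = ladder[-1]
    rng = np.random.default_rng(truth.seed)
    spectra = []
    for i, q in enumerate(ladder):
        f_peak = truth.f0_peak_au if q == 0 else truth.f0_peak_au / (1.0 + k_a * q**truth.n)
        center = truth.peak_center_nm + truth.peak_drift_nm * (q / q_max)
        inten = _gaussian_band(grid, center, truth.peak_width_nm, f_peak)
        a_ex = None if truth.a_ex_schedule is None else float(truth.a_ex_schedule[i])
        a_em = None if truth.a_em_schedule is None else float(truth.a_em_schedule[i])
        if a_ex is not None and a_em is not None:
            inten = inten / truth.ife_base ** ((a_ex + a_em) / 2.0)
        if truth.noise_sd_fraction > 0:
            inten = inten + rng.normal(0.0, truth.noise_sd_fraction * truth.f0_peak_au, size=inten.size)
            inten = np.clip(inten, 0.0, None)
        spectra.append(
            EmissionSpectrum(
                wavelengths_nm=grid,
                intensities_au=inten,
                excitation_nm=truth.excitation_nm,
                temperature_K=truth.temperature_K,
                quencher_conc_M=float(q),
                a_ex=a_ex,
                a_em=a_em,
            )
        )
    return TitrationSeries(spectra=tuple(spectra))


def simulate_ka_by_temperature(truth: ThermoTruth) -> dict[float, float]:
    """k_a(T) = exp(-dH/(R T) + dS/R), exactly."""
    out = {}
    for T in truth.temperatures_K:
        if not T > 0:
            raise ValidationError("temperatures must be > 0 K")
        out[float(T)] = math.exp(
            -truth.delta_h_J_mol / (GAS_CONSTANT_J_MOLK * T) + truth.delta_s_J_molK / GAS_CONSTANT_J_MOLK
        )
    return out


def _simulate_sync_series(truth: SyncBandTruth, rng: np.random.Generator) -> list[SynchronousSpectrum]:
    ladder = np.asarray(truth.conc_ladder_M, dtype=float)
    grid = np.arange(truth.grid_start_nm, truth.grid_stop_nm + truth.grid_step_nm / 2, truth.grid_step_nm)
    q_max = ladder[-1]
    series = []
    for q in ladder:
        frac = truth.quench_fraction * (q / q_max)
        height = truth.f0_peak_au * (1.0 - frac)
        center = truth.center_nm + truth.drift_nm * (q / q_max)
        inten = _gaussian_band(grid, center, truth.width_nm, height)
        if truth.noise_sd_fraction > 0:
            inten = np.clip(
                inten + rng.normal(0.0, truth.noise_sd_fraction * truth.f0_peak_au, size=inten.size),
                0.0,
                None,
            )
        series.append(
            SynchronousSpectrum(
                excitation_nm=grid,
                intensities_au=inten,
                delta_lambda_nm=truth.delta_lambda_nm,
                quencher_conc_M=float(q),
                temperature_K=truth.temperature_K,
            )
        )
    return series


def simulate_synchronous_pair(
    truth15: SyncBandTruth,
    truth60: SyncBandTruth,
    seed: int = 0,
) -> tuple[list[SynchronousSpectrum], list[SynchronousSpectrum]]:
    """Generate the Δλ=15 and Δλ=60 channels over a shared ladder."""
    if tuple(truth15.conc_ladder_M) != tuple(truth60.conc_ladder_M):
        raise ValidationError("the two channels must share the concentration ladder")
    rng = np.random.default_rng(seed)
    return _simulate_sync_series(truth15, rng), _simulate_sync_series(truth60, rng)


def simulate_dose_response(
    ic50: float,
    hill: float = 1.5,
    bottom: float = 0.0,
    top: float = 100.0,
    conc_ladder: Sequence[float] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100),
    noise_sd_pct: float = 0.0,
    seed: int = 0,
) -> DoseResponseTable:
    """Forward 4PL dose-response: a0 = 1.0, a1 = a0 (1 - S/100) + noise."""
    if not ic50 > 0:
        raise ValidationError("ic50 must be > 0")
    conc = np.asarray(conc_ladder, dtype=float)
    if conc.size < 1 or np.any(conc <= 0) or not np.all(np.diff(conc) > 0):
        raise ValidationError("concentration ladder must be positive and strictly increasing")
    s = four_parameter_logistic(conc, bottom, top, ic50, hill)
    a0 = np.ones_like(conc)
    a1 = a0 * (1.0 - s / 100.0)
    if noise_sd_pct > 0:
        rng = np.random.default_rng(seed)
        a1 = a1 + rng.normal(0.0, noise_sd_pct / 100.0, size=a1.size)
    a1 = np.clip(a1, 0.0, None)
    return DoseResponseTable(conc_ug_ml=conc, a0=a0, a1=a1)


def simulate_eem(
    peaks: Sequence[tuple[float, float, float]] = ((280.0, 338.0, 1000.0), (226.0, 338.0, 700.0)),
    excitation_grid_nm: np.ndarray | None = None,
    emission_grid_nm: np.ndarray | None = None,
    width_nm: float = 12.0,
    quencher_conc_M: float = 0.0,
    noise_sd_au: float = 0.0,
    seed: int = 0,
) -> EEM:
    """EEM built from separable Gaussian peaks at (excitation, emission, height)."""
    ex = np.arange(220.0, 301.0, 2.0) if excitation_grid_nm is None else np.asarray(excitation_grid_nm, float)
    em = np.arange(300.0, 451.0, 2.0) if emission_grid_nm is None else np.asarray(emission_grid_nm, float)
    mat = np.zeros((ex.size, em.size))
    for ex0, em0, height in peaks:
        mat += height * np.outer(
            np.exp(-((ex - ex0) ** 2) / (2.0 * width_nm**2)),
            np.exp(-((em - em0) ** 2) / (2.0 * width_nm**2)),
        )
    if noise_sd_au > 0:
        rng = np.random.default_rng(seed)
        mat = np.clip(mat + rng.normal(0.0, noise_sd_au, size=mat.shape), 0.0, None)
    return EEM(excitation_grid_nm=ex, emission_grid_nm=em, intensity_matrix=mat, quencher_conc_M=quencher_conc_M)
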