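"""Spectral preprocessing: inner-filter correction, peak location and
shift tracking, synchronous residue comparison, and EEM peak picking."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.signal import savgol_filter

from .datamodel import EEM, EmissionSpectrum, SynchronousSpectrum, TitrationSeries
from .errors import ValidationError

__all__ = [
    "PeakCall",
    "ShiftResult",
    "EEMPeak",
    "ResidueComparison",
    "correct_inner_filter",
    "locate_peak",
    "peak_shift_series",
    "residue_quench_comparison",
    "find_eem_peaks",
]

SpectrumLike = Union[EmissionSpectrum, SynchronousSpectrum]


@dataclass(frozen=True)
class PeakCall:
    """Location and height of a spectrum's maximum within a search window."""

    peak_nm: float
    peak_intensity_au: float
    window_nm: tuple[float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class ShiftResult:
    """Peak displacement between the first and last spectra of a series.

    ``shift_nm`` = end - start; negative values are blue shifts.
    """

    start_nm: float
    end_nm: float
    shift_nm: float
    direction: str  # "blue" | "red" | "none"
    degenerate: bool = False


@dataclass(frozen=True)
class EEMPeak:
    excitation_nm: float
    emission_nm: float
    intensity_au: float
    label: str = ""


@dataclass(frozen=True)
class ResidueComparison:
    """Fractional peak-intensity decreases at Δλ=15 vs Δλ=60 and the
    inferred binding-site proximity label."""

    fraction_15: float
    fraction_60: float
    label: str  # "tryptophan-proximal" | "tyrosine-proximal" | "indeterminate"


def correct_inner_filter(spectrum: EmissionSpectrum, base: float = math.e) -> EmissionSpectrum:
    """Multiply intensities by ``base**((a_ex + a_em)/2)``.

    The correction undoes attenuation of excitation and emission light by
    sample absorbance; with both absorbances zero it is the identity.
    """
    if spectrum.a_ex is None or spectrum.a_em is None:
        raise ValidationError("inner-filter correction requires a_ex and a_em")
    factor = base ** ((spectrum.a_ex + spectrum.a_em) / 2.0)
    return spectrum.with_intensities(spectrum.intensities_au * factor, ife_corrected=True)


def _grid_and_intensities(spectrum: SpectrumLike) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(spectrum, SynchronousSpectrum):
        return spectrum.excitation_nm, spectrum.intensities_au
    return spectrum.wavelengths_nm, spectrum.intensities_au


def locate_peak(
    spectrum: SpectrumLike,
    window_nm: tuple[float, float] | None = None,
    smooth: int | None = None,
) -> PeakCall:
    """Find the grid wavelength of maximum intensity.

    ``smooth``, if given, is the odd length of a centered quadratic
    (Savitzky-Golay) smoothing window applied before the argmax; the
    reported intensity is always the raw value at the chosen wavelength.
    Ties break toward the lowest wavelength.
    """
    grid, inten = _grid_and_intensities(spectrum)
    if window_nm is None:
        window_nm = (float(grid[0]), float(grid[-1]))
    lo, hi = window_nm
    mask = (grid >= lo) & (grid <= hi)
    if not mask.any():
        raise ValidationError("empty search window")
    sub_grid = grid[mask]
    sub_inten = inten[mask]
    if sub_grid.size < 3:
        raise ValidationError("need >= 3 points in the search window")

    if np.all(sub_inten == 0):
        return PeakCall(
            peak_nm=float(sub_grid[0]),
            peak_intensity_au=0.0,
            window_nm=(float(lo), float(hi)),
            degenerate=True,
        )

    scored = sub_inten
    if smooth is not None:
        if smooth % 2 == 0 or smooth < 3:
            raise ValidationError("smooth must be an odd integer >= 3")
        wl = smooth
        if wl > sub_inten.size:
            wl = sub_inten.size if sub_inten.size % 2 == 1 else sub_inten.size - 1
        scored = savgol_filter(sub_inten, window_length=wl, polyorder=2)
    idx = int(np.argmax(scored))  # argmax returns the first (lowest-wavelength) tie
    return PeakCall(
        peak_nm=float(sub_grid[idx]),
        peak_intensity_au=float(sub_inten[idx]),
        window_nm=(float(lo), float(hi)),
    )


def _ordered_spectra(series: TitrationSeries | Sequence[SpectrumLike]) -> list[SpectrumLike]:
    spectra = list(series.spectra) if isinstance(series, TitrationSeries) else list(series)
    if len(spectra) < 2:
        raise ValidationError("need >= 2 spectra to measure a shift")
    return sorted(spectra, key=lambda s: s.quencher_conc_M)


def peak_shift_series(
    series: TitrationSeries | Sequence[SpectrumLike],
    window_nm: tuple[float, float] | None = None,
    smooth: int | None = None,
) -> ShiftResult:
    """Shift of the peak between the lowest- and highest-concentration spectra."""
    spectra = _ordered_spectra(series)
    start = locate_peak(spectra[0], window_nm=window_nm, smooth=smooth)
    end = locate_peak(spectra[-1], window_nm=window_nm, smooth=smooth)
    shift = end.peak_nm - start.peak_nm
    direction = "none" if shift == 0 else ("blue" if shift < 0 else "red")
    return ShiftResult(
        start_nm=start.peak_nm,
        end_nm=end.peak_nm,
        shift_nm=shift,
        direction=direction,
        degenerate=start.degenerate or end.degenerate,
    )


def residue_quench_comparison(
    series15: Sequence[SynchronousSpectrum],
    series60: Sequence[SynchronousSpectrum],
    rel_tol: float = 1e-9,
) -> ResidueComparison:
    """Compare fractional peak-intensity decreases between the Δλ=15 (tyrosine)
    and Δλ=60 (tryptophan) channels.

    A strictly larger decrease in the Δλ=60 channel labels the binding site
    tryptophan-proximal; strictly smaller, tyrosine-proximal; equal within
    ``rel_tol``, indeterminate.
    """
    s15 = _ordered_spectra(series15)
    s60 = _ordered_spectra(series60)
    ladder15 = [s.quencher_conc_M for s in s15]
    ladder60 = [s.quencher_conc_M for s in s60]
    if ladder15 != ladder60:
        raise ValidationError("concentration ladders of the two channels do not match")

    def fraction(spectra: list[SynchronousSpectrum]) -> float:
        f0 = locate_peak(spectra[0]).peak_intensity_au
        f_last = locate_peak(spectra[-1]).peak_intensity_au
        if f0 == 0:
            raise ValidationError("zero-concentration peak intensity is 0")
        return 1.0 - f_last / f0

    f15 = fraction(s15)
    f60 = fraction(s60)
    scale = max(abs(f15), abs(f60), 1e-300)
    if abs(f60 - f15) <= rel_tol * scale:
        label = "indeterminate"
    elif f60 > f15:
        label = "tryptophan-proximal"
    else:
        label = "tyrosine-proximal"
    return ResidueComparison(fraction_15=f15, fraction_60=f60, label=label)


def scatter_mask(eem: EEM, scatter_halfwidth_nm: float = 15.0) -> np.ndarray:
    """Boolean mask of first- and second-order Rayleigh scatter ridges."""
    ex = eem.excitation_grid_nm[:, None]
    em = eem.emission_grid_nm[None, :]
    first = np.abs(em - ex) < scatter_halfwidth_nm
    second = np.abs(em - 2.0 * ex) < scatter_halfwidth_nm
    return first | second


def find_eem_peaks(
    eem: EEM,
    min_prominence: float = 0.05,
    scatter_halfwidth_nm: float = 15.0,
) -> list[EEMPeak]:
    """Local maxima (8-neighborhood) of the EEM outside scatter ridges.

    Intensities inside the Rayleigh masks are treated as unknown: they are
    zeroed before peak picking (so values there can never influence the
    result) and a candidate peak must have its entire 8-neighborhood
    outside the masks, which suppresses artifact maxima hugging the mask
    boundary. Peaks weaker than ``min_prominence`` times the unmasked
    global maximum are dropped. Returned sorted by descending intensity.
    """
    mask = scatter_mask(eem, scatter_halfwidth_nm)
    if mask.all():
        raise ValidationError("scatter mask covers the entire grid")
    work = np.where(mask, 0.0, eem.intensity_matrix)
    global_max = work.max()
    if global_max <= 0:
        return []
    local_max = maximum_filter(work, size=3, mode="constant", cval=-np.inf)
    near_mask = maximum_filter(mask, size=3, mode="constant", cval=False)
    is_peak = (work == local_max) & ~near_mask & (work >= min_prominence * global_max) & (work > 0)
    peaks = [
        EEMPeak(
            excitation_nm=float(eem.excitation_grid_nm[i]),
            emission_nm=float(eem.emission_grid_nm[j]),
            intensity_au=float(eem.intensity_matrix[i, j]),
        )
        for i, j in zip(*np.nonzero(is_peak))
    ]
    peaks.sort(key=lambda p: (-p.intensity_au, p.excitation_nm, p.emission_nm))
    return [
        EEMPeak(p.excitation_nm, p.emission_nm, p.intensity_au, label=f"peak {k + 1}")
        for k, p in enumerate(peaks)
    ]
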