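import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchbind.datamodel import EEM, EmissionSpectrum, SynchronousSpectrum
from quenchbind.errors import ValidationError
from quenchbind.spectral import (
    correct_inner_filter,
    find_eem_peaks,
    locate_peak,
    peak_shift_series,
    residue_quench_comparison,
    scatter_mask,
)
from quenchbind.synthetic import SyncBandTruth, simulate_eem, simulate_synchronous_pair

from conftest import gaussian_spectrum_arrays


def _spectrum(intensities, wl=None, **kw):
    wl = np.arange(300.0, 300.0 + len(intensities)) if wl is None else wl
    defaults = dict(excitation_nm=280.0, temperature_K=303.0, quencher_conc_M=0.0)
    defaults.update(kw)
    return EmissionSpectrum(wavelengths_nm=wl, intensities_au=np.asarray(intensities, float), **defaults)


class TestCorrectInnerFilter:
    def test_zero_absorbance_is_identity(self):
        s = _spectrum([1.0, 2.0, 3.0], a_ex=0.0, a_em=0.0)
        out = correct_inner_filter(s)
        np.testing.assert_array_equal(out.intensities_au, s.intensities_au)
        assert out.ife_corrected

    def test_closed_form_value(self):
        # 100 * e^((0.1+0.3)/2) = 100 * e^0.2
        s = _spectrum([100.0, 100.0], a_ex=0.1, a_em=0.3)
        out = correct_inner_filter(s)
        assert out.intensities_au[0] == pytest.approx(100.0 * math.exp(0.2), rel=1e-12)
        assert out.intensities_au[0] == pytest.approx(122.140, abs=5e-4)

    def test_sum_two_gives_factor_e(self):
        s = _spectrum([1.0, 1.0], a_ex=1.5, a_em=0.5)
        out = correct_inner_filter(s)
        np.testing.assert_allclose(out.intensities_au, math.e, rtol=1e-15)

    def test_base_ten_option(self):
        s = _spectrum([1.0, 1.0], a_ex=0.5, a_em=0.5)
        out = correct_inner_filter(s, base=10.0)
        np.testing.assert_allclose(out.intensities_au, 10.0**0.5, rtol=1e-15)

    def test_missing_absorbance_errors(self):
        with pytest.raises(ValidationError):
            correct_inner_filter(_spectrum([1.0, 2.0]))

    @given(c=st.floats(min_value=1e-3, max_value=1e3), a=st.floats(min_value=0, max_value=2))
    @settings(max_examples=50, deadline=None)
    def test_multiplicative_property(self, c, a):
        base = _spectrum([1.0, 2.0, 3.0], a_ex=a, a_em=a / 2)
        scaled = base.with_intensities(base.intensities_au * c)
        np.testing.assert_allclose(
            correct_inner_filter(scaled).intensities_au,
            correct_inner_filter(base).intensities_au * c,
            rtol=1e-12,
        )

    def test_round_trip_exact(self):
        s = _spectrum([5.0, 7.0, 11.0], a_ex=0.2, a_em=0.4)
        out = correct_inner_filter(s)
        recovered = out.intensities_au / math.e ** ((0.2 + 0.4) / 2)
        np.testing.assert_allclose(recovered, s.intensities_au, rtol=1e-15)


class TestLocatePeak:
    def test_gaussian_center(self):
        wl, inten = gaussian_spectrum_arrays(center=338.0)
        call = locate_peak(_spectrum(inten, wl=wl))
        assert call.peak_nm == 338.0
        assert call.peak_intensity_au == pytest.approx(100.0)

    def test_tie_breaks_to_lowest_wavelength(self):
        wl = np.arange(300.0, 350.0)
        inten = np.zeros_like(wl)
        inten[wl == 330.0] = 5.0
        inten[wl == 340.0] = 5.0
        call = locate_peak(_spectrum(inten, wl=wl))
        assert call.peak_nm == 330.0

    def test_all_zero_degenerate(self):
        call = locate_peak(_spectrum(np.zeros(10)))
        assert call.degenerate
        assert call.peak_nm == 300.0
        assert call.peak_intensity_au == 0.0

    def test_window_restriction(self):
        wl, inten = gaussian_spectrum_arrays(center=338.0)
        call = locate_peak(_spectrum(inten, wl=wl), window_nm=(400.0, 450.0))
        assert 400.0 <= call.peak_nm <= 450.0

    def test_empty_window_errors(self):
        wl, inten = gaussian_spectrum_arrays()
        with pytest.raises(ValidationError):
            locate_peak(_spectrum(inten, wl=wl), window_nm=(500.0, 600.0))

    def test_scale_invariance(self):
        wl, inten = gaussian_spectrum_arrays(center=345.0)
        a = locate_peak(_spectrum(inten, wl=wl))
        b = locate_peak(_spectrum(inten * 7.3, wl=wl))
        assert a.peak_nm == b.peak_nm

    def test_noisy_peak_monte_carlo(self):
        # Independent oracle: with sigma = 1% of height and 7-point quadratic
        # smoothing, the argmax should fall within +-1 nm of 338 nearly always.
        wl, clean = gaussian_spectrum_arrays(center=338.0, height=100.0, width=10.0)
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            noisy = np.clip(clean + rng.normal(0, 1.0, clean.size), 0, None)
            call = locate_peak(_spectrum(noisy, wl=wl), smooth=7)
            hits += abs(call.peak_nm - 338.0) <= 1.0
        assert hits >= 99

    def test_reported_intensity_is_unsmoothed(self):
        wl, clean = gaussian_spectrum_arrays(center=338.0)
        call = locate_peak(_spectrum(clean, wl=wl), smooth=7)
        idx = np.where(wl == call.peak_nm)[0][0]
        assert call.peak_intensity_au == clean[idx]


class TestPeakShiftSeries:
    def _series(self, centers, concs):
        spectra = []
        for c, q in zip(centers, concs):
            wl, inten = gaussian_spectrum_arrays(center=c)
            spectra.append(_spectrum(inten, wl=wl, quencher_conc_M=q))
        return spectra

    def test_blue_shift_338_to_336(self):
        spectra = self._series([338.0, 337.0, 336.0], [0.0, 1e-6, 2e-6])
        result = peak_shift_series(spectra)
        assert result.shift_nm == -2.0
        assert result.direction == "blue"
        assert (result.start_nm, result.end_nm) == (338.0, 336.0)

    def test_no_drift(self):
        spectra = self._series([338.0, 338.0], [0.0, 1e-6])
        result = peak_shift_series(spectra)
        assert result.shift_nm == 0.0
        assert result.direction == "none"

    def test_red_shift(self):
        spectra = self._series([338.0, 341.0], [0.0, 1e-6])
        result = peak_shift_series(spectra)
        assert result.shift_nm == 3.0
        assert result.direction == "red"

    def test_synchronous_293_to_291(self):
        grid = np.arange(265.0, 351.0)
        spectra = [
            SynchronousSpectrum(
                excitation_nm=grid,
                intensities_au=100 * np.exp(-((grid - c) ** 2) / 50),
                delta_lambda_nm=15.0,
                quencher_conc_M=q,
                temperature_K=303.0,
            )
            for c, q in [(293.0, 0.0), (292.0, 1e-6), (291.0, 2e-6)]
        ]
        result = peak_shift_series(spectra)
        assert result.shift_nm == -2.0
        assert result.direction == "blue"

    def test_degenerate_flag_propagates(self):
        spectra = [
            _spectrum(np.zeros(10), quencher_conc_M=0.0),
            _spectrum(np.ones(10), quencher_conc_M=1e-6),
        ]
        assert peak_shift_series(spectra).degenerate


class TestResidueComparison:
    def _sync(self, heights, delta, concs):
        grid = np.arange(265.0, 351.0)
        return [
            SynchronousSpectrum(
                excitation_nm=grid,
                intensities_au=h * np.exp(-((grid - 300.0) ** 2) / 50),
                delta_lambda_nm=delta,
                quencher_conc_M=q,
                temperature_K=303.0,
            )
            for h, q in zip(heights, concs)
        ]

    def test_tryptophan_proximal(self):
        concs = [0.0, 1e-6]
        s15 = self._sync([100.0, 60.0], 15.0, concs)  # fraction 0.4
        s60 = self._sync([100.0, 40.0], 60.0, concs)  # fraction 0.6
        cmp_ = residue_quench_comparison(s15, s60)
        assert cmp_.fraction_15 == pytest.approx(0.4)
        assert cmp_.fraction_60 == pytest.approx(0.6)
        assert cmp_.label == "tryptophan-proximal"

    def test_equal_fractions_indeterminate(self):
        concs = [0.0, 1e-6]
        s15 = self._sync([100.0, 50.0], 15.0, concs)
        s60 = self._sync([100.0, 50.0], 60.0, concs)
        assert residue_quench_comparison(s15, s60).label == "indeterminate"

    def test_tyrosine_proximal(self):
        concs = [0.0, 1e-6]
        s15 = self._sync([100.0, 30.0], 15.0, concs)
        s60 = self._sync([100.0, 60.0], 60.0, concs)
        assert residue_quench_comparison(s15, s60).label == "tyrosine-proximal"

    def test_mismatched_ladders_error(self):
        s15 = self._sync([100.0, 30.0], 15.0, [0.0, 1e-6])
        s60 = self._sync([100.0, 60.0], 60.0, [0.0, 2e-6])
        with pytest.raises(ValidationError):
            residue_quench_comparison(s15, s60)

    def test_generator_consistency(self, sync_truth_pair):
        t15, t60 = sync_truth_pair
        s15, s60 = simulate_synchronous_pair(t15, t60, seed=0)
        cmp_ = residue_quench_comparison(s15, s60)
        assert cmp_.label == "tryptophan-proximal"
        assert cmp_.fraction_60 == pytest.approx(0.6, rel=1e-9)
        assert cmp_.fraction_15 == pytest.approx(0.4, rel=1e-9)


class TestFindEEMPeaks:
    def test_recovers_planted_peaks(self):
        eem = simulate_eem()
        peaks = find_eem_peaks(eem)
        coords = {(p.excitation_nm, p.emission_nm) for p in peaks}
        assert (280.0, 338.0) in coords
        assert (226.0, 338.0) in coords

    def test_sorted_by_descending_intensity(self):
        peaks = find_eem_peaks(simulate_eem())
        intens = [p.intensity_au for p in peaks]
        assert intens == sorted(intens, reverse=True)
        assert peaks[0].label == "peak 1"

    def test_flat_zero_matrix(self):
        eem = EEM(
            excitation_grid_nm=np.arange(220.0, 301.0, 2.0),
            emission_grid_nm=np.arange(300.0, 451.0, 2.0),
            intensity_matrix=np.zeros((41, 76)),
        )
        assert find_eem_peaks(eem) == []

    def test_peak_on_diagonal_masked(self):
        ex = np.arange(260.0, 321.0, 2.0)
        em = np.arange(260.0, 321.0, 2.0)
        mat = 100 * np.outer(
            np.exp(-((ex - 290.0) ** 2) / 50), np.exp(-((em - 290.0) ** 2) / 50)
        )
        eem = EEM(excitation_grid_nm=ex, emission_grid_nm=em, intensity_matrix=mat)
        assert find_eem_peaks(eem) == []

    def test_masked_region_values_irrelevant(self):
        eem = simulate_eem()
        mask = scatter_mask(eem, 15.0)
        perturbed = eem.intensity_matrix.copy()
        perturbed[mask] = 12345.0
        eem2 = EEM(
            excitation_grid_nm=eem.excitation_grid_nm,
            emission_grid_nm=eem.emission_grid_nm,
            intensity_matrix=perturbed,
        )
        assert find_eem_peaks(eem) == find_eem_peaks(eem2)

    def test_full_mask_errors(self):
        ex = np.array([300.0, 302.0])
        em = np.array([300.0, 302.0])
        eem = EEM(excitation_grid_nm=ex, emission_grid_nm=em, intensity_matrix=np.ones((2, 2)))
        with pytest.raises(ValidationError):
            find_eem_peaks(eem, scatter_halfwidth_nm=1000.0)
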