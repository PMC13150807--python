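"""Shift-model fitting, derivative enhancement, anchoring and assignment."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import edtaqc as eq
from edtaqc.errors import (AnchorNotFoundError, DegenerateFitError,
                           SpectrumDomainError)
from edtaqc.lineshapes import VoigtPeak, voigt_profile
from edtaqc.shifts import (STATUS_ASSIGNED, STATUS_BELOW_DETECTION,
                           STATUS_FALLBACK, assign_all_species, assign_peak,
                           derivative_enhance, find_glucose_anchor,
                           fit_shift_model)
from edtaqc.spectrum import Spectrum1D

from conftest import LW_PPM


def _flat(n=512):
    return Spectrum1D(np.linspace(10, 0, n), np.full(n, 3.0), 600.13)


def _spectrum_with_peaks(peaks, n=20000, lo=-1.0, hi=15.0, noise=0.0, seed=0):
    ppm = np.linspace(hi, lo, n)
    y = np.zeros(n)
    for pk in peaks:
        y += voigt_profile(ppm, pk)
    if noise:
        y += np.random.default_rng(seed).normal(0, noise, n)
    return Spectrum1D(ppm, y, 600.13)


class TestDerivativeEnhance:
    def test_flat_spectrum_enhances_to_zero(self):
        assert np.all(derivative_enhance(_flat()) == 0.0)

    def test_sharp_peak_enhanced_over_broad(self):
        # equal heights, widths 1.5 vs 50 Hz: Lorentzian derivative maxima
        # scale as height/width, so the ratio must reach at least 10
        narrow = VoigtPeak(6.0, 0.0, 0.75 / 600.13, np.pi * 0.75 / 600.13)
        broad = VoigtPeak(3.0, 0.0, 25.0 / 600.13, np.pi * 25.0 / 600.13)
        sp = _spectrum_with_peaks([narrow, broad], n=60000)
        enh = derivative_enhance(sp)
        near = lambda c: enh[sp.region_slice(c - 0.2, c + 0.2)].max()
        assert near(6.0) / near(3.0) >= 10.0

    def test_enhanced_apexes_match_original_maxima(self):
        pk = VoigtPeak(4.0, 0.001, 0.001, 1.0)
        sp = _spectrum_with_peaks([pk])
        enh = derivative_enhance(sp)
        i_orig = int(np.argmax(sp.intensity))
        # the enhanced trace dips to a local minimum at the apex, bracketed
        # by its two maxima: the bracket midpoint falls on the apex
        i_left = int(np.argmax(enh[:i_orig]))
        i_right = i_orig + int(np.argmax(enh[i_orig:]))
        assert abs((i_left + i_right) / 2 - i_orig) <= 1.0


class TestGlucoseAnchor:
    def test_finds_synthetic_doublet(self, sample):
        sp, truth = sample
        anchor = find_glucose_anchor(sp)
        assert abs(anchor - truth.centers["glucose_anomeric"]) < 0.5 * LW_PPM

    def test_singlet_only_region_raises(self):
        pk = VoigtPeak(5.25, 0.0, LW_PPM / 2, 1.0)
        sp = _spectrum_with_peaks([pk], noise=0.001)
        with pytest.raises(AnchorNotFoundError):
            find_glucose_anchor(sp, noise_sigma=0.001)

    def test_rejects_pair_with_wrong_separation(self):
        j_ppm = 3.8 / 600.13
        good = [VoigtPeak(5.30 - j_ppm / 2, 0.0, LW_PPM / 2, 0.5),
                VoigtPeak(5.30 + j_ppm / 2, 0.0, LW_PPM / 2, 0.5)]
        # a more intense pair at twice the coupling must not win
        bad = [VoigtPeak(5.15 - j_ppm, 0.0, LW_PPM / 2, 2.0),
               VoigtPeak(5.15 + j_ppm, 0.0, LW_PPM / 2, 2.0)]
        sp = _spectrum_with_peaks(good + bad, noise=0.001)
        anchor = find_glucose_anchor(sp, noise_sigma=0.001)
        assert anchor == pytest.approx(5.30, abs=0.5 * LW_PPM)


class TestFitShiftModel:
    def test_collinear_points_perfect_fit(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = fit_shift_model(x, 0.5 * x + 2.0)
        assert m.r_squared == pytest.approx(1.0)
        assert m.rrmse == pytest.approx(0.0, abs=1e-12)
        assert m.slope == pytest.approx(0.5)

    def test_noisy_identity_recovered(self):
        rng = np.random.default_rng(0)
        x = np.linspace(5.20, 5.26, 100)
        y = x + rng.normal(0, 0.001, 100)
        m = fit_shift_model(x, y)
        # 95% CI of the slope contains 1
        se = m.rrmse / (np.std(x) * np.sqrt(len(x)))
        assert abs(m.slope - 1.0) < 2.0 * se
        assert m.rrmse == pytest.approx(0.001, rel=0.3)

    def test_degeneracy_boundary(self):
        # duplicate x values are fine as long as x is not constant
        m = fit_shift_model([1.0, 1.0, 2.0], [0.9, 1.1, 2.0])
        assert np.isfinite(m.slope)
        with pytest.raises(DegenerateFitError):
            fit_shift_model([1.0, 1.0, 1.0], [0.9, 1.1, 2.0])
        with pytest.raises(DegenerateFitError):
            fit_shift_model([1.0, 2.0], [1.0, 2.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 20)
        x = rng.normal(3.0, 0.5, n)
        if np.ptp(x) == 0:  # pragma: no cover - essentially impossible
            return
        y = rng.normal(0.0, 1.0, n)
        m = fit_shift_model(x, y)
        coeffs, *_ = np.linalg.lstsq(np.c_[x, np.ones(n)], y, rcond=None)
        assert m.slope == pytest.approx(coeffs[0], abs=1e-10)
        assert m.intercept == pytest.approx(coeffs[1], abs=1e-10)


class TestAssignPeak:
    def _one_peak(self, center=4.0, noise=0.002, seed=1):
        pk = VoigtPeak(center, 0.0, LW_PPM / 2, 1.0)
        return _spectrum_with_peaks([pk], noise=noise, seed=seed)

    def test_peak_at_prediction_returns_apex(self):
        sp = self._one_peak(noise=0.0)
        delta, status = assign_peak(sp, 4.0, 2.0, LW_PPM, 1e-3)
        assert status == STATUS_ASSIGNED
        assert delta == pytest.approx(4.0, abs=0.1 * LW_PPM)

    def test_offset_peak_recovered_within_window(self):
        sp = self._one_peak(center=4.0 + 0.8 * LW_PPM, noise=0.0)
        delta, status = assign_peak(sp, 4.0, 2.0, LW_PPM, 1e-3)
        assert status == STATUS_ASSIGNED
        assert delta == pytest.approx(4.0 + 0.8 * LW_PPM, abs=sp.dppm)

    def test_empty_window_below_detection(self):
        sp = self._one_peak(noise=0.002)
        delta, status = assign_peak(sp, 7.0, 2.0, LW_PPM, 0.002)
        assert delta is None and status == STATUS_BELOW_DETECTION

    def test_window_outside_axis_rejected(self):
        sp = self._one_peak()
        with pytest.raises(SpectrumDomainError):
            assign_peak(sp, 15.5, 2.0, LW_PPM, 0.002)

    def test_monotone_window_property(self):
        # any peak assignable with window w is assignable with w' > w
        sp = self._one_peak(center=4.0 + 0.6 * LW_PPM, noise=0.002)
        for w in (1.5, 2.0, 2.5, 3.0):
            delta, status = assign_peak(sp, 4.0, w, LW_PPM, 0.002)
            if w == 1.5:
                assert status == STATUS_ASSIGNED
            assert status == STATUS_ASSIGNED


class TestAssignAllSpecies:
    def test_all_species_within_two_line_widths(self, sample, chain):
        sp, truth = sample
        anchor = find_glucose_anchor(sp)
        result = assign_all_species(sp, chain, anchor)
        lw = result.line_width_ppm
        for species, rec in result.records.items():
            assert rec.status in (STATUS_ASSIGNED, STATUS_FALLBACK)
            assert abs(rec.assigned - truth.centers[species]) < 2 * lw

    def test_zero_zinc_flagged_below_detection(self, chain):
        comp = eq.make_composition(ca=1.2, mg=0.45, zn=0.0)
        sp, _ = eq.generate_spectrum(
            eq.GeneratorConfig(concentrations=comp), seed=8)
        result = assign_all_species(sp, chain, find_glucose_anchor(sp))
        assert result.status("zn_edta_singlet") == STATUS_BELOW_DETECTION
        assert result.status("zn_edta_quartet") == STATUS_BELOW_DETECTION
        assert result.status("ca_edta_singlet") == STATUS_ASSIGNED
        assert result.status("mg_edta_singlet") == STATUS_ASSIGNED

    def test_suppressed_ca_singlet_triggers_fallback_chain(self, chain):
        cfg = eq.GeneratorConfig(
            suppress_species=frozenset({"ca_edta_singlet"}))
        sp, truth = eq.generate_spectrum(cfg, seed=9)
        result = assign_all_species(sp, chain, find_glucose_anchor(sp))
        assert result.status("ca_edta_singlet") == STATUS_BELOW_DETECTION
        # Mg's primary model predicts from the Ca singlet; with it missing
        # the glucose-anchored fallback applies, with the 2.5 LW window
        rec = result.records["mg_edta_singlet"]
        assert rec.status == STATUS_FALLBACK
        assert rec.window_lw == pytest.approx(2.5)
        assert abs(rec.assigned - truth.centers["mg_edta_singlet"]) \
            < 2 * result.line_width_ppm

    def test_assignment_anchored_outside_windows(self, sample, chain):
        # perturbing the spectrum far from every search window must not
        # change any assignment
        sp, _ = sample
        anchor = find_glucose_anchor(sp)
        before = assign_all_species(sp, chain, anchor)
        perturbed = sp.copy()
        for c in (0.2, 4.5, 8.0):  # far from all EDTA windows and anchors
            sl = perturbed.region_slice(c - 0.05, c + 0.05)
            bump = voigt_profile(perturbed.ppm_axis[sl],
                                 VoigtPeak(c, 0.0, LW_PPM / 2, 5.0))
            perturbed.intensity[sl] += bump
        after = assign_all_species(perturbed, chain, anchor,
                                   noise_sigma=before.noise_sigma)
        for species in before.records:
            assert after.records[species].assigned == \
                before.records[species].assigned
            assert after.records[species].status == \
                before.records[species].status

    def test_windows_stay_below_two_line_widths(self, sample, chain):
        sp, _ = sample
        result = assign_all_species(sp, chain, find_glucose_anchor(sp))
        for rec in result.records.values():
            if rec.status == STATUS_ASSIGNED:
                assert rec.window_lw < 2.0
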