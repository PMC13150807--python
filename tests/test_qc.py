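"""EDTA signal removal, PCA and feature-correlation QC."""

import numpy as np
import pytest

import edtaqc as eq
from edtaqc.errors import SpectrumDomainError
from edtaqc.qc import (MODE_ALL_EDTA, MODE_FREE_ONLY, chop_regions,
                       feature_correlation, pca_scores, remove_edta_signals)
from edtaqc.spectrum import bin_and_center


@pytest.fixture(scope="module")
def processed(sample, chain, db):
    sp, truth = sample
    assignments, fits = eq.process_sample(sp, chain, db)
    return sp, truth, assignments, fits


def _clean(processed, mode, db):
    sp, truth, assignments, fits = processed
    return remove_edta_signals(
        sp, fits, mode=mode, line_width_ppm=assignments.line_width_ppm,
        noise_sigma=assignments.noise_sigma, templates=db)


class TestRemoveEdtaSignals:
    def test_free_only_keeps_metal_complexes(self, processed, chain, db):
        sp, truth, assignments, fits = processed
        cleaned, report = _clean(processed, MODE_FREE_ONLY, db)
        # the metal-EDTA systems are untouched: refitting them on the
        # cleaned spectrum reproduces their areas within 1%
        from edtaqc.deconv import fit_spin_system
        for species in ("ca_edta_singlet", "mg_edta_singlet",
                        "ca_edta_quartet"):
            refit = fit_spin_system(cleaned, db[species],
                                    fits[species].center,
                                    assignments.line_width_ppm)
            assert refit.integral == pytest.approx(fits[species].integral,
                                                   rel=0.01)

    def test_all_edta_residuals_below_three_sigma(self, processed, db):
        cleaned, report = _clean(processed, MODE_ALL_EDTA, db)
        assert report.max_center_residual_sigma <= 3.0
        assert report.removed_regions  # something was actually removed

    def test_locality_outside_removed_regions(self, processed, db):
        sp = processed[0]
        cleaned, report = _clean(processed, MODE_ALL_EDTA, db)
        mask = np.ones(sp.n_points, dtype=bool)
        for lo, hi in report.removed_regions:
            sl = sp.region_slice(lo, hi)
            mask[sl] = False
        np.testing.assert_array_equal(cleaned.intensity[mask],
                                      sp.intensity[mask])

    def test_cleaning_is_idempotent(self, processed, chain, db):
        sp, truth, assignments, fits = processed
        cleaned, _ = _clean(processed, MODE_ALL_EDTA, db)
        # second pass: the pipeline finds no EDTA signals above 3 sigma,
        # so nothing further changes
        assignments2, fits2 = eq.process_sample(cleaned, chain, db)
        for species in ("free_edta_1", "ca_edta_singlet", "mg_edta_singlet",
                        "zn_edta_singlet"):
            assert fits2[species].status == "below_detection"
        cleaned2, report2 = remove_edta_signals(
            cleaned, fits2, mode=MODE_ALL_EDTA,
            line_width_ppm=assignments.line_width_ppm,
            noise_sigma=assignments.noise_sigma, templates=db)
        np.testing.assert_array_equal(cleaned2.intensity, cleaned.intensity)

    def test_non_edta_integrals_preserved(self, processed, db):
        sp, truth = processed[0], processed[1]
        cleaned, _ = _clean(processed, MODE_ALL_EDTA, db)
        for species in ("lactate_ch3", "alanine_ch3", "glucose_anomeric"):
            c = truth.centers[species]
            sl = sp.region_slice(c - 0.03, c + 0.03)
            before = float(np.sum(sp.intensity[sl]))
            after = float(np.sum(cleaned.intensity[sl]))
            assert after == pytest.approx(before, rel=0.01)

    def test_overlapping_kept_system_forces_subtraction(self, chain):
        # move asparagine onto the Zn-EDTA singlet: removing Zn by region
        # replacement would destroy the kept asparagine signal, so the
        # fitted Zn model is subtracted instead and flagged
        db = eq.default_template_db()
        db["zn_edta_singlet"] = db["zn_edta_singlet"].with_center(2.88)
        cfg = eq.GeneratorConfig(templates=db)
        sp, truth = eq.generate_spectrum(cfg, seed=61)
        chain2 = eq.train_default_chain(n=120, seed=7, config=cfg)
        assignments, fits = eq.process_sample(sp, chain2, db)
        cleaned, report = remove_edta_signals(
            sp, fits, mode=MODE_ALL_EDTA,
            line_width_ppm=assignments.line_width_ppm,
            noise_sigma=assignments.noise_sigma, templates=db)
        assert "zn_edta_singlet" in report.subtracted_species

    def test_chop_zero_fills_regions(self, sample):
        sp, _ = sample
        chopped = chop_regions(sp, [(2.5, 3.7)])
        sl = sp.region_slice(2.5, 3.7)
        assert np.all(chopped.intensity[sl] == 0.0)
        outside = np.ones(sp.n_points, bool)
        outside[sl] = False
        np.testing.assert_array_equal(chopped.intensity[outside],
                                      sp.intensity[outside])


class TestPcaScores:
    def test_explained_variance_bounded_and_ordered(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(12, 30))
        m -= m.mean(axis=0)
        _, _, expl = pca_scores(m, 5)
        assert expl.sum() <= 100.0 + 1e-9
        assert np.all(np.diff(expl) <= 1e-9)

    def test_duplicated_samples_share_scores(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(6, 20))
        m = np.vstack([m, m[2]])
        m -= m.mean(axis=0)
        scores, _, _ = pca_scores(m, 3)
        np.testing.assert_allclose(scores[6], scores[2], atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(5, 4))
        m -= m.mean(axis=0)
        scores, loadings, expl = pca_scores(m, 3)
        # brute-force oracle: eigendecomposition of the covariance
        cov = m.T @ m
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for k in range(3):
            oracle = m @ v[:, k]
            got = scores[:, k]
            sign = np.sign(oracle @ got) or 1.0
            np.testing.assert_allclose(got, sign * oracle, atol=1e-8)
        np.testing.assert_allclose(expl[:3], w[:3] / np.sum(w) * 100,
                                   atol=1e-8)

    def test_k_too_large_rejected(self):
        with pytest.raises(SpectrumDomainError):
            pca_scores(np.zeros((4, 10)), 4)


class TestFeatureCorrelation:
    def test_own_column_correlates_perfectly(self):
        rng = np.random.default_rng(6)
        m = rng.normal(size=(30, 8))
        r, flags = feature_correlation(m, m[:, 5])
        assert r[5] == pytest.approx(1.0)
        assert not flags.any()

    def test_constant_feature_flagged_zero(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(10, 4))
        m[:, 2] = 3.14
        r, flags = feature_correlation(m, m[:, 0])
        assert r[2] == 0.0
        assert flags[2]

    def test_noise_features_below_permutation_null(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(50, 200))
        target = rng.normal(size=50)
        r, _ = feature_correlation(m, target)
        # permutation oracle for the null 99th percentile of max |r|
        null_max = []
        for _ in range(60):
            perm = rng.permutation(target)
            rp, _ = feature_correlation(m, perm)
            null_max.append(np.max(np.abs(rp)))
        assert np.max(np.abs(r)) <= np.percentile(null_max, 99)

    def test_too_few_samples_rejected(self):
        with pytest.raises(SpectrumDomainError):
            feature_correlation(np.zeros((2, 3)), [1.0, 2.0])

    def test_ca_concentration_maps_to_ca_singlet_bins(self, chain, db):
        cohort = eq.generate_cohort(20, seed=62, zn_dropout=0.0)
        matrix, centers = bin_and_center([sp for sp, _ in cohort],
                                         bin_width=0.02, region=(0.5, 5.5))
        target = [t.concentrations["ca"] for _, t in cohort]
        r, _ = feature_correlation(matrix, target)
        best = centers[int(np.argmax(np.abs(r)))]
        # the winning bin lies in the Ca-EDTA singlet neighbourhood
        assert 2.50 <= best <= 2.60
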