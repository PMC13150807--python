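"""Self-contained simulation studies exercising the whole pipeline.

Each study builds its own synthetic inputs (training shift table,
instrument blanks, calibration standards, cohorts), runs the full
assignment -> deconvolution -> quantification chain, and returns summary
statistics. They are used by the validation suite and by the
reproduction script; all randomness derives from one integer seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .deconv import deconvolute_all
from .pipeline import (IONS, add_field_reference, calibrate, generate_blank,
                       generate_standards, process_sample, quantify_sample,
                       train_default_chain)
from .qc import MODE_ALL_EDTA, chop_regions, pca_scores, remove_edta_signals
from .quant import edta_mass_balance, regression_coincidence_test
from .shifts import STATUS_ASSIGNED, STATUS_FALLBACK, assign_all_species
from .spectrum import bin_and_center
from .synth import (GeneratorConfig, generate_cohort, generate_spectrum,
                    make_composition)
from .templates import default_template_db


def _seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def quantification_fidelity_study(seed: int = 42, n_cohort: int = 40,
                                  n_standards: int = 8) -> dict:
    """Estimated vs true Ca/Mg/Zn concentrations on a synthetic cohort.

    Trains the shift models, calibrates on ``n_standards`` standards, runs
    the full pipeline on an ``n_cohort``-sample serum-EDTA cohort spanning
    the physiological ranges, and reports the per-ion coefficient of
    determination (samples with the ion below detection are excluded, as
    they carry no concentration estimate).
    """
    s_train, s_blank, s_std, s_cohort = _seeds(seed, 4)
    db = default_template_db()
    chain = train_default_chain(n=150, seed=s_train)
    blank = generate_blank(600.13, seed=s_blank)
    setup = calibrate(generate_standards(600.13, n_standards, seed=s_std),
                      blank, chain, db)
    cohort = generate_cohort(n_cohort, seed=s_cohort)

    est = {ion: [] for ion in IONS}
    true = {ion: [] for ion in IONS}
    for sp, truth in cohort:
        report, _, _ = quantify_sample(sp, chain, setup, db)
        for ion in IONS:
            c = report.concentration(ion)
            if c is None:
                continue
            est[ion].append(c)
            true[ion].append(truth.concentrations[ion.lower()])

    r2 = {ion: float(stats.linregress(true[ion], est[ion]).rvalue ** 2)
          for ion in IONS}
    return {"r2": r2, "min_r2": min(r2.values()), "n": n_cohort,
            "n_quantified": {ion: len(est[ion]) for ion in IONS}}


def mass_balance_study(seed: int = 42) -> dict:
    """Recover the in-tube total EDTA from one synthetic serum sample.

    The sample's EDTA is partitioned among free EDTA and the Ca/Mg/Zn
    complexes; all four species are deconvoluted and converted to
    concentrations through the per-proton response calibrated on
    standards, then summed.
    """
    s_train, s_blank, s_std, s_sample = _seeds(seed, 4)
    db = default_template_db()
    chain = train_default_chain(n=150, seed=s_train)
    blank = generate_blank(600.13, seed=s_blank)
    setup = calibrate(generate_standards(600.13, 8, seed=s_std), blank,
                      chain, db)

    comp = make_composition(ca=1.20, mg=0.45, zn=0.007)
    sp, truth = generate_spectrum(
        replace(GeneratorConfig(), concentrations=comp), seed=s_sample)
    assignments, fits = process_sample(sp, chain, db)
    pools = edta_mass_balance(fits, setup.reference_for(600.13),
                              setup.s_ref, setup.kappa, db,
                              sigma_f=assignments.noise_sigma)
    return {"pools_mM": pools, "total_mM": pools["total"],
            "true_total_mM": truth.total_edta(), "n": 1}


def assignment_validation_study(seed: int = 42, n: int = 100,
                                n_suppressed: int = 5) -> dict:
    """Fraction of spin systems assigned within two line widths of truth.

    ``n`` full spectra with latent-variable shift covariation are
    assigned through the model chain; additionally ``n_suppressed``
    spectra with the Ca-EDTA singlet suppressed exercise the
    glucose-anchored fallback path for Mg.
    """
    s_train, s_cohort, s_sup = _seeds(seed, 3)
    db = default_template_db()
    chain = train_default_chain(n=150, seed=s_train)

    total = within = 0
    statuses_ok = True
    for sp, truth in generate_cohort(n, seed=s_cohort, zn_dropout=0.0):
        assignments, _ = process_sample(sp, chain, db)
        lw = assignments.line_width_ppm
        for species, rec in assignments.records.items():
            total += 1
            if rec.status not in (STATUS_ASSIGNED, STATUS_FALLBACK):
                statuses_ok = False
                continue
            if abs(rec.assigned - truth.centers[species]) < 2 * lw:
                within += 1

    fallback_ok = 0
    cfg = GeneratorConfig(suppress_species=frozenset({"ca_edta_singlet"}))
    for child in _seeds(s_sup, n_suppressed):
        sp, truth = generate_spectrum(cfg, seed=child)
        assignments, _ = process_sample(sp, chain, db)
        rec = assignments.records["mg_edta_singlet"]
        if (rec.status == STATUS_FALLBACK
                and abs(rec.assigned - truth.centers["mg_edta_singlet"])
                < 2 * assignments.line_width_ppm):
            fallback_ok += 1

    return {"fraction_within_2lw": within / total, "n_assignments": total,
            "all_assigned": statuses_ok, "n": n,
            "fallback_exercised": fallback_ok, "n_suppressed": n_suppressed}


def cross_field_study(seed: int = 42, n_seeds: int = 50,
                      n_compositions: int = 6, n_standards: int = 24) -> dict:
    """Cross-spectrometer harmonization at 500.13 vs 600.13 MHz.

    Per replicate: calibrate at 500.13 MHz, render ``n_compositions``
    identical compositions at both fields, quantify, and per ion run the
    regression-coincidence F-test of both field cohorts (NMR estimate vs
    true concentration) against the fixed 1:1 line at alpha = 0.05.
    Reports per-ion mean relative differences between fields and the
    fraction of non-rejections over all per-ion tests.
    """
    s_train, s_rest = _seeds(seed, 2)
    db = default_template_db()
    chain = train_default_chain(n=150, seed=s_train)
    rep_seeds = _seeds(s_rest, n_seeds)

    reldiff = {ion: [] for ion in IONS}
    tests = rejections = 0
    for rs in rep_seeds:
        s_blank5, s_blank6, s_std, s_val = _seeds(rs, 4)
        blank5 = generate_blank(500.13, seed=s_blank5)
        setup = calibrate(
            generate_standards(500.13, n_standards, seed=s_std), blank5,
            chain, db)
        add_field_reference(setup, generate_blank(600.13, seed=s_blank6), db)

        est = {f: {ion: [] for ion in IONS} for f in (500.13, 600.13)}
        true = {ion: [] for ion in IONS}
        val_seeds = _seeds(s_val, 2 * n_compositions)
        for i in range(n_compositions):
            frac = i / max(n_compositions - 1, 1)
            ca = 1.05 + 0.25 * frac
            mg = 0.35 + 0.15 * frac
            zn = 0.0045 + 0.0045 * frac
            comp = make_composition(ca=ca, mg=mg, zn=zn)
            for ion, v in (("Ca", ca), ("Mg", mg), ("Zn", zn)):
                true[ion].append(v)
            for j, f in enumerate((500.13, 600.13)):
                cfg = replace(GeneratorConfig(), concentrations=comp,
                              field_mhz=f)
                sp, _ = generate_spectrum(cfg, seed=val_seeds[2 * i + j])
                report, _, _ = quantify_sample(sp, chain, setup, db)
                for ion in IONS:
                    est[f][ion].append(report.concentration(ion))
        for ion in IONS:
            c5, c6 = est[500.13][ion], est[600.13][ion]
            reldiff[ion].extend(abs(a - b) / a * 100 for a, b in zip(c5, c6))
            *_, p = regression_coincidence_test(true[ion], c5, true[ion], c6,
                                                reference=(1.0, 0.0))
            tests += 1
            if p < 0.05:
                rejections += 1

    return {
        "mean_rel_diff_pct": {ion: float(np.mean(v))
                              for ion, v in reldiff.items()},
        "coincidence_tests": tests,
        "coincidence_non_rejection_fraction": (tests - rejections) / tests,
        "n": n_seeds,
    }


def cleaning_fidelity_study(seed: int = 42, n: int = 20,
                            bin_region: tuple = (0.5, 5.5)) -> dict:
    """PCA fidelity of automated EDTA removal vs region chopping.

    Three matched cohorts share metabolite concentrations, shift
    covariation, baselines and noise: serum-EDTA, the same samples without
    EDTA, and the EDTA cohort after cleanup (plus the zero-filled
    comparator over the same regions). The summary is the PC1+PC2
    cumulative explained variance of each binned (0.02 ppm,
    mean-centred) matrix.
    """
    s_train, s_cohort = _seeds(seed, 2)
    db = default_template_db()
    chain = train_default_chain(n=150, seed=s_train)

    edta_cohort = generate_cohort(n, seed=s_cohort, zn_dropout=0.0)
    base_cfg = GeneratorConfig()
    free_cohort, cleaned, chopped = [], [], []
    preserved = []
    for sp, truth in edta_cohort:
        comp0 = dict(truth.concentrations,
                     free_edta=0.0, ca=0.0, mg=0.0, zn=0.0)
        sp0, _ = generate_spectrum(
            replace(base_cfg, concentrations=comp0), seed=truth.seed)
        free_cohort.append(sp0)

        assignments, fits = process_sample(sp, chain, db)
        clean_sp, report = remove_edta_signals(
            sp, fits, mode=MODE_ALL_EDTA,
            line_width_ppm=assignments.line_width_ppm,
            noise_sigma=assignments.noise_sigma, templates=db)
        cleaned.append(clean_sp)
        chopped.append(chop_regions(sp, report.removed_regions))

        # non-EDTA metabolite integrals before vs after cleaning
        for species in ("lactate_ch3", "alanine_ch3", "glucose_anomeric"):
            c = truth.centers[species]
            sl = sp.region_slice(c - 0.03, c + 0.03)
            before = float(np.sum(sp.intensity[sl]))
            after = float(np.sum(clean_sp.intensity[sl]))
            preserved.append(abs(after - before) / abs(before))

    def cumvar2(spectra):
        matrix, _ = bin_and_center(spectra, 0.02, region=bin_region)
        _, _, expl = pca_scores(matrix, 2)
        return float(expl[:2].sum())

    cv = {"edta_free": cumvar2(free_cohort), "cleaned": cumvar2(cleaned),
          "chopped": cumvar2(chopped)}
    return {
        "cumvar2_pct": cv,
        "cleaned_closer": abs(cv["cleaned"] - cv["edta_free"])
        <= abs(cv["chopped"] - cv["edta_free"]),
        "max_non_edta_integral_change": float(np.max(preserved)),
        "n": n,
    }
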