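"""High-level orchestration: blank references, calibration, full-sample runs.

This module wires the stages together the way a study would run them:

1. train the chemical-shift model chain (here: on a synthetic training
   table; external model files are accepted too);
2. acquire a metal-free EDTA blank per spectrometer and measure the
   instrument reference (reference free-EDTA integral, noise, S_f);
3. acquire calibration standards spanning the physiological ranges, run
   the assignment + deconvolution pipeline on them and fit the universal
   calibration curves (plus the pooled per-proton EDTA response);
4. for every study sample: anchor on glucose, assign all species through
   the model chain, deconvolute, and convert integrals to concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .deconv import FittedSystem, deconvolute_all
from .quant import (CalibrationCurve, InstrumentReference, QuantReport,
                    build_instrument_reference, fit_calibration,
                    fit_per_proton_response, normalized_integral,
                    quantify_ions)
from .shifts import (AssignmentResult, ModelChain, assign_all_species,
                     find_glucose_anchor, train_model_chain)
from .spectrum import Spectrum1D, estimate_noise
from .synth import (TOTAL_EDTA_MM, GeneratorConfig, SyntheticGroundTruth,
                    generate_delta_table, generate_spectrum, make_composition)
from .templates import ION_SINGLET, SpinSystemTemplate, default_template_db
from .templates import reference_species as _ref_species

IONS = ("Ca", "Mg", "Zn")

#: EDTA species entering the pooled per-proton response fit
_RESPONSE_SPECIES = {
    "free_edta_1": "free_edta", "free_edta_2": "free_edta",
    "ca_edta_singlet": "ca", "ca_edta_quartet": "ca",
    "mg_edta_singlet": "mg",
    "zn_edta_singlet": "zn", "zn_edta_quartet": "zn",
}


def train_default_chain(n: int = 150, seed: int = 7,
                        config: GeneratorConfig | None = None) -> ModelChain:
    """Train the shift-model chain on a synthetic cohort's shift table."""
    return train_model_chain(generate_delta_table(n, seed=seed, config=config))


def process_sample(
    spectrum: Spectrum1D,
    chain: ModelChain,
    templates: dict[str, SpinSystemTemplate] | None = None,
) -> tuple[AssignmentResult, dict[str, FittedSystem]]:
    """Anchor, assign and deconvolute one sample."""
    db = templates if templates is not None else default_template_db()
    noise = estimate_noise(spectrum)
    anchor = find_glucose_anchor(spectrum, noise_sigma=noise)
    assignments = assign_all_species(spectrum, chain, anchor,
                                     noise_sigma=noise)
    fits = deconvolute_all(spectrum, assignments, db)
    return assignments, fits


# ---------------------------------------------------------------------------
# synthetic acquisition helpers (blank + standards)
# ---------------------------------------------------------------------------

def generate_blank(field_mhz: float, seed: int = 0,
                   config: GeneratorConfig | None = None,
                   total_edta: float = TOTAL_EDTA_MM) -> Spectrum1D:
    """Metal-free EDTA blank: buffer + EDTA only, no serum matrix."""
    base = config if config is not None else GeneratorConfig()
    conc = {k: 0.0 for k in base.concentrations}
    conc["free_edta"] = total_edta
    blank_cfg = replace(base, concentrations=conc, field_mhz=field_mhz,
                        baseline=())
    return generate_spectrum(blank_cfg, seed=seed)[0]


def standard_levels(n_levels: int = 8, seed: int = 0) -> list[dict]:
    """Metal levels for synthetic calibration standards.

    Levels bracket the physiological in-tube ranges (standard curves
    extend beyond the expected window so every study sample interpolates);
    each ion's levels are permuted independently so the ions are not
    collinear across standards.
    """
    rng = np.random.default_rng(seed)
    grids = {
        "ca": np.linspace(0.80, 1.70, n_levels),
        "mg": np.linspace(0.25, 0.65, n_levels),
        "zn": np.linspace(0.0020, 0.0140, n_levels),
    }
    order = {ion: rng.permutation(n_levels) for ion in grids}
    return [{ion: float(grids[ion][order[ion][i]]) for ion in grids}
            for i in range(n_levels)]


def generate_standards(
    field_mhz: float, n_levels: int = 8, seed: int = 0,
    config: GeneratorConfig | None = None,
    total_edta: float = TOTAL_EDTA_MM,
) -> list[tuple[Spectrum1D, SyntheticGroundTruth]]:
    """Render calibration standards (buffer + EDTA + metals + glucose).

    A small fixed glucose amount is included so the standards run through
    the same automated assignment path as study samples.
    """
    base = config if config is not None else GeneratorConfig()
    out = []
    for i, lv in enumerate(standard_levels(n_levels, seed)):
        comp = make_composition(ca=lv["ca"], mg=lv["mg"], zn=lv["zn"],
                                total_edta=total_edta, glucose=2.5,
                                asparagine=0.0, lactate=0.0, alanine=0.0)
        cfg = replace(base, concentrations=comp, field_mhz=field_mhz)
        out.append(generate_spectrum(cfg, seed=seed * 1000 + 17 * i + 1))
    return out


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationSetup:
    """Everything quantification needs, tied to one reference spectrometer."""

    curves: dict[str, CalibrationCurve]
    reference_by_field: dict[float, InstrumentReference]
    s_ref: float
    kappa: float                       # per-proton response (I_norm units)

    def reference_for(self, field_mhz: float) -> InstrumentReference:
        for f, ref in self.reference_by_field.items():
            if abs(f - field_mhz) < 1e-6:
                return ref
        raise KeyError(f"no instrument reference for {field_mhz} MHz")


def calibrate(
    standards: list[tuple[Spectrum1D, SyntheticGroundTruth]],
    blank: Spectrum1D,
    chain: ModelChain,
    templates: dict[str, SpinSystemTemplate] | None = None,
) -> CalibrationSetup:
    """Build universal calibration curves from standards + a blank.

    The blank defines the instrument reference of the calibration field,
    which also becomes the reference spectrometer (S_ref).
    """
    db = templates if templates is not None else default_template_db()
    ref = build_instrument_reference(blank, db)
    s_ref = ref.sensitivity

    per_ion: dict[str, list[tuple[float, float]]] = {i: [] for i in IONS}
    resp_i, resp_cp = [], []
    for spectrum, truth in standards:
        assignments, fits = process_sample(spectrum, chain, db)
        s_f = ref.sample_sensitivity(assignments.noise_sigma)
        for ion in IONS:
            fit = fits.get(ION_SINGLET[ion])
            if fit is None or fit.status != "ok":
                continue
            i_norm = normalized_integral(fit.integral, ref.edta_ref_integral,
                                         s_ref, s_f)
            per_ion[ion].append((truth.concentrations[ion.lower()], i_norm))
        for sp, pool in _RESPONSE_SPECIES.items():
            fit = fits.get(sp)
            if fit is None or fit.status != "ok":
                continue
            i_norm = normalized_integral(fit.integral, ref.edta_ref_integral,
                                         s_ref, s_f)
            resp_i.append(i_norm)
            resp_cp.append(truth.concentrations[pool] * db[sp].n_protons)

    curves = {
        ion: fit_calibration([c for c, _ in pts], [i for _, i in pts],
                             ion=ion, s_ref=s_ref)
        for ion, pts in per_ion.items() if len(pts) >= 3
    }
    kappa = fit_per_proton_response(resp_i, resp_cp)
    return CalibrationSetup(curves=curves,
                            reference_by_field={blank.field_mhz: ref},
                            s_ref=s_ref, kappa=kappa)


def add_field_reference(setup: CalibrationSetup, blank: Spectrum1D,
                        templates: dict[str, SpinSystemTemplate] | None = None
                        ) -> CalibrationSetup:
    """Register another spectrometer's blank with an existing calibration."""
    db = templates if templates is not None else default_template_db()
    setup.reference_by_field[blank.field_mhz] = \
        build_instrument_reference(blank, db)
    return setup


def quantify_sample(
    spectrum: Spectrum1D,
    chain: ModelChain,
    setup: CalibrationSetup,
    templates: dict[str, SpinSystemTemplate] | None = None,
) -> tuple[QuantReport, AssignmentResult, dict[str, FittedSystem]]:
    """Full pipeline for one study sample."""
    db = templates if templates is not None else default_template_db()
    assignments, fits = process_sample(spectrum, chain, db)
    ref = setup.reference_for(spectrum.field_mhz)
    report = quantify_ions(fits, setup.curves, spectrum, ref, setup.s_ref, db)
    return report, assignments, fits
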