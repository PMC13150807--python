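# edtaqc

EDTA-aware quality control and metal-ion quantification for serum/plasma
¹H NMR spectra.

Blood collected in EDTA tubes (and serum prepared with EDTA-containing
buffer) shows intense ¹H NMR signals from free EDTA and its Ca²⁺-, Mg²⁺-
and Zn²⁺-chelates. These signals crowd the 2.5–3.7 ppm region, overlap
endogenous metabolites, and are routinely either misassigned or removed
by chopping whole spectral regions. They also carry useful information:
each metal–EDTA complex's signal intensity reports the concentration of
the chelated ion.

`edtaqc` automates the whole workflow on processed 1D spectra:

1. **Assignment.** Chemical shifts in blood are not constants — pH, ionic
   strength and composition move every resonance, and they move together.
   The glucose anomeric doublet (δ ≈ 5.23 ppm, J ≈ 3.8 Hz) is located by
   derivative-enhanced peak picking; chained linear models
   δ_target = a·δ_predictor + b then predict each EDTA spin system's
   shift, and the observed local maximum inside a window narrower than
   two line widths re-anchors every step (with a wider, 2.5-line-width
   glucose-anchored fallback when a primary model finds nothing).
2. **Deconvolution.** Each spin system (two free-EDTA singlets, Ca–EDTA
   singlet + AB quartet, Mg–EDTA singlet, Zn–EDTA singlet + quartet) is a
   template of Voigt components with fixed relative offsets (Hz) and
   areas; fits free only the total area, a bounded centre shift, a width
   scale and a local baseline. The asparagine CH₂ doublet of doublets is
   fitted and subtracted before the weak Zn–EDTA signals.
3. **Quantification.** Integrals are harmonized across spectrometers via
   the free-EDTA reference of a metal-free blank and the instrument
   sensitivity S_f = Int_EDTA,peak1,f / σ_f (σ_f = sd of the 13.0–14.0
   ppm region): I_norm = (Int_M / Int_EDTA,peak1,f)·(S_ref/S_f), then
   C_M = a_M·I_norm + b_M on one universal calibration per ion. LOD/LOQ
   (3.3σ/a, 10σ/a), spike recovery, regression-coincidence F-tests and
   an EDTA mass balance are included.
4. **Cleanup.** Free-EDTA-only or all EDTA-related signals are removed
   and replaced by a baseline interpolant through flanking anchors;
   everything outside the removed regions stays bit-identical. PCA on
   binned (0.02 ppm, mean-centred) cohorts and feature-wise Pearson
   correlation provide the QC analytics.

A first-class synthetic-spectrum generator renders serum-EDTA-like
spectra with known ground truth (latent-variable shift covariation,
macromolecule baseline, noise), so every stage is testable without real
data. Bruker processed-data directories, JCAMP-DX and two-column text
spectra are read natively.

## Worked example

```python
import edtaqc as eq
from edtaqc.pipeline import calibrate, generate_blank, generate_standards, quantify_sample

chain = eq.train_default_chain(n=150, seed=3)           # shift models
blank = generate_blank(500.13, seed=5)                  # metal-free EDTA blank
setup = calibrate(generate_standards(500.13, 8, seed=9), blank, chain)

comp = eq.make_composition(ca=1.20, mg=0.45, zn=0.007)  # in-tube, mM
spectrum, truth = eq.generate_spectrum(
    eq.GeneratorConfig(concentrations=comp, field_mhz=500.13), seed=20)
report, assignments, fits = quantify_sample(spectrum, chain, setup)
for ion in ("Ca", "Mg", "Zn"):
    print(ion, report.concentration(ion))
```

prints (true values 1.200 / 0.450 / 0.0070 mM):

```
Ca 1.1832...
Mg 0.4433...
Zn 0.0069...
```

The ~1% deviations are set by estimating the spectral noise (hence the
sensitivity S_f) from the 13.0–14.0 ppm region of each spectrum. The
scripts in `examples/` walk through simulation, assignment, cross-field
quantification and cleanup, printing the numbers they compute. A thin
CLI mirrors the API: `edtaqc simulate | fit-models | assign | calibrate |
quantify | clean | qc`.

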