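# Methods

This note records the models the package implements, the defaults it
ships, and the choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The spectrum model and the synthetic generator

A `Spectrum1D` is a processed (Fourier-transformed, phased,
baseline-corrected) real-part spectrum on a descending ppm axis, with the
acquisition metadata the quantification equations need: ¹H frequency
(MHz), receiver gain and number of scans. Receiver-gain normalization
(intensity / RG) is applied at load time by default and tracked by a
metadata flag so it is idempotent.

The generator renders the features of serum/plasma-EDTA spectra that the
pipeline must cope with, each with known ground truth:

* **Species.** Glucose anomeric doublet (5.233 ppm, J = 3.8 Hz; the
  assignment anchor), free-EDTA acetate singlet (3.600 ppm, 8H; the
  normalization reference "peak 1") and ethylenic singlet (3.115 ppm,
  4H), Ca–EDTA singlet (2.550, 4H) + AB quartet (3.095, 8H), Mg–EDTA
  singlet (2.700, 4H), Zn–EDTA singlet (2.600, 4H) + quartet (3.300,
  8H), asparagine β-CH₂ doublet of doublets (2.86/2.94), plus lactate
  and alanine CH₃ doublets for metabolic variance outside the EDTA
  region. Centres are database entries, not contracts — only the
  relative geometry matters to the algorithms. Multiplet offsets are
  stored in Hz, so splittings are field-constant in Hz and shrink in ppm
  at higher field.
* **AB quartets** are four Voigt lines at ±(D±J)/2 Hz
  (D = √(Δν² + J²)) with roof-effect areas (1 ∓ J/D)/4. Defaults
  (J = 16.2, Δν = 7.0 Hz for Ca; 16.8/6.5 for Zn) put the two inner
  lines ~1.4 Hz apart so they merge into a single apex at the system
  centre — windowed maximum-picking then lands on the multiplet centre
  rather than an inner line.
* **Lineshape.** Voigt with FWHM 1.5 Hz (Gaussian share 0.43 of the
  width), evaluated exactly via the Faddeeva function. Typical of
  well-shimmed serum spectra.
* **Concentrations** are in-tube values (serum diluted 1:1 with buffer).
  Total EDTA defaults to 2.8245 mM (a 5.649 mM buffer halved); free
  EDTA closes the mass balance, free = total − Ca − Mg − Zn. Cohort
  ranges span adult blood reference intervals after dilution:
  Ca 1.05–1.30, Mg 0.35–0.50, Zn 0.0045–0.009, glucose 1.75–4.0 mM. A
  configurable fraction (default 6%) of cohort samples gets Zn below the
  detection threshold, mirroring the minority of real samples where
  Zn–EDTA is unrecoverable.
* **Shift covariation.** One latent condition variable u ~ N(0,1) per
  sample (standing in for pH/ionic-strength/composition effects) moves
  every species' centre along its own slope (0.002–0.0052 ppm per unit),
  plus independent jitter of sd 1.5·10⁻⁴ ppm. This is what makes chained
  linear shift models work, and the jitter sets their rRMSE scale.
* **Baseline and noise.** Broad macromolecule background = three wide
  Gaussians (centres 0.95/2.10/4.05 ppm, σ 0.35–0.5 ppm) whose common
  amplitude varies ~12% per sample (protein-level variation); white
  Gaussian noise with sd 0.07 at the reference instrument — chosen so
  the weakest quantified signal, the Zn–EDTA singlet at physiological
  Zn, has peak SNR ≈ 100.
* **Instrument model.** Signal areas scale with field^1.5, receiver gain
  and scans; noise with gain and √scans. By default the virtual
  spectrometers are sensitivity-matched across fields (equal SNR — as
  when the lower-field instrument carries a cryoprobe), which is the
  regime in which one universal calibration can serve both fields;
  `snr_mode="constant_noise"` instead keeps the noise floor
  field-independent, making S_f genuinely field-dependent (used in unit
  tests of the sensitivity correction).
* **Grid.** 49,152 points over 14.5…−1.5 ppm (≈0.2 Hz/point at 600 MHz,
  matching the real acquisitions' point density) so the 13.0–14.0 ppm
  noise region is on-axis.

What the generator does **not** emulate: water/urea residuals, lipid
multiplet complexity, T₁/T₂ relaxation weighting, pH-driven *nonlinear*
shift behaviour, peak-width variation across species, or chemical
exchange. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not performance on arbitrary real
spectra; on real data the shift models must be trained on assigned real
cohorts and the templates measured from a reference EDTA spectrum.

## Assignment

Peak detection uses the magnitude of the first derivative (sharp peaks
are enhanced as height/width; smooth baseline vanishes) and
prominence-based maxima. The anchor search looks for apex pairs split by
J/field ± 20% with line intensities within a factor of three (the
anomeric doublet is 1:1); the most intense qualifying pair wins, and a
missing anchor aborts the sample.

"Line width" is operationalized as the measured FWHM of the assigned
free-EDTA reference singlet of the current spectrum (fallback 1.5
Hz/field). Search windows: half-width = max(model rRMSE, 0.5 LW), capped
so the primary window stays under 2 LW; fallback windows are 2.5 LW. A
qualifying maximum must have prominence ≥ 3σ **and** rise ≥ 3σ above the
window's local median — either criterion alone false-triggers (on noise
ripples riding a peak shoulder, or on the macromolecule baseline,
respectively). Apexes are refined by 3-point parabolic interpolation.
Fallback is triggered operationally: the primary window contains no
qualifying maximum, or the primary model's predictor was itself
unassigned. The default chain is glucose → Ca-quartet → Ca-singlet →
Mg-singlet, glucose-anchored models for both Zn systems and the free-EDTA
singlets, and glucose-anchored fallbacks where a primary model chains
off another EDTA signal.

## Deconvolution

Fits are local nonlinear least squares (lmfit/MINPACK) over each
system's multiplet span ± 6 line widths. Free parameters per system:
total area (≥ 0), centre shift bounded to ±0.5 LW (the assignment
already localized the system; the bound prevents peak stealing), one
width scale (0.4–2.5); component offsets and area ratios are fixed by
the template. Systems whose regions overlap (the downfield free-EDTA
singlet rides on the Ca-quartet by default) are fitted jointly. Each fit
region carries a local **quadratic** baseline: the curving Lorentzian
tails of the intense Ca-EDTA and free-EDTA singlets reach the weak
Zn-EDTA region, and a straight line leaves a Zn area bias proportional
to Ca. The ±6 LW flanks (rather than a minimal ±3) anchor that baseline;
with narrow flanks the area/baseline covariance inflates the Zn integral
noise several-fold.

The asparagine dd is located by a matched-template scan across its
region (no shift model needed), fitted jointly with any overlapping
Zn-EDTA singlet, and subtracted — only inside its declared region —
before the Zn fits. If its matched amplitude is below 3σ the spectrum
passes through unchanged.

Integral uncertainty = residual rms × √(region width × point spacing),
the white-noise sd of an integral over the fit region. Negative areas
cannot occur (bound at 0); a fit pinned at zero is flagged.

## Quantification

Provenance of the normalization inputs (the equations name the
quantities but not their source spectra): the reference free-EDTA
integral Int_EDTA,peak1,f is measured **per field** on a metal-free
EDTA blank — a per-sample denominator would make the calibration
nonlinear, since free EDTA = total − chelated varies with the analyte —
while the spectral noise σ_f is estimated **per sample** from its own
13.0–14.0 ppm region, so S_f = Int_peak1,f/σ_f is reported per sample.
Per-sample σ̂ errors are zero-mean and independent (≈1.3% relative: the
sd of ~3,000 points; this is scale-free, so higher SNR does not shrink
it), which makes them ordinary residual scatter rather than a per-field
systematic — the property the cross-field coincidence tests rely on.
This σ̂ scatter is also what limits single-cohort recovery precision to
a few percent; it is inherent to the stated noise-region convention.

Calibration fits C on I_norm by OLS with a free intercept; the
intercept's 95% t-interval is reported with an origin-compatibility
flag. Standards bracket the physiological window (Ca 0.80–1.70,
Mg 0.25–0.65, Zn 0.002–0.014 mM in-tube), with each ion's levels
permuted so ions are not collinear across standards; a small fixed
glucose amount is included so standards run through the same automated
assignment path as samples. LOD/LOQ use the ICH-style 3.3σ/slope and
10σ/slope convention (factors configurable). The EDTA mass balance
converts every EDTA species through a pooled per-proton response κ
(I_norm per mM·proton, fitted through the origin on the standards) and
sums free EDTA (8H reference singlet) with the three 4H complex
singlets. Concentration uncertainties propagate the integral errors of
the metal and reference fits through the linear map.

The regression-coincidence test is the extra-sum-of-squares F-test:
pooled single line vs separate per-cohort lines, or fitted line(s) vs a
fixed reference line (df = 2 per constrained line).

## Cleanup and QC analytics

Removal replaces each targeted system's fitted-component span ± 3 LW
with a monotone interpolant (PCHIP) through anchors flanking the merged
region — medians of 0.01 ppm windows, computed **after subtracting the
fitted tails of the removed systems** so the anchors estimate baseline
rather than peak shoulders (the flanks themselves are never modified;
every point outside removed regions is bit-identical). When a targeted
system overlaps one that must be kept, its fitted model is subtracted
instead and the report flags it. Noise re-injection into reconstructed
regions is available but off by default, so cleaned spectra are smooth.
The "manual removal" comparator zero-fills the same regions.

Binning integrates half-open 0.02 ppm bins aligned to the region start
(sum × point spacing) and mean-centres columns; PCA is SVD on that
matrix with explained variance in percent of total; feature correlation
is vectorized Pearson r per column with constant features flagged at
r = 0.

## Study conditions and problem sizes

The validation studies use: shift-model training tables of 150 samples;
8 calibration standards (24, over the wider bracketing grids, for the
cross-field study, where calibration bias would otherwise dominate the
coincidence tests); cohorts of 40 (quantification fidelity), 100
(assignment validation), 20 × 3 matched cohorts (cleanup PCA); 50
replicates × 6 compositions × 2 fields for harmonization. Coincidence
with the 1:1 line is tested per ion (estimate vs true concentration,
both field cohorts jointly), and the non-rejection rate is tallied over
all per-ion tests. Single-study recovery slopes carry ~4% sd from the
σ̂ scatter above, so the slope-recovery check averages five replicate
studies rather than widening its band.

## Known limitations

* Templates and shift models are calibrated to the generator itself;
  real-data use requires training on assigned cohorts (external model
  files are supported via JSON).
* Only the metal-free-blank normalization route is implemented for
  Eq-style harmonization; per-sample-reference normalization is
  available through the low-level API but is nonlinear in the analyte.
* The JCAMP reader handles uncompressed AFFN tables only; the Bruker
  reader handles int32 processed data (`DTYPP = 0`).
* Cleaning removes everything inside a replaced region: a metabolite
  fully co-resonant with an EDTA signal is lost unless it is itself
  fitted (then the EDTA model is subtracted instead).
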