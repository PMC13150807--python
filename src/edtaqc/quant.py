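"""Absolute ion quantification via sensitivity-normalized integrals.

Cross-spectrometer harmonization works in three steps:

1. *Instrument sensitivity.* For each spectrometer operating at field f,
   ``S_f = Int_EDTA,peak1,f / sigma_f``: the integral of the reference
   free-EDTA peak of a metal-free reference (blank) EDTA spectrum divided
   by that spectrum's noise (standard deviation of the 13.0-14.0 ppm
   region by default).
2. *Normalized integrals.* Each metal-EDTA complex integral is expressed
   relative to the same per-field reference integral and corrected for
   the sensitivity ratio: ``I_norm = (Int_M / Int_ref) * (S_ref / S_f)``,
   with S_ref the sensitivity of the reference spectrometer. The blank is
   acquired per field, so the normalization cancels the instrument
   response and the sensitivity factor absorbs residual differences.
3. *Universal calibration.* ``C_M = a_M * I_norm + b_M`` fitted on
   standards; the intercept is fitted (not forced through zero) and a
   95% CI diagnostic reports whether the curve passes statistically
   through the origin.

LOD/LOQ follow the ICH-style 3.3 sigma / slope and 10 sigma / slope
convention (configurable factors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .deconv import STATUS_OK, FittedSystem, fit_spin_system
from .errors import DegenerateFitError, SpectrumDomainError
from .spectrum import Spectrum1D, estimate_noise
from .templates import ION_SINGLET, SpinSystemTemplate, reference_species


def spectrometer_sensitivity(edta_ref_integral: float,
                             noise_sigma: float) -> float:
    """Instrument sensitivity S_f = reference free-EDTA integral / noise."""
    if noise_sigma <= 0:
        raise SpectrumDomainError("noise sigma must be positive")
    return edta_ref_integral / noise_sigma


def normalized_integral(metal_integral: float, edta_ref_integral: float,
                        s_ref: float, s_f: float) -> float:
    """Sensitivity-normalized integral of a metal-EDTA complex."""
    if edta_ref_integral <= 0:
        raise SpectrumDomainError("reference EDTA integral must be positive")
    if s_f <= 0:
        raise SpectrumDomainError("sensitivity must be positive")
    return (metal_integral / edta_ref_integral) * (s_ref / s_f)


# ---------------------------------------------------------------------------
# per-field instrument reference (metal-free EDTA blank)
# ---------------------------------------------------------------------------

@dataclass
class InstrumentReference:
    """Per-spectrometer quantities from the metal-free EDTA blank."""

    field_mhz: float
    edta_ref_integral: float      # Int_EDTA,peak1,f
    noise_sigma: float            # sigma of the blank itself
    ref_integral_uncertainty: float = 0.0

    @property
    def sensitivity(self) -> float:
        """S_f of the blank acquisition (used as S_ref of a calibration)."""
        return spectrometer_sensitivity(self.edta_ref_integral,
                                        self.noise_sigma)

    def sample_sensitivity(self, sigma_sample: float) -> float:
        """S_f entering a sample's normalization: the per-field reference
        integral over that sample's own spectral noise."""
        return spectrometer_sensitivity(self.edta_ref_integral, sigma_sample)


def build_instrument_reference(
    blank: Spectrum1D,
    templates: dict[str, SpinSystemTemplate],
    line_width_ppm: float | None = None,
    search_halfwidth: float = 0.05,
) -> InstrumentReference:
    """Measure S_f ingredients from a metal-free EDTA blank spectrum.

    The reference free-EDTA peak (the template flagged ``reference=True``)
    is located by the maximum near its database position and deconvoluted;
    the noise is the standard deviation of the default noise region.
    """
    ref_name = reference_species(templates)
    t = templates[ref_name]
    lw = line_width_ppm or 1.5 / blank.field_mhz
    sl = blank.region_slice(t.default_center - search_halfwidth,
                            t.default_center + search_halfwidth)
    if sl.stop - sl.start < 3:
        raise SpectrumDomainError("blank does not cover the reference peak")
    apex = float(blank.ppm_axis[sl][np.argmax(blank.intensity[sl])])
    fit = fit_spin_system(blank, t, apex, lw)
    if fit.status != STATUS_OK:
        raise SpectrumDomainError(
            f"reference peak fit failed on blank: {fit.diagnostics}")
    return InstrumentReference(
        field_mhz=blank.field_mhz, edta_ref_integral=fit.integral,
        noise_sigma=estimate_noise(blank),
        ref_integral_uncertainty=fit.uncertainty)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Universal calibration C_M = a_M * I_norm + b_M for one ion."""

    ion: str
    slope: float                      # mM per normalized-integral unit
    intercept: float                  # mM
    intercept_ci95: tuple[float, float]
    s_ref: float                      # sensitivity of the reference field
    n_points: int
    r_squared: float = np.nan
    lod: float | None = None          # mM, optional

    @property
    def origin_compatible(self) -> bool:
        """True when the 95% CI of the intercept contains zero."""
        lo, hi = self.intercept_ci95
        return lo <= 0.0 <= hi


def fit_calibration(concentrations, norm_integrals, ion: str = "",
                    s_ref: float = 1.0) -> CalibrationCurve:
    """OLS fit of concentration on normalized integral.

    Reports the intercept's 95% confidence interval; the curve "passes
    statistically through the origin" when that interval contains zero.
    """
    c = np.asarray(concentrations, dtype=float)
    i_norm = np.asarray(norm_integrals, dtype=float)
    if c.size != i_norm.size or c.size < 3:
        raise DegenerateFitError("calibration needs >= 3 (C, I_norm) points")
    if np.ptp(i_norm) <= 0:
        raise DegenerateFitError("normalized integrals span zero range")
    res = stats.linregress(i_norm, c)
    n = c.size
    tval = stats.t.ppf(0.975, n - 2)
    ci = (res.intercept - tval * res.intercept_stderr,
          res.intercept + tval * res.intercept_stderr)
    return CalibrationCurve(
        ion=ion, slope=float(res.slope), intercept=float(res.intercept),
        intercept_ci95=(float(ci[0]), float(ci[1])), s_ref=s_ref,
        n_points=int(n), r_squared=float(res.rvalue**2))


# ---------------------------------------------------------------------------
# per-sample quantification
# ---------------------------------------------------------------------------

ION_STATUS_OK = "ok"
ION_STATUS_BELOW_DETECTION = "below_detection"
ION_STATUS_BELOW_LOD = "below_LOD"


@dataclass
class IonQuant:
    ion: str
    norm_integral: float
    concentration: float | None      # mM; None when below detection
    uncertainty: float               # mM
    status: str


@dataclass
class QuantReport:
    """Per-sample quantification output."""

    label: str
    s_f: float
    sigma_f: float
    edta_ref_integral: float         # per-field blank reference integral
    free_edta_integral: float        # this sample's fitted free-EDTA peak1
    ions: dict[str, IonQuant] = field(default_factory=dict)

    def concentration(self, ion: str) -> float | None:
        q = self.ions.get(ion)
        return q.concentration if q else None

    def to_rows(self) -> list[dict]:
        return [
            {"sample": self.label, "ion": q.ion, "I_norm": q.norm_integral,
             "C_mM": q.concentration, "uncertainty_mM": q.uncertainty,
             "status": q.status}
            for q in self.ions.values()
        ]


def quantify_ions(
    fits: dict[str, FittedSystem],
    curves: dict[str, CalibrationCurve],
    spectrum: Spectrum1D,
    reference: InstrumentReference,
    s_ref: float | None = None,
    templates: dict[str, SpinSystemTemplate] | None = None,
    sigma_f: float | None = None,
) -> QuantReport:
    """Convert deconvoluted integrals into absolute ion concentrations.

    ``reference`` carries the per-field blank reference integral entering
    the normalization; ``sigma_f`` is this sample's spectral noise
    (estimated from the default noise region when not given), so
    ``S_f = Int_ref,f / sigma_f`` is per sample. ``s_ref`` is the
    sensitivity of the reference spectrometer the calibration was built
    on. Ions whose complex signal was below detection are reported as
    such, never as 0 mM.
    """
    ref_name = "free_edta_1" if templates is None else reference_species(templates)
    ref_fit = fits.get(ref_name)
    if ref_fit is None or ref_fit.status != STATUS_OK:
        raise SpectrumDomainError(
            "per-sample free-EDTA reference fit missing or failed")
    if sigma_f is None:
        sigma_f = estimate_noise(spectrum)
    s_f = reference.sample_sensitivity(sigma_f)
    report = QuantReport(
        label=spectrum.label, s_f=s_f, sigma_f=sigma_f,
        edta_ref_integral=reference.edta_ref_integral,
        free_edta_integral=ref_fit.integral)

    for ion, curve in curves.items():
        singlet = ION_SINGLET[ion]
        fit = fits.get(singlet)
        if fit is None or fit.status not in (STATUS_OK,):
            report.ions[ion] = IonQuant(ion, 0.0, None, 0.0,
                                        ION_STATUS_BELOW_DETECTION)
            continue
        i_norm = normalized_integral(
            fit.integral, reference.edta_ref_integral,
            s_ref if s_ref is not None else curve.s_ref, s_f)
        conc = curve.slope * i_norm + curve.intercept
        rel = 0.0
        if fit.integral > 0:
            rel = (fit.uncertainty / fit.integral) ** 2
        if reference.edta_ref_integral > 0:
            rel += (reference.ref_integral_uncertainty
                    / reference.edta_ref_integral) ** 2
        unc = abs(curve.slope) * i_norm * np.sqrt(rel) if i_norm else 0.0
        status = ION_STATUS_OK
        if curve.lod is not None and conc < curve.lod:
            status = ION_STATUS_BELOW_LOD
        report.ions[ion] = IonQuant(ion, float(i_norm), float(conc),
                                    float(unc), status)
    return report


# ---------------------------------------------------------------------------
# regression coincidence (extra-sum-of-squares F-test)
# ---------------------------------------------------------------------------

def _ols_sse(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.linregress(x, y)
    return float(np.sum((y - (res.slope * x + res.intercept)) ** 2))


def regression_coincidence_test(
    x1, y1, x2=None, y2=None,
    reference: tuple[float, float] | None = None,
):
    """Extra-sum-of-squares F-test of regression coincidence.

    With two cohorts: compares one pooled line against separate per-cohort
    lines. With ``reference=(slope, intercept)`` given: compares the fixed
    line against the fitted line(s). Returns ``(F, df_num, df_den, p)``.
    """
    sets = [(np.asarray(x1, float), np.asarray(y1, float))]
    if x2 is not None:
        sets.append((np.asarray(x2, float), np.asarray(y2, float)))
    for x, y in sets:
        if x.size != y.size or x.size < 3:
            raise DegenerateFitError("each cohort needs >= 3 points")
        if np.ptp(x) <= 0:
            raise DegenerateFitError("degenerate cohort (constant x)")
    n = sum(x.size for x, _ in sets)
    k = len(sets)
    sse_full = sum(_ols_sse(x, y) for x, y in sets)
    df_full = n - 2 * k

    if reference is not None:
        a, b = reference
        sse_red = sum(float(np.sum((y - (a * x + b)) ** 2)) for x, y in sets)
        df_num = 2 * k
    else:
        if k < 2:
            raise DegenerateFitError(
                "two cohorts or a reference line are required")
        xall = np.concatenate([x for x, _ in sets])
        yall = np.concatenate([y for _, y in sets])
        sse_red = _ols_sse(xall, yall)
        df_num = 2 * (k - 1)

    if df_full <= 0:
        raise DegenerateFitError("not enough points for the F-test")
    num = max(sse_red - sse_full, 0.0) / df_num
    den = sse_full / df_full
    if den == 0:
        f_stat = 0.0 if num == 0 else np.inf
    else:
        f_stat = num / den
    p = float(stats.f.sf(f_stat, df_num, df_full)) if np.isfinite(f_stat) else 0.0
    return float(f_stat), int(df_num), int(df_full), p


# ---------------------------------------------------------------------------
# LOD / LOQ / recovery
# ---------------------------------------------------------------------------

def lod_loq_recovery(curve: CalibrationCurve, blank_sd: float,
                     spiked: float | None = None, base: float | None = None,
                     added: float | None = None,
                     lod_factor: float = 3.3, loq_factor: float = 10.0,
                     ) -> tuple[float, float, float | None]:
    """LOD = 3.3 sigma_blank / a_M, LOQ = 10 sigma_blank / a_M (in mM),
    and the spike recovery percentage when a spiking triple is given."""
    if curve.slope <= 0:
        raise DegenerateFitError("calibration slope must be positive")
    lod = lod_factor * blank_sd / curve.slope
    loq = loq_factor * blank_sd / curve.slope
    recovery = None
    if spiked is not None or base is not None or added is not None:
        if added is None or added <= 0:
            raise SpectrumDomainError("spike 'added' must be positive")
        recovery = 100.0 * (spiked - base) / added
    return float(lod), float(loq), recovery


# ---------------------------------------------------------------------------
# per-proton response and EDTA mass balance
# ---------------------------------------------------------------------------

def fit_per_proton_response(norm_integrals, conc_times_protons) -> float:
    """Through-origin response kappa: I_norm per (mM x proton).

    Pooled over EDTA species of known concentration in standards; used to
    convert any EDTA species' normalized integral into a concentration,
    ``C = I_norm / (kappa * n_protons)``.
    """
    i = np.asarray(norm_integrals, float)
    cp = np.asarray(conc_times_protons, float)
    if i.size < 1 or np.all(cp == 0):
        raise DegenerateFitError("no usable response points")
    return float(cp @ i / (cp @ cp))


#: species used for the EDTA mass balance and their complex/pool
MASS_BALANCE_SPECIES = {
    "free_edta_1": "free_edta",
    "ca_edta_singlet": "ca",
    "mg_edta_singlet": "mg",
    "zn_edta_singlet": "zn",
}


def edta_mass_balance(
    fits: dict[str, FittedSystem],
    reference: InstrumentReference,
    s_ref: float,
    kappa: float,
    templates: dict[str, SpinSystemTemplate],
    sigma_f: float | None = None,
) -> dict[str, float]:
    """Concentrations of free EDTA and each metal-EDTA complex (mM).

    Returns one entry per pool plus ``"total"`` — the in-tube EDTA
    concentration recovered from the spectrum alone.
    """
    s_f = (reference.sample_sensitivity(sigma_f) if sigma_f is not None
           else reference.sensitivity)
    out: dict[str, float] = {}
    for species, pool in MASS_BALANCE_SPECIES.items():
        fit = fits.get(species)
        if fit is None or fit.status != STATUS_OK:
            out[pool] = 0.0
            continue
        i_norm = normalized_integral(fit.integral,
                                     reference.edta_ref_integral, s_ref, s_f)
        out[pool] = i_norm / (kappa * templates[species].n_protons)
    out["total"] = sum(v for k, v in out.items() if k != "total")
    return out
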