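"""Template-constrained Voigt deconvolution of assigned spin systems.

Each spin system is fitted over a local region (its multiplet span plus
three line widths on each side) with the component offsets and relative
areas fixed by its template. Free parameters are the overall area, a
small centre shift (bounded by half a line width — the assignment already
localized the system, and the bound prevents peak stealing), a shared
width scale, and a local quadratic baseline — broad background under the
crowded EDTA region includes the curving tails of neighbouring intense
singlets, which a straight line cannot absorb. Systems whose fit regions
overlap (for
example the downfield free-EDTA singlet riding on the Ca-EDTA quartet)
are fitted jointly in one least-squares problem.

Integral uncertainties are propagated from the fit residuals as
``rms * sqrt(region_width * point_spacing)`` — the white-noise error of
an integral over the fit region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .errors import SpectrumDomainError
from .lineshapes import VoigtPeak, voigt_profile, voigt_widths_for_fwhm
from .shifts import (STATUS_BELOW_DETECTION, AssignmentResult)
from .spectrum import Spectrum1D
from .templates import SpinSystemTemplate

# fit region: multiplet span +- this many line widths; wide enough flanks
# anchor the local baseline, which otherwise trades off against the area
# of weak peaks (Zn-EDTA) and inflates their integral noise
FIT_REGION_PAD_LW = 6.0
CENTER_BOUND_LW = 0.5       # allowed centre shift during fitting

STATUS_OK = "ok"
STATUS_FIT_FAILURE = "fit_failure"
STATUS_CLIPPED = "clipped_to_zero"


@dataclass
class FittedSystem:
    """Result of deconvoluting one spin system."""

    species: str
    peaks: list[VoigtPeak] = field(default_factory=list)
    integral: float = 0.0            # total area (intensity x ppm)
    center: float = np.nan           # fitted system centre (ppm)
    residual_rms: float = np.nan
    uncertainty: float = 0.0         # integral error from residuals
    status: str = STATUS_OK
    region: tuple[float, float] = (np.nan, np.nan)
    n_protons: int = 1
    diagnostics: str = ""


def _fit_region(template: SpinSystemTemplate, delta: float, field_mhz: float,
                line_width_ppm: float) -> tuple[float, float]:
    lo, hi = template.span_ppm(field_mhz)
    pad = FIT_REGION_PAD_LW * line_width_ppm
    return delta + lo - pad, delta + hi + pad


def _system_model(ppm: np.ndarray, template: SpinSystemTemplate,
                  center: float, area: float, sigma_g: float,
                  gamma_l: float, field_mhz: float) -> np.ndarray:
    y = np.zeros_like(ppm)
    for off_hz, rel in template.components:
        y += voigt_profile(ppm, VoigtPeak(center + off_hz / field_mhz,
                                          sigma_g, gamma_l, area * rel))
    return y


def fit_systems_joint(
    spectrum: Spectrum1D,
    systems: list[tuple[SpinSystemTemplate, float]],
    line_width_ppm: float,
    gaussian_fraction: float = 0.43,
) -> list[FittedSystem]:
    """Fit one or more spin systems over the union of their fit regions.

    ``systems`` is a list of (template, assigned centre). All systems
    share one linear baseline; each has its own area, bounded centre
    shift and width scale.
    """
    if not systems:
        return []
    f = spectrum.field_mhz
    regions = [_fit_region(t, d, f, line_width_ppm) for t, d in systems]
    lo = min(r[0] for r in regions)
    hi = max(r[1] for r in regions)
    if not spectrum.contains_region(lo, hi):
        raise SpectrumDomainError(
            f"fit region ({lo:.3f}, {hi:.3f}) outside the ppm axis")
    sl = spectrum.region_slice(lo, hi)
    x = spectrum.ppm_axis[sl]
    y = spectrum.intensity[sl]
    x0 = float(x.mean())
    dppm = spectrum.dppm

    sg0, gl0 = voigt_widths_for_fwhm(line_width_ppm, gaussian_fraction)
    height_unit = 1.0 / (np.pi * line_width_ppm / 2.0)  # ~peak height per area

    params = Parameters()
    floor = float(np.percentile(y, 10))
    params.add("b0", value=floor)
    params.add("b1", value=0.0)
    params.add("b2", value=0.0)
    for i, (t, d) in enumerate(systems):
        # crude initial area from the apex height above the floor
        near_lo, near_hi = _fit_region(t, d, f, 0.5 * line_width_ppm)
        near = (x >= near_lo) & (x <= near_hi)
        apex = float(np.max(y[near] - floor, initial=0.0))
        rel_max = max(rel for _, rel in t.components)
        a0 = max(apex / (height_unit * rel_max), 1e-12)
        params.add(f"area_{i}", value=a0, min=0.0)
        params.add(f"dc_{i}", value=0.0,
                   min=-CENTER_BOUND_LW * line_width_ppm,
                   max=CENTER_BOUND_LW * line_width_ppm)
        params.add(f"wscale_{i}", value=1.0, min=0.4, max=2.5)

    def model(p) -> np.ndarray:
        dx = x - x0
        out = p["b0"].value + p["b1"].value * dx + p["b2"].value * dx * dx
        for i, (t, d) in enumerate(systems):
            out = out + _system_model(
                x, t, d + p[f"dc_{i}"].value, p[f"area_{i}"].value,
                sg0 * p[f"wscale_{i}"].value, gl0 * p[f"wscale_{i}"].value, f)
        return out

    def residual(p):
        return model(p) - y

    out = []
    try:
        res = minimize(residual, params, method="leastsq")
        ok = res.success
        p = res.params
        rms = float(np.sqrt(np.mean(res.residual**2)))
    except Exception as exc:  # noqa: BLE001 - report as status, not raise
        for t, d in systems:
            out.append(FittedSystem(species=t.species, status=STATUS_FIT_FAILURE,
                                    n_protons=t.n_protons, diagnostics=str(exc)))
        return out

    for i, ((t, d), reg) in enumerate(zip(systems, regions)):
        area = float(p[f"area_{i}"].value)
        center = d + float(p[f"dc_{i}"].value)
        ws = float(p[f"wscale_{i}"].value)
        peaks = [VoigtPeak(center + off_hz / f, sg0 * ws, gl0 * ws, area * rel)
                 for off_hz, rel in t.components]
        width = reg[1] - reg[0]
        status = STATUS_OK if ok else STATUS_FIT_FAILURE
        if area <= 1e-12:
            area, status = 0.0, STATUS_CLIPPED
        out.append(FittedSystem(
            species=t.species, peaks=peaks, integral=area, center=center,
            residual_rms=rms, uncertainty=rms * np.sqrt(width * dppm),
            status=status, region=reg, n_protons=t.n_protons,
            diagnostics="" if ok else "leastsq did not converge"))
    return out


def fit_spin_system(spectrum: Spectrum1D, template: SpinSystemTemplate,
                    assigned_delta: float, line_width_ppm: float,
                    **kwargs) -> FittedSystem:
    """Deconvolute a single spin system (see :func:`fit_systems_joint`)."""
    return fit_systems_joint(spectrum, [(template, assigned_delta)],
                             line_width_ppm, **kwargs)[0]


# ---------------------------------------------------------------------------
# asparagine subtraction
# ---------------------------------------------------------------------------

def subtract_asparagine(
    spectrum: Spectrum1D,
    asn_template: SpinSystemTemplate,
    region: tuple[float, float] | None = None,
    line_width_ppm: float | None = None,
    noise_sigma: float | None = None,
    companions: list[tuple[SpinSystemTemplate, float]] | None = None,
) -> tuple[Spectrum1D, FittedSystem | None]:
    """Fit and remove the asparagine CH2 doublet of doublets.

    The dd pattern is located by a matched-template scan across ``region``
    (no shift model needed), then fitted with the usual bounded
    deconvolution; the fitted asparagine model — and only it — is
    subtracted inside the region. ``companions`` (e.g. an overlapping
    Zn-EDTA singlet) are fitted jointly but left in the spectrum. If no
    asparagine signal rises 3 sigma above the local floor, the input is
    returned unchanged with ``None`` as the fitted system.
    """
    from .spectrum import estimate_noise
    from .shifts import _local_floor

    f = spectrum.field_mhz
    lw = line_width_ppm or 1.5 / f
    span_lo, span_hi = asn_template.span_ppm(f)
    half_span = (span_hi - span_lo) / 2.0
    if region is None:
        c = asn_template.default_center
        region = (c - half_span - 8 * lw, c + half_span + 8 * lw)
    low, high = min(region), max(region)
    if not spectrum.contains_region(low, high):
        raise SpectrumDomainError("asparagine region outside the ppm axis")
    if noise_sigma is None:
        noise_sigma = estimate_noise(spectrum)

    sl = spectrum.region_slice(low, high)
    x = spectrum.ppm_axis[sl]
    y = spectrum.intensity[sl]
    # local linear floor between the region edges
    edge = max(3, x.size // 20)
    bl_lo, bl_hi = float(np.median(y[-edge:])), float(np.median(y[:edge]))
    base = np.interp(x, [x[-1], x[0]], [bl_lo, bl_hi])
    resid = y - base

    # matched-template scan for the dd centre
    centers = np.arange(low + half_span + lw, high - half_span - lw, lw / 4.0)
    if centers.size == 0:
        return spectrum, None
    sg0, gl0 = voigt_widths_for_fwhm(lw)
    best_c, best_score = None, -np.inf
    for c in centers:
        shape = _system_model(x, asn_template, c, 1.0, sg0, gl0, f)
        score = float(shape @ resid)
        if score > best_score:
            best_c, best_score = float(c), score

    # amplitude check at the matched centre
    probe = _system_model(x, asn_template, best_c, 1.0, sg0, gl0, f)
    amp = best_score / float(probe @ probe)  # least-squares area at fixed shape
    peak_height = amp * float(np.max(probe))
    if peak_height < 3.0 * noise_sigma:
        return spectrum, None

    systems = [(asn_template.with_center(best_c), best_c)]
    if companions:
        systems += [(t, d) for t, d in companions if low <= d <= high]
    fits = fit_systems_joint(spectrum, systems, lw)
    asn_fit = fits[0]

    corrected = spectrum.copy()
    model_in_region = np.zeros_like(x)
    for pk in asn_fit.peaks:
        model_in_region += voigt_profile(x, pk)
    corrected.intensity[sl] = y - model_in_region
    return corrected, asn_fit


# ---------------------------------------------------------------------------
# whole-sample deconvolution
# ---------------------------------------------------------------------------

def _group_overlapping(items: list[tuple[SpinSystemTemplate, float,
                                         tuple[float, float]]]):
    """Group systems whose fit regions overlap into joint-fit clusters."""
    items = sorted(items, key=lambda it: it[2][0])
    groups: list[list] = []
    for it in items:
        if groups and it[2][0] <= groups[-1][-1][2][1]:
            groups[-1].append(it)
        else:
            groups.append([it])
    return groups


def deconvolute_all(
    spectrum: Spectrum1D,
    assignments: AssignmentResult,
    templates: dict[str, SpinSystemTemplate],
    species: tuple[str, ...] | None = None,
    subtract_asn: bool = True,
) -> dict[str, FittedSystem]:
    """Deconvolute every assigned EDTA spin system of a sample.

    The asparagine dd is subtracted first (jointly fitted with any
    overlapping Zn-EDTA singlet), then systems are fitted in joint groups
    of overlapping regions. Species assigned ``below_detection`` yield a
    zero integral with the same flag.
    """
    from .templates import EDTA_SPECIES

    if species is None:
        species = tuple(s for s in EDTA_SPECIES if s in templates)
    lw = assignments.line_width_ppm
    f = spectrum.field_mhz

    results: dict[str, FittedSystem] = {}
    fitted_items = []
    for sp in species:
        delta = assignments.delta(sp)
        if delta is None:
            results[sp] = FittedSystem(
                species=sp, integral=0.0, status=STATUS_BELOW_DETECTION,
                n_protons=templates[sp].n_protons)
            continue
        t = templates[sp]
        fitted_items.append((t, delta, _fit_region(t, delta, f, lw)))

    working = spectrum
    asn_fit = None
    if subtract_asn and "asparagine_dd" in templates:
        asn_t = templates["asparagine_dd"]
        span_lo, span_hi = asn_t.span_ppm(f)
        c = asn_t.default_center
        region = (c + span_lo - 8 * lw, c + span_hi + 8 * lw)
        companions = [(t, d) for t, d, _ in fitted_items
                      if region[0] <= d <= region[1]]
        working, asn_fit = subtract_asparagine(
            spectrum, asn_t, region=region, line_width_ppm=lw,
            noise_sigma=assignments.noise_sigma, companions=companions)
    if asn_fit is not None:
        results["asparagine_dd"] = asn_fit

    for group in _group_overlapping(fitted_items):
        fits = fit_systems_joint(working, [(t, d) for t, d, _ in group], lw)
        for fs in fits:
            results[fs.species] = fs
    return results
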