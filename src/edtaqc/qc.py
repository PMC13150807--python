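"""EDTA signal removal with baseline reconstruction, plus the PCA and
feature-correlation QC analytics.

Removal replaces each targeted spin system's region (its fitted
components plus three line widths on each side) with a smooth monotone
interpolant through baseline anchors flanking the region — medians of
0.01 ppm windows on each side. Every point outside the removed regions is
left bit-identical. When a targeted system overlaps a system that must be
kept, its fitted model is subtracted instead of replacing the region, and
the report flags it.

A "region-chop" comparator (zero-filling the same regions, emulating
manual removal of whole spectral windows) is provided for the PCA
fidelity comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.decomposition import PCA

from .deconv import STATUS_OK, FittedSystem
from .errors import SpectrumDomainError
from .lineshapes import voigt_profile
from .spectrum import Spectrum1D

MODE_FREE_ONLY = "free_only"
MODE_ALL_EDTA = "all_edta"

_TARGET_GROUPS = {
    MODE_FREE_ONLY: {"free_edta"},
    MODE_ALL_EDTA: {"free_edta", "ca", "mg", "zn"},
}

REMOVAL_PAD_LW = 3.0
ANCHOR_WIDTH_PPM = 0.01


@dataclass
class CleanReport:
    mode: str
    removed_regions: list[tuple[float, float]] = field(default_factory=list)
    anchors: list[tuple[tuple[float, float], tuple[float, float]]] = \
        field(default_factory=list)   # ((ppm, value) left/right) per region
    subtracted_species: list[str] = field(default_factory=list)
    max_center_residual_sigma: float = 0.0


def _system_region(fs: FittedSystem, line_width_ppm: float
                   ) -> tuple[float, float]:
    centers = [p.center for p in fs.peaks]
    pad = REMOVAL_PAD_LW * line_width_ppm
    return min(centers) - pad, max(centers) + pad


def _merge(regions: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not regions:
        return []
    regions = sorted(regions)
    out = [list(regions[0])]
    for lo, hi in regions[1:]:
        if lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return [tuple(r) for r in out]


def remove_edta_signals(
    spectrum: Spectrum1D,
    fits: dict[str, FittedSystem],
    mode: str = MODE_ALL_EDTA,
    line_width_ppm: float | None = None,
    noise_sigma: float | None = None,
    templates: dict | None = None,
    reinject_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Spectrum1D, CleanReport]:
    """Remove free-EDTA-only or all EDTA-related signals from a spectrum.

    ``fits`` is the per-species deconvolution output; the species group of
    each fitted system decides whether it is targeted under ``mode``.
    Returns the cleaned copy and a :class:`CleanReport`.
    """
    if mode not in _TARGET_GROUPS:
        raise SpectrumDomainError(f"unknown cleanup mode {mode!r}")
    from .templates import default_template_db

    db = templates if templates is not None else default_template_db()
    targets = _TARGET_GROUPS[mode]
    lw = line_width_ppm
    if lw is None:
        any_fit = next((f for f in fits.values() if f.peaks), None)
        lw = any_fit.peaks[0].fwhm if any_fit else 1.5 / spectrum.field_mhz
    if noise_sigma is None:
        from .spectrum import estimate_noise
        try:
            noise_sigma = estimate_noise(spectrum)
        except SpectrumDomainError:
            noise_sigma = float(np.std(np.diff(spectrum.intensity)) / np.sqrt(2))

    target_fits, keep_regions = [], []
    for name, fs in fits.items():
        if fs.status != STATUS_OK or not fs.peaks:
            continue
        group = db[name].group if name in db else "metabolite"
        if group in targets:
            target_fits.append(fs)
        else:
            keep_regions.append(_system_region(fs, lw))

    report = CleanReport(mode=mode)
    cleaned = spectrum.copy()

    # split targets into region-replacement vs model-subtraction
    replace_regions, centers_of_interest = [], []
    for fs in target_fits:
        reg = _system_region(fs, lw)
        centers_of_interest.extend(p.center for p in fs.peaks)
        overlaps_kept = any(reg[0] <= khi and klo <= reg[1]
                            for klo, khi in keep_regions)
        if overlaps_kept:
            sl = cleaned.region_slice(*reg)
            x = cleaned.ppm_axis[sl]
            model = np.zeros_like(x)
            for pk in fs.peaks:
                model += voigt_profile(x, pk)
            cleaned.intensity[sl] -= model
            report.subtracted_species.append(fs.species)
        else:
            replace_regions.append(reg)

    def _baseline_anchor(sl: slice) -> tuple[float, float]:
        """Anchor (ppm, value): flank median with the fitted tails of the
        targeted systems subtracted, so the anchor estimates the baseline
        rather than the shoulder of the removed peaks. The flank itself
        is never modified."""
        x = cleaned.ppm_axis[sl]
        y = cleaned.intensity[sl].copy()
        for fs in target_fits:
            for pk in fs.peaks:
                y -= voigt_profile(x, pk)
        return float(np.mean(x)), float(np.median(y))

    merged = _merge(replace_regions)
    rng = rng or np.random.default_rng(0)
    for lo, hi in merged:
        left = cleaned.region_slice(lo - ANCHOR_WIDTH_PPM, lo)
        right = cleaned.region_slice(hi, hi + ANCHOR_WIDTH_PPM)
        if (left.stop - left.start) < 1 or (right.stop - right.start) < 1:
            raise SpectrumDomainError(
                f"no anchor points flanking removed region ({lo:.3f}, {hi:.3f})")
        xl, yl = _baseline_anchor(left)
        xr, yr = _baseline_anchor(right)
        interp = PchipInterpolator([xl, xr], [yl, yr])
        sl = cleaned.region_slice(lo, hi)
        vals = interp(cleaned.ppm_axis[sl])
        if reinject_noise:
            vals = vals + rng.normal(0.0, noise_sigma, size=vals.size)
        cleaned.intensity[sl] = vals
        report.removed_regions.append((lo, hi))
        report.anchors.append(((xl, yl), (xr, yr)))

    # residuals at removed peak centres, in sigma units
    max_resid = 0.0
    for c in centers_of_interest:
        for (lo, hi), ((xl, yl), (xr, yr)) in zip(report.removed_regions,
                                                  report.anchors):
            if lo <= c <= hi:
                i = int(np.argmin(np.abs(cleaned.ppm_axis - c)))
                expect = float(PchipInterpolator([xl, xr], [yl, yr])(c))
                max_resid = max(max_resid,
                                abs(cleaned.intensity[i] - expect) / noise_sigma)
    report.max_center_residual_sigma = max_resid
    return cleaned, report


def chop_regions(spectrum: Spectrum1D,
                 regions: list[tuple[float, float]]) -> Spectrum1D:
    """Zero-fill the given ppm regions (the manual-removal comparator)."""
    out = spectrum.copy()
    for lo, hi in regions:
        out.intensity[out.region_slice(min(lo, hi), max(lo, hi))] = 0.0
    return out


# ---------------------------------------------------------------------------
# multivariate QC analytics
# ---------------------------------------------------------------------------

def pca_scores(binned: np.ndarray, k: int
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA via SVD on a (mean-centred) samples x bins matrix.

    Returns ``(scores, loadings, explained_pct)`` with explained variance
    per component as percent of total.
    """
    binned = np.asarray(binned, dtype=float)
    n, m = binned.shape
    if not 1 <= k <= min(n - 1, m):
        raise SpectrumDomainError(
            f"k = {k} exceeds min(samples - 1, bins) = {min(n - 1, m)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(binned)
    return scores, pca.components_, pca.explained_variance_ratio_ * 100.0


def feature_correlation(matrix: np.ndarray, target
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every feature column against a per-sample target.

    Returns ``(r, constant_mask)``; constant features get r = 0 and are
    flagged in the mask.
    """
    x = np.asarray(matrix, dtype=float)
    t = np.asarray(target, dtype=float)
    if x.ndim != 2 or x.shape[0] != t.size:
        raise SpectrumDomainError("matrix rows must match target length")
    if x.shape[0] < 3:
        raise SpectrumDomainError("feature correlation needs >= 3 samples")
    tc = t - t.mean()
    st = float(np.sqrt(np.sum(tc**2)))
    if st == 0:
        raise SpectrumDomainError("target has zero variance")
    xc = x - x.mean(axis=0, keepdims=True)
    sx = np.sqrt(np.sum(xc**2, axis=0))
    constant = sx == 0
    sx_safe = np.where(constant, 1.0, sx)
    r = (xc.T @ tc) / (sx_safe * st)
    r[constant] = 0.0
    return r, constant
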