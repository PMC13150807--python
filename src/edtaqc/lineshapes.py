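"""Voigt lineshapes and multiplet geometry helpers.

The Voigt profile — the convolution of a Gaussian (field inhomogeneity,
shimming) and a Lorentzian (T2 relaxation) — is the standard model for
solution NMR peaks. It is evaluated exactly through the real part of the
Faddeeva function (``scipy.special.voigt_profile``), not as a pseudo-Voigt
sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import voigt_profile as _scipy_voigt

from .errors import SpectrumDomainError


@dataclass(frozen=True)
class VoigtPeak:
    """A single Voigt line.

    center: position (ppm); sigma_g: Gaussian width sigma (ppm);
    gamma_l: Lorentzian half-width at half maximum (ppm);
    area: integrated intensity (intensity x ppm).
    """

    center: float
    sigma_g: float
    gamma_l: float
    area: float

    def __post_init__(self) -> None:
        if self.sigma_g < 0 or self.gamma_l < 0:
            raise SpectrumDomainError("Voigt widths must be non-negative")
        if self.sigma_g == 0 and self.gamma_l == 0:
            raise SpectrumDomainError("Voigt peak needs sigma_g or gamma_l > 0")
        if not np.isfinite(self.area):
            raise SpectrumDomainError("Voigt area must be finite")

    @property
    def fwhm(self) -> float:
        """Approximate full width at half maximum (ppm), Olivero-Longbothum."""
        fl = 2.0 * self.gamma_l
        fg = 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.sigma_g
        return 0.5346 * fl + np.sqrt(0.2166 * fl**2 + fg**2)


def voigt_profile(x: np.ndarray, peak: VoigtPeak) -> np.ndarray:
    """Evaluate a Voigt peak on grid ``x``; unit-area profile scaled by area.

    The profile integrates to ``peak.area`` over (-inf, inf).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise SpectrumDomainError("empty evaluation grid")
    if peak.sigma_g == 0:
        # scipy handles sigma=0 as a pure Lorentzian, but do it explicitly
        g = peak.gamma_l
        return peak.area * g / (np.pi * ((x - peak.center) ** 2 + g**2))
    return peak.area * _scipy_voigt(x - peak.center, peak.sigma_g, peak.gamma_l)


def voigt_widths_for_fwhm(
    fwhm_ppm: float, gaussian_fraction: float = 0.43
) -> tuple[float, float]:
    """(sigma_g, gamma_l) giving a Voigt of the requested FWHM.

    ``gaussian_fraction`` is the share of the FWHM carried by the Gaussian
    component; the default mixes widths typical of well-shimmed serum
    spectra. Uses the Olivero-Longbothum inversion.
    """
    if not 0.0 <= gaussian_fraction < 1.0:
        raise SpectrumDomainError("gaussian_fraction must be in [0, 1)")
    fg = gaussian_fraction * fwhm_ppm
    # solve 0.5346 fl + sqrt(0.2166 fl^2 + fg^2) = fwhm for fl
    # => (fwhm - 0.5346 fl)^2 = 0.2166 fl^2 + fg^2, a quadratic in fl
    a = 0.5346**2 - 0.2166
    b = -2.0 * 0.5346 * fwhm_ppm
    c = fwhm_ppm**2 - fg**2
    fl = (-b - np.sqrt(b**2 - 4 * a * c)) / (2 * a)
    sigma_g = fg / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return float(sigma_g), float(fl / 2.0)


def ab_quartet_components(j_hz: float, dnu_hz: float) -> list[tuple[float, float]]:
    """Line offsets (Hz from system centre) and relative areas of an AB quartet.

    Two strongly coupled inequivalent protons with coupling ``j_hz`` and
    chemical-shift separation ``dnu_hz`` give four lines at
    +-(D+J)/2 and +-(D-J)/2 Hz (D = sqrt(dnu^2 + J^2)) with the familiar
    roof effect: outer lines weakened by (1 - J/D), inner strengthened by
    (1 + J/D). Relative areas sum to 1.
    """
    if j_hz <= 0 or dnu_hz < 0:
        raise SpectrumDomainError("AB quartet needs J > 0 and dnu >= 0")
    d = float(np.hypot(dnu_hz, j_hz))
    outer, inner = (1.0 - j_hz / d) / 4.0, (1.0 + j_hz / d) / 4.0
    return [
        (-(d + j_hz) / 2.0, outer),
        (-(d - j_hz) / 2.0, inner),
        ((d - j_hz) / 2.0, inner),
        ((d + j_hz) / 2.0, outer),
    ]


def measure_fwhm(ppm: np.ndarray, intensity: np.ndarray, apex_ppm: float,
                 baseline: float = 0.0) -> float:
    """FWHM (ppm) of the peak whose apex is nearest ``apex_ppm``.

    Walks outward from the apex to the half-maximum crossings with linear
    interpolation between grid points; ``baseline`` is subtracted first.
    """
    y = np.asarray(intensity, dtype=float) - baseline
    i0 = int(np.argmin(np.abs(np.asarray(ppm) - apex_ppm)))
    # climb to the true local apex
    while 0 < i0 < y.size - 1:
        if y[i0 + 1] > y[i0]:
            i0 += 1
        elif y[i0 - 1] > y[i0]:
            i0 -= 1
        else:
            break
    half = y[i0] / 2.0
    if half <= 0:
        raise SpectrumDomainError("no positive apex for FWHM measurement")

    def _cross(direction: int) -> float:
        i = i0
        while 0 < i + direction < y.size and y[i + direction] > half:
            i += direction
        j = i + direction
        if j < 0 or j >= y.size:
            raise SpectrumDomainError("half-maximum crossing off the axis")
        frac = (y[i] - half) / (y[i] - y[j])
        return float(ppm[i] + frac * (ppm[j] - ppm[i]))

    return abs(_cross(1) - _cross(-1))
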