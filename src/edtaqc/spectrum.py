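"""The 1D spectrum container and the low-level spectral utilities.

A :class:`Spectrum1D` holds a processed (Fourier-transformed, phased,
baseline-corrected) 1D proton spectrum: a chemical-shift axis in ppm
(stored descending, the NMR display convention), the real-part
intensities, and the acquisition metadata the quantification equations
need (spectrometer 1H frequency, receiver gain, number of scans).

All ppm intervals throughout the package are given as ``(low, high)``
pairs regardless of axis direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import SpectrumDomainError

#: Default spectral region used for noise estimation (ppm): a signal-free
#: segment downfield of every resonance in serum/plasma spectra.
DEFAULT_NOISE_REGION = (13.0, 14.0)


@dataclass
class Spectrum1D:
    """A processed 1D 1H NMR spectrum.

    Parameters
    ----------
    ppm_axis:
        Chemical shift per point (ppm), strictly monotone. Stored
        descending; an ascending input is flipped together with the
        intensities.
    intensity:
        Real-part intensity per point (arbitrary units).
    field_mhz:
        1H Larmor frequency of the spectrometer (MHz).
    receiver_gain:
        Dimensionless receiver gain the spectrum was acquired with.
    num_scans:
        Number of accumulated scans.
    label:
        Sample identifier.
    metadata:
        Free-form key/value store. The key ``rg_applied`` records whether
        the intensities have already been divided by the receiver gain.
    """

    ppm_axis: np.ndarray
    intensity: np.ndarray
    field_mhz: float
    receiver_gain: float = 1.0
    num_scans: int = 32
    label: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm_axis = np.asarray(self.ppm_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm_axis.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumDomainError("ppm_axis and intensity must be 1-D")
        if self.ppm_axis.size != self.intensity.size or self.ppm_axis.size < 2:
            raise SpectrumDomainError(
                "ppm_axis and intensity must have equal length >= 2"
            )
        d = np.diff(self.ppm_axis)
        if np.all(d > 0):  # ascending input: flip to the display convention
            self.ppm_axis = self.ppm_axis[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d < 0):
            raise SpectrumDomainError("ppm_axis must be strictly monotone")
        if not self.field_mhz > 0:
            raise SpectrumDomainError("field_mhz must be positive")
        if not self.receiver_gain > 0:
            raise SpectrumDomainError("receiver_gain must be positive")
        if int(self.num_scans) < 1:
            raise SpectrumDomainError("num_scans must be >= 1")
        self.num_scans = int(self.num_scans)

    # -- geometry helpers -------------------------------------------------

    @property
    def n_points(self) -> int:
        return self.ppm_axis.size

    @property
    def dppm(self) -> float:
        """Absolute point spacing in ppm (grid assumed uniform)."""
        return float(abs(np.median(np.diff(self.ppm_axis))))

    def region_slice(self, low: float, high: float) -> slice:
        """Index slice covering ``[low, high]`` ppm on the descending axis."""
        if low > high:
            low, high = high, low
        # axis is descending: high ppm sits at small indices
        start = int(np.searchsorted(-self.ppm_axis, -high, side="left"))
        stop = int(np.searchsorted(-self.ppm_axis, -low, side="right"))
        return slice(start, stop)

    def contains_region(self, low: float, high: float) -> bool:
        lo_ax = float(self.ppm_axis[-1])
        hi_ax = float(self.ppm_axis[0])
        if low > high:
            low, high = high, low
        return low >= lo_ax and high <= hi_ax

    def copy(self) -> "Spectrum1D":
        return replace(
            self,
            ppm_axis=self.ppm_axis.copy(),
            intensity=self.intensity.copy(),
            metadata=dict(self.metadata),
        )

    def scaled(self, k: float) -> "Spectrum1D":
        out = self.copy()
        out.intensity *= k
        return out


def estimate_noise(
    spectrum: Spectrum1D,
    region: tuple[float, float] = DEFAULT_NOISE_REGION,
) -> float:
    """Noise level sigma_f: sample standard deviation of a signal-free region.

    The default region is 13.0-14.0 ppm, downfield of all serum/plasma
    resonances.

    Raises
    ------
    SpectrumDomainError
        If the region lies outside the axis or holds fewer than 16 points.
    """
    low, high = min(region), max(region)
    if not spectrum.contains_region(low, high):
        raise SpectrumDomainError(
            f"noise region ({low}, {high}) lies outside the ppm axis"
        )
    seg = spectrum.intensity[spectrum.region_slice(low, high)]
    if seg.size < 16:
        raise SpectrumDomainError(
            f"noise region holds {seg.size} points; >= 16 required"
        )
    return float(np.std(seg, ddof=1))


def bin_and_center(
    spectra: list[Spectrum1D],
    bin_width: float = 0.02,
    region: tuple[float, float] | None = None,
    center: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate spectra into uniform ppm bins and mean-center the columns.

    Each bin value is the integral (sum of intensities x point spacing)
    of the points whose ppm falls in the half-open bin; bins run from the
    high-ppm end of ``region`` downward (``[hi, lo)`` half-open, matching
    the descending axis), with edges aligned to the region start.

    Returns
    -------
    (matrix, centers):
        ``matrix`` is samples x bins; ``centers`` the bin centres in ppm
        (descending).
    """
    if not spectra:
        raise SpectrumDomainError("no spectra given")
    if not bin_width > 0:
        raise SpectrumDomainError("bin_width must be positive")
    f0 = spectra[0].field_mhz
    if any(abs(s.field_mhz - f0) > 1e-9 for s in spectra):
        raise SpectrumDomainError(
            "bin_and_center requires all spectra to share field_mhz"
        )
    if region is None:
        low = max(float(s.ppm_axis[-1]) for s in spectra)
        high = min(float(s.ppm_axis[0]) for s in spectra)
    else:
        low, high = min(region), max(region)
    n_bins = int(np.floor((high - low) / bin_width + 1e-9))
    if n_bins < 1:
        raise SpectrumDomainError("region narrower than one bin")
    edges_hi = high - bin_width * np.arange(n_bins)
    centers = edges_hi - bin_width / 2.0

    matrix = np.empty((len(spectra), n_bins))
    for i, sp in enumerate(spectra):
        # bin index for each point: half-open [hi, lo) downward from `high`
        idx = np.floor((high - sp.ppm_axis) / bin_width).astype(int)
        ok = (idx >= 0) & (idx < n_bins)
        matrix[i] = np.bincount(
            idx[ok], weights=sp.intensity[ok], minlength=n_bins
        ) * sp.dppm
    if center:
        matrix = matrix - matrix.mean(axis=0, keepdims=True)
    return matrix, centers
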