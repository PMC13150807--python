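"""Synthetic serum/plasma-EDTA spectrum generator with known ground truth.

The generator emulates the features of 1D 1H serum/plasma-EDTA spectra
the pipeline must cope with:

* the glucose anomeric doublet used as the assignment anchor;
* two free-EDTA singlets (the downfield 8H acetate singlet is the
  normalization reference), the Ca-EDTA singlet + AB quartet, the
  Mg-EDTA singlet, and the Zn-EDTA singlet + quartet;
* the asparagine CH2 doublet of doublets crowding the same region;
* a broad macromolecule baseline (sum of up to three very broad
  Gaussians) whose amplitude varies sample to sample;
* white Gaussian noise;
* sample-to-sample chemical-shift covariation driven by a single latent
  physicochemical variable ``u ~ N(0, 1)`` — every species' centre is an
  affine function of ``u`` plus small independent jitter, which is what
  makes chained linear shift-prediction models work.

Concentrations are in-tube values (serum diluted 1:1 with buffer). The
total EDTA in the tube defaults to 2.8245 mM (5.649 mM buffer diluted by
half), and free EDTA is the total minus whatever the metals chelate.

Instrument model: peak areas scale with field^(3/2), receiver gain and
number of scans; noise scales with gain and sqrt(scans). By default the
virtual spectrometers at different fields are sensitivity-matched (equal
SNR — e.g. a cryoprobe on the lower-field instrument), so the noise also
carries the field^(3/2) factor; ``snr_mode="constant_noise"`` keeps the
noise floor field-independent instead, making the instrument-sensitivity
correction of the quantification equations non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SpectrumDomainError
from .lineshapes import VoigtPeak, voigt_profile, voigt_widths_for_fwhm
from .spectrum import Spectrum1D
from .templates import SpinSystemTemplate, default_template_db

#: total EDTA in the NMR tube (mM): 5.649 mM buffer diluted 1:1 with sample
TOTAL_EDTA_MM = 5.649 / 2.0

REFERENCE_FIELD_MHZ = 600.13

#: chemical-shift sensitivity to the latent condition variable (ppm per unit)
DELTA_SENSITIVITY = {
    "glucose_anomeric": 0.0040,
    "free_edta_1": 0.0030,
    "free_edta_2": 0.0028,
    "ca_edta_singlet": 0.0044,
    "ca_edta_quartet": 0.0048,
    "mg_edta_singlet": 0.0036,
    "zn_edta_singlet": 0.0050,
    "zn_edta_quartet": 0.0052,
    "asparagine_dd": 0.0020,
    "lactate_ch3": 0.0010,
    "alanine_ch3": 0.0012,
}

#: concentration keys -> the species rendered from them
SPECIES_OF = {
    "glucose": ("glucose_anomeric",),
    "free_edta": ("free_edta_1", "free_edta_2"),
    "ca": ("ca_edta_singlet", "ca_edta_quartet"),
    "mg": ("mg_edta_singlet",),
    "zn": ("zn_edta_singlet", "zn_edta_quartet"),
    "asparagine": ("asparagine_dd",),
    "lactate": ("lactate_ch3",),
    "alanine": ("alanine_ch3",),
}

#: physiological in-tube concentration ranges (mM), serum diluted 1:1;
#: metal ranges anchor to adult blood reference intervals
DEFAULT_RANGES = {
    "ca": (1.05, 1.30),
    "mg": (0.35, 0.50),
    "zn": (0.0045, 0.0090),
    "glucose": (1.75, 4.00),
    "asparagine": (0.015, 0.035),
    "lactate": (0.50, 1.50),
    "alanine": (0.15, 0.40),
}

#: broad macromolecule background: (centre ppm, sigma ppm, amplitude)
DEFAULT_BASELINE = ((0.95, 0.35, 3.0), (2.10, 0.50, 2.5), (4.05, 0.40, 2.0))


def make_composition(ca: float, mg: float, zn: float,
                     total_edta: float = TOTAL_EDTA_MM,
                     glucose: float = 2.5, asparagine: float = 0.025,
                     lactate: float = 1.0, alanine: float = 0.25,
                     ) -> dict[str, float]:
    """In-tube composition with free EDTA closing the EDTA mass balance."""
    chelated = ca + mg + zn
    if chelated > total_edta:
        raise SpectrumDomainError(
            f"chelated metals ({chelated:.3f} mM) exceed total EDTA "
            f"({total_edta:.3f} mM)")
    return {
        "glucose": glucose, "free_edta": total_edta - chelated,
        "ca": ca, "mg": mg, "zn": zn, "asparagine": asparagine,
        "lactate": lactate, "alanine": alanine,
    }


@dataclass
class GeneratorConfig:
    """Composition plus acquisition settings for one synthetic sample."""

    concentrations: dict[str, float] = field(
        default_factory=lambda: make_composition(ca=1.20, mg=0.45, zn=0.007))
    field_mhz: float = REFERENCE_FIELD_MHZ
    ppm_range: tuple[float, float] = (-1.5, 14.5)
    n_points: int = 49152
    receiver_gain: float = 1.0
    num_scans: int = 32
    fwhm_hz: float = 1.5
    gaussian_fraction: float = 0.43
    #: noise sd (intensity units) at the 600.13 MHz reference instrument
    noise_sd: float = 0.07
    snr_mode: str = "matched"  # or "constant_noise"
    latent_sd: float = 1.0
    jitter_sd: float = 1.5e-4
    baseline: tuple = DEFAULT_BASELINE
    baseline_variability: float = 0.12
    suppress_species: frozenset[str] = frozenset()
    templates: dict[str, SpinSystemTemplate] | None = None

    def __post_init__(self) -> None:
        for key, c in self.concentrations.items():
            if c < 0:
                raise SpectrumDomainError(f"negative concentration for {key}")
        if self.snr_mode not in ("matched", "constant_noise"):
            raise SpectrumDomainError(f"unknown snr_mode {self.snr_mode!r}")

    def db(self) -> dict[str, SpinSystemTemplate]:
        return self.templates if self.templates is not None else default_template_db()

    @property
    def area_scale(self) -> float:
        """Rendered area per (mM x proton): instrument response."""
        return ((self.field_mhz / REFERENCE_FIELD_MHZ) ** 1.5
                * self.receiver_gain * self.num_scans / 32.0)

    @property
    def noise_scale(self) -> float:
        s = self.receiver_gain * np.sqrt(self.num_scans / 32.0)
        if self.snr_mode == "matched":
            s *= (self.field_mhz / REFERENCE_FIELD_MHZ) ** 1.5
        return float(s)


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knew: the oracle for every downstream test."""

    concentrations: dict[str, float]
    centers: dict[str, float]           # true delta per rendered species (ppm)
    areas: dict[str, float]             # rendered multiplet area per species
    latent: float
    seed: int
    fwhm_hz: float
    field_mhz: float
    sigma_g_ppm: float
    gamma_l_ppm: float
    baseline_params: tuple              # ((centre, sigma, amplitude), ...)

    @property
    def fwhm_ppm(self) -> float:
        return self.fwhm_hz / self.field_mhz

    def total_edta(self) -> float:
        c = self.concentrations
        return c.get("free_edta", 0.0) + c.get("ca", 0.0) + c.get("mg", 0.0) \
            + c.get("zn", 0.0)


def _truth_peaks(config: GeneratorConfig, truth: SyntheticGroundTruth
                 ) -> list[VoigtPeak]:
    db = config.db()
    peaks = []
    for sp, area in truth.areas.items():
        if area <= 0:
            continue
        t = db[sp]
        c0 = truth.centers[sp]
        for off_hz, rel in t.components:
            peaks.append(VoigtPeak(
                center=c0 + off_hz / config.field_mhz,
                sigma_g=truth.sigma_g_ppm, gamma_l=truth.gamma_l_ppm,
                area=area * rel))
    return peaks


def render_truth_components(ppm: np.ndarray, config: GeneratorConfig,
                            truth: SyntheticGroundTruth) -> np.ndarray:
    """Sum of the ground-truth Voigt multiplets on ``ppm``."""
    y = np.zeros_like(np.asarray(ppm, dtype=float))
    for pk in _truth_peaks(config, truth):
        y += voigt_profile(ppm, pk)
    return y


def render_truth_baseline(ppm: np.ndarray,
                          truth: SyntheticGroundTruth) -> np.ndarray:
    ppm = np.asarray(ppm, dtype=float)
    y = np.zeros_like(ppm)
    for c, s, a in truth.baseline_params:
        y += a * np.exp(-0.5 * ((ppm - c) / s) ** 2)
    return y


def generate_spectrum(config: GeneratorConfig | None = None, seed: int = 0,
                      ) -> tuple[Spectrum1D, SyntheticGroundTruth]:
    """Render one synthetic spectrum and its ground truth.

    Identical ``(config, seed)`` give bit-identical output.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(seed)
    db = config.db()

    lo, hi = min(config.ppm_range), max(config.ppm_range)
    ppm = np.linspace(hi, lo, config.n_points)  # descending

    u = rng.normal(0.0, config.latent_sd)
    sigma_g, gamma_l = voigt_widths_for_fwhm(
        config.fwhm_hz / config.field_mhz, config.gaussian_fraction)

    centers: dict[str, float] = {}
    areas: dict[str, float] = {}
    k = config.area_scale
    # draw per-species jitter in a fixed (sorted) species order for
    # seed-stable output regardless of dict insertion order
    for key in sorted(config.concentrations):
        conc = config.concentrations[key]
        for sp in SPECIES_OF[key]:
            t = db[sp]
            jitter = rng.normal(0.0, config.jitter_sd)
            centers[sp] = (t.default_center
                           + DELTA_SENSITIVITY.get(sp, 0.0) * u + jitter)
            suppressed = sp in config.suppress_species
            areas[sp] = 0.0 if (suppressed or conc <= 0) else conc * t.n_protons * k

    amp_scale = max(0.3, 1.0 + rng.normal(0.0, config.baseline_variability))
    baseline_params = tuple((c, s, a * amp_scale * k)
                            for c, s, a in config.baseline)

    truth = SyntheticGroundTruth(
        concentrations=dict(config.concentrations), centers=centers,
        areas=areas, latent=float(u), seed=int(seed),
        fwhm_hz=config.fwhm_hz, field_mhz=config.field_mhz,
        sigma_g_ppm=float(sigma_g),
        gamma_l_ppm=float(gamma_l), baseline_params=baseline_params)

    y = render_truth_components(ppm, config, truth)
    y += render_truth_baseline(ppm, truth)
    noise_sd = config.noise_sd * config.noise_scale
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=ppm.size)

    spectrum = Spectrum1D(
        ppm_axis=ppm, intensity=y, field_mhz=config.field_mhz,
        receiver_gain=config.receiver_gain, num_scans=config.num_scans,
        label=f"synthetic-{seed}",
        metadata={"rg_applied": config.receiver_gain == 1.0,
                  "seed": int(seed)},
    )
    return spectrum, truth


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def generate_cohort(n: int, ranges: dict | None = None, seed: int = 0,
                    config: GeneratorConfig | None = None,
                    zn_dropout: float = 0.06,
                    total_edta: float = TOTAL_EDTA_MM,
                    ) -> list[tuple[Spectrum1D, SyntheticGroundTruth]]:
    """Draw ``n`` samples with concentrations uniform over ``ranges``.

    A fraction ``zn_dropout`` of samples gets Zn below the detection
    threshold (emulating the minority of real samples where Zn-EDTA is
    unrecoverable).
    """
    if n < 1:
        raise SpectrumDomainError("cohort size must be >= 1")
    base = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(seed)
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    out = []
    for child in _child_seeds(seed, n):
        draw = {key: float(rng.uniform(*ranges[key])) for key in sorted(ranges)}
        if zn_dropout > 0 and rng.random() < zn_dropout:
            draw["zn"] = float(rng.uniform(0.0, 1e-4))
        comp = make_composition(
            ca=draw["ca"], mg=draw["mg"], zn=draw["zn"],
            total_edta=total_edta, glucose=draw["glucose"],
            asparagine=draw["asparagine"], lactate=draw["lactate"],
            alanine=draw["alanine"])
        out.append(generate_spectrum(replace(base, concentrations=comp),
                                     seed=child))
    return out


def generate_delta_table(n: int, seed: int = 0,
                         config: GeneratorConfig | None = None) -> pd.DataFrame:
    """True chemical shifts for ``n`` latent draws, without rendering spectra.

    One row per sample, one column per species — the training table for
    the chained shift-prediction models.
    """
    if config is None:
        config = GeneratorConfig()
    db = config.db()
    rng = np.random.default_rng(seed)
    rows = []
    species = [sp for key in sorted(SPECIES_OF) for sp in SPECIES_OF[key]
               if sp in db]
    for _ in range(n):
        u = rng.normal(0.0, config.latent_sd)
        rows.append({
            sp: db[sp].default_center + DELTA_SENSITIVITY.get(sp, 0.0) * u
            + rng.normal(0.0, config.jitter_sd)
            for sp in species
        })
    return pd.DataFrame(rows)
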