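"""Chained chemical-shift prediction models and anchored peak assignment.

In blood spectra, chemical shifts are not constants: pH, ionic strength
and overall composition move every resonance, and they move together.
The shifts of the metal-EDTA spin systems are therefore predictable by
linear models chained off a single anchor — the glucose anomeric doublet,
present in essentially every serum/plasma sample.

The assignment loop applies the trained models in a configured order
(glucose -> Ca-EDTA quartet -> Ca-EDTA singlet -> Mg-EDTA singlet, plus
glucose-anchored models for the Zn systems and free EDTA). Each model's
prediction opens a search window narrower than two line widths, inside
which the observed local maximum is taken — so every step re-anchors on
an actual spectral feature and prediction errors do not propagate. When a
primary model fails to find a qualifying maximum (or its predictor was
itself unassigned), the glucose-anchored fallback model is applied with a
wider, 2.5-line-width window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (AnchorNotFoundError, DegenerateFitError,
                     SpectrumDomainError)
from .lineshapes import measure_fwhm
from .spectrum import Spectrum1D, estimate_noise

STATUS_ANCHOR = "anchor"
STATUS_ASSIGNED = "assigned"
STATUS_FALLBACK = "fallback_assigned"
STATUS_BELOW_DETECTION = "below_detection"


# ---------------------------------------------------------------------------
# shift-prediction models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShiftModel:
    """One linear delta -> delta prediction model (OLS fit)."""

    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    rrmse: float          # root-mean-square residual, absolute ppm
    n_train: int

    def predict(self, delta: float) -> float:
        return self.slope * delta + self.intercept


def fit_shift_model(x, y, predictor: str = "x", response: str = "y"
                    ) -> ShiftModel:
    """Ordinary least squares ``y = slope * x + intercept``.

    ``r_squared`` and ``rrmse`` (root mean squared residual, in ppm) are
    computed on the training data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateFitError("need equal-length x, y with n >= 3")
    if np.ptp(x) <= 0:
        raise DegenerateFitError("constant predictor")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst
    rrmse = float(np.sqrt(np.mean(resid**2)))
    return ShiftModel(predictor, response, float(slope), float(intercept),
                      float(max(0.0, min(1.0, r2))), rrmse, int(x.size))


@dataclass(frozen=True)
class ChainStep:
    target: str
    primary: str                 # model id
    fallback: str | None = None  # glucose-anchored model id


@dataclass
class ModelChain:
    """A set of shift models plus the order they are applied in."""

    models: dict[str, ShiftModel]
    steps: list[ChainStep]
    anchor_species: str = "glucose_anomeric"

    def model_for(self, model_id: str) -> ShiftModel:
        return self.models[model_id]


#: model id -> (predictor species, response species); the lettered chain
#: follows the configured assignment order, each step anchored to the
#: previously assigned feature, with glucose-anchored fallbacks.
DEFAULT_EDGES = {
    "E1": ("glucose_anomeric", "free_edta_1"),
    "E2": ("free_edta_1", "free_edta_2"),
    "E2_fb": ("glucose_anomeric", "free_edta_2"),
    "A": ("glucose_anomeric", "ca_edta_quartet"),
    "B": ("ca_edta_quartet", "ca_edta_singlet"),
    "B_fb": ("glucose_anomeric", "ca_edta_singlet"),
    "C": ("ca_edta_singlet", "mg_edta_singlet"),
    "C_fb": ("glucose_anomeric", "mg_edta_singlet"),
    "D1": ("glucose_anomeric", "zn_edta_singlet"),
    "D2": ("glucose_anomeric", "zn_edta_quartet"),
}

DEFAULT_STEPS = [
    ChainStep("free_edta_1", "E1", None),
    ChainStep("free_edta_2", "E2", "E2_fb"),
    ChainStep("ca_edta_quartet", "A", None),
    ChainStep("ca_edta_singlet", "B", "B_fb"),
    ChainStep("mg_edta_singlet", "C", "C_fb"),
    ChainStep("zn_edta_singlet", "D1", None),
    ChainStep("zn_edta_quartet", "D2", None),
]


def train_model_chain(delta_table: pd.DataFrame,
                      edges: dict[str, tuple[str, str]] | None = None,
                      steps: list[ChainStep] | None = None) -> ModelChain:
    """Fit every model of the chain from a per-sample table of shifts.

    ``delta_table`` has one row per training sample and one column per
    species (ppm). Edges whose species are absent are skipped, and steps
    referring to missing models are dropped.
    """
    edges = edges if edges is not None else DEFAULT_EDGES
    steps = steps if steps is not None else DEFAULT_STEPS
    models = {}
    for mid, (px, py) in edges.items():
        if px in delta_table.columns and py in delta_table.columns:
            models[mid] = fit_shift_model(
                delta_table[px].to_numpy(), delta_table[py].to_numpy(),
                predictor=px, response=py)
    kept = [s for s in steps if s.primary in models]
    kept = [ChainStep(s.target, s.primary,
                      s.fallback if s.fallback in models else None)
            for s in kept]
    return ModelChain(models=models, steps=kept)


def save_model_chain(chain: ModelChain, path) -> None:
    payload = {
        "anchor_species": chain.anchor_species,
        "models": {mid: vars(m) for mid, m in chain.models.items()},
        "steps": [vars(s) for s in chain.steps],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model_chain(path) -> ModelChain:
    payload = json.loads(Path(path).read_text())
    models = {mid: ShiftModel(**d) for mid, d in payload["models"].items()}
    steps = [ChainStep(**d) for d in payload["steps"]]
    return ModelChain(models=models, steps=steps,
                      anchor_species=payload.get("anchor_species",
                                                 "glucose_anomeric"))


# ---------------------------------------------------------------------------
# peak picking
# ---------------------------------------------------------------------------

def derivative_enhance(spectrum: Spectrum1D, smooth_window: int = 0
                       ) -> np.ndarray:
    """Magnitude of the numerical first derivative of the intensity.

    Sharp peaks (derivative ~ height / width) are enhanced relative to
    broad macromolecule features of comparable height; a smooth offset
    vanishes entirely. ``smooth_window`` > 1 applies a boxcar average
    first.
    """
    if spectrum.n_points < 3:
        raise SpectrumDomainError("derivative enhancement needs >= 3 points")
    y = spectrum.intensity
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    return np.abs(np.gradient(y))


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima."""
    if y.size < 3:
        return np.array([], dtype=int)
    idx = np.nonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]))[0] + 1
    return idx


def _parabolic_refine(ppm: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-grid apex position by a 3-point parabola around grid maximum."""
    if i <= 0 or i >= y.size - 1:
        return float(ppm[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom >= 0:
        return float(ppm[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    return float(ppm[i] + shift * (ppm[min(i + 1, y.size - 1)] - ppm[i]))


def _local_floor(spectrum: Spectrum1D, low: float, high: float,
                 inflate: float = 5.0) -> float:
    """Robust local intensity floor: 25th percentile of a context band
    around the window (the broad-baseline level peaks must rise above)."""
    half = (high - low) / 2.0
    mid = (high + low) / 2.0
    ctx = spectrum.region_slice(mid - inflate * half, mid + inflate * half)
    seg = spectrum.intensity[ctx]
    if seg.size == 0:
        return 0.0
    return float(np.percentile(seg, 25))


def find_glucose_anchor(spectrum: Spectrum1D,
                        search_region: tuple[float, float] = (5.10, 5.40),
                        j_hz: float = 3.8,
                        j_tolerance: float = 0.20,
                        noise_sigma: float | None = None) -> float:
    """Locate the glucose anomeric doublet and return its midpoint (ppm).

    Candidate apexes are local maxima with prominence of at least 5 sigma
    (noise ripples riding on a peak shoulder do not qualify); pairs
    separated by ``j_hz`` (in ppm: J / field) within the relative
    tolerance whose line intensities match within a factor of three (the
    anomeric doublet has 1:1 lines) qualify, and the highest-intensity
    pair wins.
    """
    low, high = min(search_region), max(search_region)
    if not spectrum.contains_region(low, high):
        raise SpectrumDomainError("anchor search region outside the axis")
    if noise_sigma is None:
        noise_sigma = _default_noise(spectrum, low, high)
    sl = spectrum.region_slice(low, high)
    ppm = spectrum.ppm_axis[sl]
    y = spectrum.intensity[sl]

    idx, _ = find_peaks(y, prominence=5.0 * noise_sigma)
    idx = list(idx)
    j_ppm = j_hz / spectrum.field_mhz
    best, best_score = None, -np.inf
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            ia, ib = idx[a], idx[b]
            sep = abs(ppm[ia] - ppm[ib])
            if abs(sep - j_ppm) > j_tolerance * j_ppm:
                continue
            lines = sorted((y[ia], y[ib]))
            if lines[0] < lines[1] / 3.0:  # doublet lines are ~1:1
                continue
            score = y[ia] + y[ib]
            if score > best_score:
                best, best_score = (ia, ib), score
    if best is None:
        raise AnchorNotFoundError(
            f"no doublet with J = {j_hz} Hz (+-{j_tolerance:.0%}) in "
            f"({low}, {high}) ppm")
    pa = _parabolic_refine(ppm, y, best[0])
    pb = _parabolic_refine(ppm, y, best[1])
    return (pa + pb) / 2.0


def _default_noise(spectrum: Spectrum1D, low: float, high: float) -> float:
    try:
        return estimate_noise(spectrum)
    except SpectrumDomainError:
        # axis does not span the default noise region; fall back to a
        # robust estimate from first differences near the search region
        sl = spectrum.region_slice(low - 0.5, high + 0.5)
        d = np.diff(spectrum.intensity[sl])
        return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))


def assign_peak(spectrum: Spectrum1D, predicted: float, window_lw: float,
                line_width_ppm: float, noise_sigma: float
                ) -> tuple[float | None, str]:
    """Pick the observed maximum for a predicted shift.

    The search window is ``window_lw`` line widths wide, centred at the
    prediction. Local maxima exceeding 3 sigma — operationalized as
    prominence >= 3 sigma AND height >= 3 sigma above the local median, so
    that neither the broad macromolecule baseline nor isolated noise
    ripples trigger detections — qualify; the one nearest the prediction
    wins (tie: higher intensity), refined by 3-point parabolic
    interpolation. Returns ``(delta, "assigned")`` or
    ``(None, "below_detection")``.
    """
    half = window_lw * line_width_ppm / 2.0
    low, high = predicted - half, predicted + half
    if not spectrum.contains_region(low, high):
        raise SpectrumDomainError("search window outside the ppm axis")
    # pad the evaluation slice so an apex at the window rim still has
    # neighbours for the prominence test; the apex itself must lie inside
    pad = max(0.5 * line_width_ppm, 3 * spectrum.dppm)
    sl = spectrum.region_slice(max(low - pad, spectrum.ppm_axis[-1]),
                               min(high + pad, spectrum.ppm_axis[0]))
    ppm = spectrum.ppm_axis[sl]
    y = spectrum.intensity[sl]

    # a qualifying maximum must both be prominent and rise 3 sigma above
    # the local level (the median of the padded slice); either criterion
    # alone admits too many pure-noise ripples
    level = float(np.median(y))
    cand, _ = find_peaks(y, prominence=3.0 * noise_sigma)
    cand = [i for i in cand
            if low <= ppm[i] <= high and y[i] >= level + 3.0 * noise_sigma]
    if not cand:
        return None, STATUS_BELOW_DETECTION
    cand.sort(key=lambda i: (abs(ppm[i] - predicted), -y[i]))
    i = cand[0]
    # refine on the full axis so the parabola can use out-of-window points
    gi = sl.start + i
    delta = _parabolic_refine(spectrum.ppm_axis, spectrum.intensity, gi)
    return delta, STATUS_ASSIGNED


# ---------------------------------------------------------------------------
# full-chain assignment
# ---------------------------------------------------------------------------

@dataclass
class Assignment:
    species: str
    assigned: float | None
    predicted: float
    model_id: str | None
    window_lw: float
    status: str


@dataclass
class AssignmentResult:
    """Per spin system: assigned/predicted shift, model used, status."""

    anchor: float
    line_width_ppm: float
    noise_sigma: float
    records: dict[str, Assignment] = field(default_factory=dict)

    def delta(self, species: str) -> float | None:
        if species == "glucose_anomeric":
            return self.anchor
        rec = self.records.get(species)
        return rec.assigned if rec else None

    def status(self, species: str) -> str:
        if species == "glucose_anomeric":
            return STATUS_ANCHOR
        rec = self.records.get(species)
        return rec.status if rec else STATUS_BELOW_DETECTION

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records.values()])


#: primary windows stay under 2 line widths; fallback widens to 2.5
PRIMARY_WINDOW_CAP_LW = 1.9
FALLBACK_WINDOW_LW = 2.5


def _primary_window_lw(rrmse: float, line_width_ppm: float) -> float:
    """Window width (in line widths): the model's rRMSE defines it, floored
    at one line width and capped below two."""
    half = max(rrmse, 0.5 * line_width_ppm)
    half = min(half, PRIMARY_WINDOW_CAP_LW * line_width_ppm / 2.0)
    return 2.0 * half / line_width_ppm


def assign_all_species(spectrum: Spectrum1D, chain: ModelChain,
                       anchor: float,
                       noise_sigma: float | None = None,
                       line_width_ppm: float | None = None,
                       default_fwhm_hz: float = 1.5) -> AssignmentResult:
    """Run the model chain, re-anchoring each step on the found peak.

    Assignment failures become statuses (``fallback_assigned`` /
    ``below_detection``), never exceptions.
    """
    if noise_sigma is None:
        noise_sigma = estimate_noise(spectrum)
    lw = line_width_ppm or default_fwhm_hz / spectrum.field_mhz

    assigned: dict[str, float] = {chain.anchor_species: anchor}
    ok_status = {STATUS_ANCHOR, STATUS_ASSIGNED, STATUS_FALLBACK}
    result = AssignmentResult(anchor=anchor, line_width_ppm=lw,
                              noise_sigma=noise_sigma)

    def _try(model_id: str, window_lw: float):
        model = chain.model_for(model_id)
        pred_x = assigned.get(model.predictor)
        if pred_x is None:
            return None, None, None
        predicted = model.predict(pred_x)
        try:
            delta, status = assign_peak(spectrum, predicted, window_lw, lw,
                                        noise_sigma)
        except SpectrumDomainError:
            return predicted, None, STATUS_BELOW_DETECTION
        return predicted, delta, status

    first_measured = False
    for step in chain.steps:
        window = _primary_window_lw(chain.model_for(step.primary).rrmse, lw)
        predicted, delta, status = _try(step.primary, window)
        model_used = step.primary
        if delta is None and step.fallback is not None:
            p2, d2, s2 = _try(step.fallback, FALLBACK_WINDOW_LW)
            if d2 is not None:
                predicted, delta, status = p2, d2, STATUS_FALLBACK
                model_used, window = step.fallback, FALLBACK_WINDOW_LW
            elif predicted is None:
                predicted, status = p2, s2
        if delta is not None:
            assigned[step.target] = delta
            if status is None or status == STATUS_ASSIGNED:
                status = (STATUS_ASSIGNED if model_used == step.primary
                          else STATUS_FALLBACK)
        else:
            status = STATUS_BELOW_DETECTION
        result.records[step.target] = Assignment(
            species=step.target, assigned=delta,
            predicted=predicted if predicted is not None else np.nan,
            model_id=model_used, window_lw=window, status=status)

        # the free-EDTA reference singlet is always present: once assigned,
        # measure the spectrum's own line width and use it from then on
        if (not first_measured and step.target == "free_edta_1"
                and delta is not None):
            try:
                lw_meas = measure_fwhm(
                    spectrum.ppm_axis, spectrum.intensity, delta,
                    baseline=_local_floor(spectrum, delta - 10 * lw,
                                          delta + 10 * lw))
                if 0.2 * lw < lw_meas < 5.0 * lw:
                    lw = lw_meas
                    result.line_width_ppm = lw
            except SpectrumDomainError:
                pass
            first_measured = True

    return result
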