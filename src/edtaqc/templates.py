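"""Spin-system fingerprint templates.

Each species the pipeline handles — the two free-EDTA singlets, the
Ca/Mg/Zn-EDTA complex signals, the glucose anomeric doublet used as the
assignment anchor, and the asparagine CH2 doublet of doublets that
overlaps the crowded EDTA region — is described by a
:class:`SpinSystemTemplate`: a list of line offsets *in Hz* from the
system centre with relative areas summing to 1. Offsets are stored in Hz
so multiplet geometry is field-independent (and shrinks in ppm as the
field grows); they are converted to ppm by dividing by the spectrometer
frequency at evaluation time.

The default centres below are configurable database entries, not
contracts: only the relative geometry matters to the algorithms. They
place every EDTA-related signal inside the crowded 2.5-3.7 ppm window of
serum/plasma spectra, with the glucose anchor at 5.233 ppm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import ConfigurationError
from .lineshapes import ab_quartet_components

#: species groups used by quantification and QC cleanup
GROUP_FREE_EDTA = "free_edta"
GROUP_METAL = {"ca": "Ca", "mg": "Mg", "zn": "Zn"}

EDTA_SPECIES = (
    "free_edta_1", "free_edta_2",
    "ca_edta_singlet", "ca_edta_quartet",
    "mg_edta_singlet",
    "zn_edta_singlet", "zn_edta_quartet",
)

#: 4H singlet of each complex used for ion quantification
ION_SINGLET = {"Ca": "ca_edta_singlet", "Mg": "mg_edta_singlet",
               "Zn": "zn_edta_singlet"}


@dataclass(frozen=True)
class SpinSystemTemplate:
    """A species' multiplet fingerprint.

    components: (offset from the system centre in Hz, relative area);
    relative areas sum to 1. ``reference`` flags the free-EDTA peak used
    as the sensitivity/normalization reference ("peak1").
    """

    species: str
    components: tuple[tuple[float, float], ...]
    n_protons: int
    default_center: float
    group: str = "metabolite"
    reference: bool = False

    def __post_init__(self) -> None:
        if self.n_protons < 1:
            raise ConfigurationError("n_protons must be >= 1")
        total = sum(a for _, a in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{self.species}: relative areas sum to {total}, not 1")

    def offsets_ppm(self, field_mhz: float) -> list[float]:
        return [off / field_mhz for off, _ in self.components]

    def span_ppm(self, field_mhz: float) -> tuple[float, float]:
        offs = self.offsets_ppm(field_mhz)
        return min(offs), max(offs)

    @property
    def is_edta(self) -> bool:
        return self.group in ("free_edta", "ca", "mg", "zn")

    def with_center(self, center: float) -> "SpinSystemTemplate":
        return replace(self, default_center=center)


def _singlet() -> tuple[tuple[float, float], ...]:
    return ((0.0, 1.0),)


def _doublet(j_hz: float) -> tuple[tuple[float, float], ...]:
    return ((-j_hz / 2.0, 0.5), (j_hz / 2.0, 0.5))


def _asn_dd(delta_hz: float = 48.0, j_gem: float = 16.9,
            j_a: float = 4.3, j_b: float = 7.6) -> tuple[tuple[float, float], ...]:
    """Asparagine beta-CH2: two diastereotopic protons, each a doublet of
    doublets (geminal coupling shared, vicinal couplings distinct)."""
    comps = []
    for centre, jv in ((-delta_hz / 2.0, j_a), (delta_hz / 2.0, j_b)):
        for sg in (-1.0, 1.0):
            for sv in (-1.0, 1.0):
                comps.append((centre + sg * j_gem / 2.0 + sv * jv / 2.0, 0.125))
    return tuple(comps)


def default_template_db() -> dict[str, SpinSystemTemplate]:
    """The built-in spin-system database."""
    db = {
        "glucose_anomeric": SpinSystemTemplate(
            "glucose_anomeric", _doublet(3.8), 1, 5.233, group="metabolite"),
        "free_edta_1": SpinSystemTemplate(  # acetate CH2, 8H — reference peak1
            "free_edta_1", _singlet(), 8, 3.600, group="free_edta",
            reference=True),
        "free_edta_2": SpinSystemTemplate(  # ethylenic CH2, 4H
            "free_edta_2", _singlet(), 4, 3.115, group="free_edta"),
        "ca_edta_singlet": SpinSystemTemplate(
            "ca_edta_singlet", _singlet(), 4, 2.550, group="ca"),
        "ca_edta_quartet": SpinSystemTemplate(
            "ca_edta_quartet",
            tuple(ab_quartet_components(16.2, 7.0)), 8, 3.095, group="ca"),
        "mg_edta_singlet": SpinSystemTemplate(
            "mg_edta_singlet", _singlet(), 4, 2.700, group="mg"),
        "zn_edta_singlet": SpinSystemTemplate(
            "zn_edta_singlet", _singlet(), 4, 2.600, group="zn"),
        "zn_edta_quartet": SpinSystemTemplate(
            "zn_edta_quartet",
            tuple(ab_quartet_components(16.8, 6.5)), 8, 3.300, group="zn"),
        "asparagine_dd": SpinSystemTemplate(
            "asparagine_dd", _asn_dd(), 2, 2.900, group="metabolite"),
        "lactate_ch3": SpinSystemTemplate(
            "lactate_ch3", _doublet(6.9), 3, 1.330, group="metabolite"),
        "alanine_ch3": SpinSystemTemplate(
            "alanine_ch3", _doublet(7.2), 3, 1.480, group="metabolite"),
    }
    return db


def reference_species(db: dict[str, SpinSystemTemplate]) -> str:
    """Name of the template flagged ``reference=True`` (free-EDTA peak1)."""
    for name, t in db.items():
        if t.reference:
            return name
    raise ConfigurationError("template database has no reference entry")


def save_template_db(db: dict[str, SpinSystemTemplate], path) -> None:
    payload = {
        name: {
            "species": t.species,
            "components": [list(c) for c in t.components],
            "n_protons": t.n_protons,
            "default_center": t.default_center,
            "group": t.group,
            "reference": t.reference,
        }
        for name, t in db.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_template_db(path) -> dict[str, SpinSystemTemplate]:
    payload = json.loads(Path(path).read_text())
    return {
        name: SpinSystemTemplate(
            species=d["species"],
            components=tuple(tuple(c) for c in d["components"]),
            n_protons=int(d["n_protons"]),
            default_center=float(d["default_center"]),
            group=d.get("group", "metabolite"),
            reference=bool(d.get("reference", False)),
        )
        for name, d in payload.items()
    }


# re-export for dataclass field typing convenience
__all__ = [
    "SpinSystemTemplate", "default_template_db", "reference_species",
    "save_template_db", "load_template_db", "EDTA_SPECIES", "ION_SINGLET",
    "field",
]
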