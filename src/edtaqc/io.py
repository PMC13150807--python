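"""Readers and writers for processed 1D spectra.

Three dialects are supported, the ones the pipeline meets in practice:

``tsv``
    Plain two-column tab-separated text (ppm, intensity) with ``# key: value``
    header comments carrying the acquisition metadata. Lossless round trip.
``jcamp``
    A minimal JCAMP-DX 5.00 single-spectrum file, AFFN ``(X++(Y..Y))``
    tables only (no SQZ/DIF compression).
``bruker_proc``
    A Bruker processed-data directory: the real part ``pdata/<proc>/1r``
    plus the parameter files ``procs``/``acqus``. Only the keys the
    pipeline needs are read (point count, spectral width, offset, field,
    receiver gain, number of scans); no raw FID handling.

Receiver-gain normalization: by default (``normalize_rg=True``) the
intensities are divided by the receiver gain at load time, so spectra
acquired at different gains are directly comparable. The metadata key
``rg_applied`` tracks whether this has been done, which makes the
operation idempotent across write/load cycles.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .spectrum import Spectrum1D

_META_KEYS = ("field_mhz", "receiver_gain", "num_scans", "label", "rg_applied")


def _apply_rg(spectrum: Spectrum1D, normalize_rg: bool) -> Spectrum1D:
    if normalize_rg and not spectrum.metadata.get("rg_applied", False):
        spectrum.intensity = spectrum.intensity / spectrum.receiver_gain
        spectrum.metadata["rg_applied"] = True
    return spectrum


# ---------------------------------------------------------------------------
# tsv dialect
# ---------------------------------------------------------------------------

def write_tsv(spectrum: Spectrum1D, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column text with metadata header comments."""
    lines = [
        f"# field_mhz: {spectrum.field_mhz!r}",
        f"# receiver_gain: {spectrum.receiver_gain!r}",
        f"# num_scans: {spectrum.num_scans}",
        f"# label: {spectrum.label}",
        f"# rg_applied: {bool(spectrum.metadata.get('rg_applied', False))}",
    ]
    body = "\n".join(
        f"{p:.17g}\t{y:.17g}"
        for p, y in zip(spectrum.ppm_axis, spectrum.intensity)
    )
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def load_tsv(
    path: str | os.PathLike,
    field_mhz: float | None = None,
    receiver_gain: float | None = None,
    num_scans: int | None = None,
    normalize_rg: bool = True,
) -> Spectrum1D:
    meta: dict = {}
    ppm, y = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*([\w_]+)\s*:\s*(.*)", line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            parts = line.split("\t")
            ppm.append(float(parts[0]))
            y.append(float(parts[1]))
    fmhz = field_mhz if field_mhz is not None else _float_or_none(meta.get("field_mhz"))
    if fmhz is None:
        raise ConfigurationError(
            f"{path}: field_mhz absent from file header and no override given"
        )
    rg = receiver_gain if receiver_gain is not None else _float_or_none(
        meta.get("receiver_gain"), 1.0)
    ns = num_scans if num_scans is not None else int(
        float(meta.get("num_scans", 32)))
    sp = Spectrum1D(
        ppm_axis=np.array(ppm),
        intensity=np.array(y),
        field_mhz=fmhz,
        receiver_gain=rg,
        num_scans=ns,
        label=meta.get("label", Path(path).stem),
        metadata={"rg_applied": meta.get("rg_applied", "False") == "True"},
    )
    return _apply_rg(sp, normalize_rg)


def _float_or_none(s, default=None):
    if s is None or s == "":
        return default
    return float(s)


# ---------------------------------------------------------------------------
# JCAMP-DX dialect (minimal, AFFN)
# ---------------------------------------------------------------------------

def write_jcamp(spectrum: Spectrum1D, path: str | os.PathLike) -> None:
    y = spectrum.intensity
    ymax = float(np.max(np.abs(y))) or 1.0
    yfactor = ymax / 2**30
    yi = np.round(y / yfactor).astype(np.int64)
    n = spectrum.n_points
    firstx, lastx = float(spectrum.ppm_axis[0]), float(spectrum.ppm_axis[-1])
    out = [
        "##TITLE= %s" % (spectrum.label or "spectrum"),
        "##JCAMP-DX= 5.00",
        "##DATA TYPE= NMR SPECTRUM",
        "##DATA CLASS= XYDATA",
        "##XUNITS= PPM",
        "##YUNITS= ARBITRARY UNITS",
        "##.OBSERVE FREQUENCY= %r" % spectrum.field_mhz,
        "##$RECEIVERGAIN= %r" % spectrum.receiver_gain,
        "##$NUMSCANS= %d" % spectrum.num_scans,
        "##$RGAPPLIED= %d" % int(spectrum.metadata.get("rg_applied", False)),
        "##FIRSTX= %r" % firstx,
        "##LASTX= %r" % lastx,
        "##NPOINTS= %d" % n,
        "##XFACTOR= 1.0",
        "##YFACTOR= %r" % yfactor,
        "##XYDATA= (X++(Y..Y))",
    ]
    per_line = 6
    dx = (lastx - firstx) / (n - 1)
    for i in range(0, n, per_line):
        chunk = yi[i:i + per_line]
        out.append(
            f"{firstx + i * dx:.6f} " + " ".join(str(int(v)) for v in chunk)
        )
    out.append("##END=")
    Path(path).write_text("\n".join(out) + "\n")


def load_jcamp(
    path: str | os.PathLike,
    field_mhz: float | None = None,
    receiver_gain: float | None = None,
    num_scans: int | None = None,
    normalize_rg: bool = True,
) -> Spectrum1D:
    text = Path(path).read_text()
    headers: dict[str, str] = {}
    for m in re.finditer(r"^##([^=\n]+)=\s*(.*)$", text, re.MULTILINE):
        headers[m.group(1).strip().upper()] = m.group(2).strip()

    m = re.search(r"^##XYDATA=.*$", text, re.MULTILINE)
    if m is None:
        raise ConfigurationError(f"{path}: no XYDATA table")
    table = text[m.end():]
    end = table.find("##END")
    if end >= 0:
        table = table[:end]
    ys: list[float] = []
    for line in table.strip().splitlines():
        vals = line.split()
        if not vals:
            continue
        ys.extend(float(v) for v in vals[1:])  # first token is X

    n = int(headers.get("NPOINTS", len(ys)))
    if len(ys) != n:
        raise ConfigurationError(f"{path}: NPOINTS={n} but {len(ys)} Y values")
    firstx = float(headers["FIRSTX"])
    lastx = float(headers["LASTX"])
    yfactor = float(headers.get("YFACTOR", 1.0))
    ppm = np.linspace(firstx, lastx, n)
    y = np.asarray(ys) * yfactor

    fmhz = field_mhz if field_mhz is not None else _float_or_none(
        headers.get(".OBSERVE FREQUENCY"))
    if fmhz is None:
        raise ConfigurationError(f"{path}: observe frequency missing")
    rg = receiver_gain if receiver_gain is not None else _float_or_none(
        headers.get("$RECEIVERGAIN"), 1.0)
    ns = num_scans if num_scans is not None else int(
        float(headers.get("$NUMSCANS", 32)))
    sp = Spectrum1D(
        ppm_axis=ppm, intensity=y, field_mhz=fmhz, receiver_gain=rg,
        num_scans=ns, label=headers.get("TITLE", Path(path).stem),
        metadata={"rg_applied": headers.get("$RGAPPLIED", "0") == "1"},
    )
    return _apply_rg(sp, normalize_rg)


# ---------------------------------------------------------------------------
# Bruker processed-data directory
# ---------------------------------------------------------------------------

def _read_bruker_params(path: Path) -> dict[str, str]:
    params: dict[str, str] = {}
    if not path.exists():
        return params
    for m in re.finditer(r"^##\$?([^=\n]+)=\s*(.*)$", path.read_text(),
                         re.MULTILINE):
        params[m.group(1).strip()] = m.group(2).strip()
    return params


def load_bruker(
    path: str | os.PathLike,
    proc_no: int = 1,
    field_mhz: float | None = None,
    receiver_gain: float | None = None,
    num_scans: int | None = None,
    normalize_rg: bool = True,
) -> Spectrum1D:
    """Read the processed real part (``1r``) of a Bruker data directory.

    ``path`` may point at the experiment directory (containing ``acqus``
    and ``pdata/<proc_no>``) or directly at a ``pdata/<n>`` directory.
    """
    root = Path(path)
    if (root / "1r").exists():
        procdir = root
        expdir = root.parent.parent
    else:
        procdir = root / "pdata" / str(proc_no)
        expdir = root
    procs = _read_bruker_params(procdir / "procs")
    acqus = _read_bruker_params(expdir / "acqus")
    try:
        si = int(float(procs["SI"]))
        offset = float(procs["OFFSET"])
        sw_p = float(procs["SW_p"])
        sf = float(procs["SF"])
    except KeyError as exc:
        raise ConfigurationError(f"{procdir}: missing procs key {exc}") from exc
    nc_proc = int(float(procs.get("NC_proc", 0)))
    bytordp = int(float(procs.get("BYTORDP", 0)))
    dtypp = int(float(procs.get("DTYPP", 0)))
    if dtypp != 0:
        raise ConfigurationError("only int32 processed data (DTYPP=0) supported")
    dtype = "<i4" if bytordp == 0 else ">i4"
    raw = np.fromfile(procdir / "1r", dtype=dtype)
    if raw.size != si:
        raise ConfigurationError(
            f"{procdir}/1r holds {raw.size} points, procs SI={si}")
    y = raw.astype(float) * 2.0 ** nc_proc

    sw_ppm = sw_p / sf
    ppm = offset - sw_ppm * np.arange(si) / si

    fmhz = field_mhz if field_mhz is not None else _float_or_none(
        acqus.get("SFO1"), sf)
    rg = receiver_gain if receiver_gain is not None else _float_or_none(
        acqus.get("RG"), 1.0)
    ns = num_scans if num_scans is not None else int(float(acqus.get("NS", 32)))
    sp = Spectrum1D(
        ppm_axis=ppm, intensity=y, field_mhz=fmhz, receiver_gain=rg,
        num_scans=ns, label=expdir.name, metadata={"rg_applied": False},
    )
    return _apply_rg(sp, normalize_rg)


def write_bruker(spectrum: Spectrum1D, path: str | os.PathLike,
                 proc_no: int = 1) -> Path:
    """Write a Bruker-style processed directory (used to build fixtures)."""
    expdir = Path(path)
    procdir = expdir / "pdata" / str(proc_no)
    procdir.mkdir(parents=True, exist_ok=True)
    si = spectrum.n_points
    sf = spectrum.field_mhz
    sw_ppm = spectrum.dppm * si
    offset = float(spectrum.ppm_axis[0])
    ymax = float(np.max(np.abs(spectrum.intensity))) or 1.0
    nc_proc = int(np.ceil(np.log2(ymax / 2**29))) if ymax > 0 else 0
    yi = np.round(spectrum.intensity / 2.0 ** nc_proc).astype("<i4")
    (procdir / "1r").write_bytes(yi.tobytes())
    (procdir / "procs").write_text(
        "##TITLE= Parameter file\n"
        f"##$SI= {si}\n"
        f"##$OFFSET= {offset!r}\n"
        f"##$SW_p= {sw_ppm * sf!r}\n"
        f"##$SF= {sf!r}\n"
        f"##$NC_proc= {nc_proc}\n"
        "##$BYTORDP= 0\n"
        "##$DTYPP= 0\n"
        "##END=\n"
    )
    (expdir / "acqus").write_text(
        "##TITLE= Parameter file\n"
        f"##$SFO1= {sf!r}\n"
        f"##$RG= {spectrum.receiver_gain!r}\n"
        f"##$NS= {spectrum.num_scans}\n"
        "##END=\n"
    )
    return expdir


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_LOADERS = {"tsv": load_tsv, "jcamp": load_jcamp, "bruker_proc": load_bruker}


def load_spectrum(path: str | os.PathLike, format: str | None = None,
                  **kwargs) -> Spectrum1D:
    """Load a spectrum, inferring the dialect from the path when not given.

    Directories are read as Bruker processed data; ``.dx``/``.jdx`` files
    as JCAMP-DX; everything else as two-column text.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file or directory: {p}")
    if format is None:
        if p.is_dir():
            format = "bruker_proc"
        elif p.suffix.lower() in {".dx", ".jdx", ".jcamp"}:
            format = "jcamp"
        else:
            format = "tsv"
    try:
        loader = _LOADERS[format]
    except KeyError:
        raise ConfigurationError(f"unknown spectrum format {format!r}")
    return loader(p, **kwargs)
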