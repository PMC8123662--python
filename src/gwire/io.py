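"""Readers and writers for correlation curves, height maps and datasets.

Native curve format (one curve per file): a ``#``-prefixed header block of
``key = value`` metadata followed by a two-column CSV body::

    # gwire correlation curve v1
    # angle_deg = 90.0
    # wavelength_m = 6.33e-07
    # refractive_index = 1.33
    # temperature_K = 296.0
    # viscosity_Pa_s = 0.000932
    lag_time_s,g2
    1.000000e-07,1.809999
    ...

A reader for correlator ASCII exports is also provided.  Supported
dialect: a free-form metadata preamble of ``key : value`` lines (keys
recognised case-insensitively: ``angle``/``Angle [°]``, ``wavelength
[nm]``, ``refractive index``, ``temperature [K]``, ``viscosity [cp]``),
then a line whose first token is ``"Correlation"``, then a tab- or
whitespace-separated block of (lag in milliseconds, g2 - 1) pairs ending
at the first non-numeric line (e.g. a ``"Count Rate"`` section).

Height maps are read from grayscale TIFF (values times ``height_scale``
give nm) or whitespace-delimited text matrices.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import tifffile

from .afm import HeightMap
from .dls_model import CorrelationCurve, OpticalContext
from .errors import ValidationError
from .synthetic import SimulatedDataset

__all__ = [
    "read_curve",
    "read_curves",
    "write_curve",
    "read_correlator_ascii",
    "write_dataset",
    "read_dataset",
    "read_height_map",
]

_CURVE_MAGIC = "# gwire correlation curve v1"


def write_curve(curve: CorrelationCurve, path) -> Path:
    """Write one curve in the native header + CSV format."""
    path = Path(path)
    ctx = curve.context
    lines = [
        _CURVE_MAGIC,
        f"# angle_deg = {curve.angle_deg!r}",
        f"# wavelength_m = {ctx.wavelength!r}",
        f"# refractive_index = {ctx.refractive_index!r}",
        f"# temperature_K = {ctx.temperature!r}",
        f"# viscosity_Pa_s = {ctx.viscosity!r}",
        "lag_time_s,g2",
    ]
    lines += [
        f"{t:.12e},{g:.12e}" for t, g in zip(curve.lag_times, curve.g2)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_curve(path) -> CorrelationCurve:
    """Read one curve from the native format; rejects non-monotone lag grids."""
    path = Path(path)
    meta: dict[str, float] = {}
    lags, g2s = [], []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*=\s*(\S+)", line)
                if m:
                    meta[m.group(1)] = float(m.group(2))
                continue
            if line.lower().startswith("lag_time"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'lag,g2', got {line!r}"
                )
            try:
                lags.append(float(parts[0]))
                g2s.append(float(parts[1]))
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    required = {"angle_deg", "wavelength_m", "refractive_index", "temperature_K",
                "viscosity_Pa_s"}
    missing = required - set(meta)
    if missing:
        raise ValidationError(f"{path}: missing header keys {sorted(missing)}")
    if not lags:
        raise ValidationError(f"{path}: no data rows")
    context = OpticalContext(
        wavelength=meta["wavelength_m"],
        refractive_index=meta["refractive_index"],
        temperature=meta["temperature_K"],
        viscosity=meta["viscosity_Pa_s"],
    )
    try:
        return CorrelationCurve(
            lag_times=np.array(lags), g2=np.array(g2s),
            angle_deg=meta["angle_deg"], context=context,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_correlator_ascii(
    path, context_defaults: OpticalContext = OpticalContext()
) -> CorrelationCurve:
    """Read a correlator ASCII export (dialect documented in the module docstring).

    Lag times are in milliseconds and the correlation column holds g2 - 1.
    Metadata found in the preamble overrides ``context_defaults``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: dict[str, float] = {}
    block_start = None
    for i, line in enumerate(lines):
        stripped = line.strip().strip('"')
        if stripped.lower().startswith("correlation"):
            block_start = i + 1
            break
        m = re.match(r"(.+?)\s*:\s*([-+0-9.eE]+)\s*$", line.strip())
        if m:
            key = m.group(1).strip().strip('"').lower()
            try:
                meta[key] = float(m.group(2))
            except ValueError:  # dates and other non-numeric values
                continue
    if block_start is None:
        raise ValidationError(f"{path}: no \"Correlation\" block found")
    lags, g2s = [], []
    for lineno, line in enumerate(lines[block_start:], start=block_start + 1):
        parts = line.split()
        if len(parts) < 2:
            break
        try:
            lag_ms, g2m1 = float(parts[0]), float(parts[1])
        except ValueError:
            break
        lags.append(lag_ms * 1e-3)
        g2s.append(1.0 + g2m1)
    if not lags:
        raise ValidationError(f"{path}: empty correlation block")

    def pick(*keys, default):
        for k in keys:
            if k in meta:
                return meta[k]
        return default

    angle = pick("angle [°]", "angle [deg]", "angle", default=None)
    if angle is None:
        raise ValidationError(f"{path}: no scattering angle in preamble")
    wavelength_nm = pick("wavelength [nm]", "wavelength",
                         default=context_defaults.wavelength * 1e9)
    context = OpticalContext(
        wavelength=wavelength_nm * 1e-9,
        refractive_index=pick("refractive index",
                              default=context_defaults.refractive_index),
        temperature=pick("temperature [k]", default=context_defaults.temperature),
        viscosity=pick("viscosity [cp]", default=context_defaults.viscosity * 1e3)
        * 1e-3,
    )
    return CorrelationCurve(
        lag_times=np.array(lags), g2=np.array(g2s), angle_deg=angle, context=context
    )


def read_curves(path, format: str = "csv") -> list[CorrelationCurve]:
    """Read one or many curves from a file or directory.

    ``format`` is ``"csv"`` (native) or ``"correlator"``.  For a directory,
    all ``*.csv`` (native) or ``*.asc``/``*.txt`` (correlator) files are
    read, sorted by name.
    """
    path = Path(path)
    if format not in ("csv", "correlator"):
        raise ValidationError(f"unknown curve format {format!r}")
    reader = read_curve if format == "csv" else read_correlator_ascii
    if path.is_dir():
        patterns = ("*.csv",) if format == "csv" else ("*.asc", "*.txt")
        files = sorted(f for pat in patterns for f in path.glob(pat))
        if not files:
            raise ValidationError(f"no curve files matching {patterns} in {path}")
        return [reader(f) for f in files]
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    return [reader(path)]


def write_dataset(dataset: SimulatedDataset, directory) -> Path:
    """Write a simulated dataset: one curve file per angle plus truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, curve in enumerate(dataset.curves):
        write_curve(curve, directory / f"curve_{i:02d}_angle{curve.angle_deg:g}.csv")
    (directory / "truth.json").write_text(json.dumps(dataset.truth, indent=2))
    return directory


def read_dataset(directory) -> tuple[list[CorrelationCurve], dict | None]:
    """Read back the curves (and truth, if present) written by write_dataset."""
    directory = Path(directory)
    curves = read_curves(directory, format="csv")
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return curves, truth


def read_height_map(
    path, pixel_size: float, height_scale: float = 1.0, provenance: str | None = None
) -> HeightMap:
    """Read a height map from grayscale TIFF or a plain-text matrix.

    ``pixel_size`` is nm/pixel; pixel values times ``height_scale`` give
    heights in nm.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path).astype(float)
    else:
        data = np.loadtxt(path, dtype=float)
    return HeightMap(
        heights=data * height_scale,
        pixel_size=pixel_size,
        provenance=provenance or str(path),
    )
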