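"""Readers and writers: spectrum CSV dialects, parameter configs, reports.

Spectrum files are plain CSV with unit-bearing headers.  Two dialects are
auto-detected:

* rectangular -- ``frequency_hz,re_z_ohm,im_z_ohm``
* polar       -- ``frequency_hz,mag_z_ohm,phase_deg`` (phase in degrees)

Rows are sorted by frequency on read; duplicate frequencies are rejected
with the offending line number.  Reports are JSON with sorted keys and a
schema version, so serialisation is byte-stable.
"""

from __future__ import annotations

import csv
import json
import tomllib
from pathlib import Path

import numpy as np

from .calibration import CalibrationCurve
from .circuit import CircuitParams, ComplexSpectrum, FrequencyGrid
from .dmi import DMiSpectrum
from .fitting import FitResult

__all__ = [
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "write_nyquist",
    "write_bode",
    "write_dmi",
    "read_params",
    "write_report",
    "report_dict",
]

RECT_HEADER = ["frequency_hz", "re_z_ohm", "im_z_ohm"]
POLAR_HEADER = ["frequency_hz", "mag_z_ohm", "phase_deg"]
SCHEMA_VERSION = 1


class SpectrumParseError(ValueError):
    """A spectrum CSV could not be parsed; message carries the line number."""


def read_spectrum(path) -> ComplexSpectrum:
    """Read a spectrum CSV in either dialect into a complex spectrum."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [(i + 1, r) for i, r in enumerate(rows) if any(cell.strip() for cell in r)]
    if not rows:
        raise SpectrumParseError(f"{path}: empty file")
    header = [c.strip().lower() for c in rows[0][1]]
    if header == RECT_HEADER:
        polar = False
    elif header == POLAR_HEADER:
        polar = True
    else:
        raise SpectrumParseError(
            f"{path}: line 1: unknown header {','.join(header)!r}; expected "
            f"{','.join(RECT_HEADER)!r} or {','.join(POLAR_HEADER)!r}"
        )
    freqs: list[float] = []
    zs: list[complex] = []
    seen: dict[float, int] = {}
    for lineno, row in rows[1:]:
        if len(row) != 3:
            raise SpectrumParseError(f"{path}: line {lineno}: expected 3 columns, got {len(row)}")
        try:
            a, b, c = (float(cell) for cell in row)
        except ValueError:
            raise SpectrumParseError(f"{path}: line {lineno}: non-numeric cell in {row!r}") from None
        if a <= 0:
            raise SpectrumParseError(f"{path}: line {lineno}: non-positive frequency {a}")
        if a in seen:
            raise SpectrumParseError(
                f"{path}: line {lineno}: duplicate frequency {a} (first seen on line {seen[a]})"
            )
        seen[a] = lineno
        freqs.append(a)
        if polar:
            theta = np.deg2rad(c)
            zs.append(complex(b * np.cos(theta), b * np.sin(theta)))
        else:
            zs.append(complex(b, c))
    if not freqs:
        raise SpectrumParseError(f"{path}: no data rows")
    order = np.argsort(freqs)
    f = np.asarray(freqs)[order]
    z = np.asarray(zs)[order]
    return ComplexSpectrum(FrequencyGrid(f), z)


def _write_csv(path, header: list[str], columns: list[np.ndarray]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in zip(*columns):
            w.writerow([repr(float(v)) for v in row])


def write_spectrum(spectrum: ComplexSpectrum, path, dialect: str = "rect") -> None:
    """Write a spectrum CSV in the rectangular or polar dialect."""
    f = spectrum.frequencies_hz
    if dialect == "rect":
        _write_csv(path, RECT_HEADER, [f, spectrum.z.real, spectrum.z.imag])
    elif dialect == "polar":
        _write_csv(path, POLAR_HEADER, [f, spectrum.magnitude, spectrum.phase_deg])
    else:
        raise ValueError("dialect must be 'rect' or 'polar'")


def write_nyquist(spectrum: ComplexSpectrum, path) -> None:
    """Nyquist export: Re(Z) vs -Im(Z), frequency implicit."""
    _write_csv(path, ["re_z_ohm", "neg_im_z_ohm"], [spectrum.z.real, -spectrum.z.imag])


def write_bode(spectrum: ComplexSpectrum, path) -> None:
    """Bode export: |Z| and phase (degrees) vs frequency."""
    write_spectrum(spectrum, path, dialect="polar")


def write_dmi(spectrum: DMiSpectrum, path) -> None:
    _write_csv(path, ["frequency_hz", "dmi"], [spectrum.grid.frequencies_hz, spectrum.dmi])


def read_params(path) -> CircuitParams:
    """Read circuit parameters from a flat key-value TOML file (SI units)."""
    with Path(path).open("rb") as fh:
        data = tomllib.load(fh)
    missing = {"ts", "ps", "ce", "rd", "td", "pd"} - {k.lower() for k in data}
    if missing:
        raise ValueError(f"{path}: missing circuit parameters: {sorted(missing)}")
    return CircuitParams.from_dict(data)


def report_dict(result) -> dict:
    """JSON-ready report for a fit result or a calibration curve."""
    if isinstance(result, FitResult):
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "circuit_fit",
            "params_si": result.params.as_dict(),
            "cef_F": result.cef,
            "cef_uF": round(result.cef * 1e6, 4),
            "cost": result.cost,
            "converged": result.converged,
            "n_evaluations": result.n_evaluations,
            "start_index": result.start_index,
        }
    if isinstance(result, CalibrationCurve):
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "calibration",
            "slope": result.slope,
            "intercept": result.intercept,
            "r_squared": result.r_squared,
            "n": result.n,
            "log_concentration": result.log_concentration,
        }
    if isinstance(result, dict):
        return {"schema_version": SCHEMA_VERSION, **result}
    raise TypeError(f"cannot report {type(result).__name__}")


def write_report(result, path) -> dict:
    """Serialise a report as stable JSON (sorted keys); returns the dict."""
    doc = report_dict(result)
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
    return doc
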