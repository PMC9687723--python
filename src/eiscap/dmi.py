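"""Dispersed-medium index (DMi): normalized impedance-magnitude spectra.

DMi compares a suspension against its pure liquid medium per frequency:

    DMi(f) = (|Z|_S(f) - |Z|_LM(f)) / |Z|_LM(f)

so the liquid medium itself sits at zero and the index is invariant to any
common rescaling of both spectra (cell constant, electrode area).  Replicate
aliquots are averaged in magnitude before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circuit import ComplexSpectrum, FrequencyGrid

__all__ = [
    "MagnitudeSpectrum",
    "DMiSpectrum",
    "magnitude_of",
    "average_magnitude",
    "compute_dmi",
    "dmi_at",
]


@dataclass(frozen=True)
class MagnitudeSpectrum:
    """|Z| sampled on a frequency grid (Ohm)."""

    grid: FrequencyGrid
    mag_ohm: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mag_ohm, dtype=float)
        if m.shape != (len(self.grid),):
            raise ValueError("magnitude array must match the grid length")
        if np.any(m <= 0):
            raise ValueError("impedance magnitudes must be positive")
        object.__setattr__(self, "mag_ohm", m)


@dataclass(frozen=True)
class DMiSpectrum:
    """Per-frequency dispersed-medium index (dimensionless)."""

    grid: FrequencyGrid
    dmi: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dmi, dtype=float)
        if d.shape != (len(self.grid),):
            raise ValueError("dmi array must match the grid length")
        if np.any(d < -1.0):
            raise ValueError("DMi below -1 is impossible for positive magnitudes")
        object.__setattr__(self, "dmi", d)


def magnitude_of(spectrum: ComplexSpectrum) -> MagnitudeSpectrum:
    """Magnitude view of a complex spectrum."""
    return MagnitudeSpectrum(spectrum.grid, spectrum.magnitude)


def average_magnitude(
    replicates: Sequence[MagnitudeSpectrum],
) -> tuple[MagnitudeSpectrum, np.ndarray]:
    """Average replicate |Z| spectra on a shared grid.

    Returns the mean spectrum and the per-frequency relative standard
    deviation in percent (population sd over mean), the dispersion figure
    reported for replicate aliquots.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    grid = replicates[0].grid
    for r in replicates[1:]:
        if not np.array_equal(r.grid.frequencies_hz, grid.frequencies_hz):
            raise ValueError("replicates must share one frequency grid")
    stack = np.vstack([r.mag_ohm for r in replicates])
    mean = stack.mean(axis=0)
    sigma_pct = 100.0 * stack.std(axis=0) / mean
    return MagnitudeSpectrum(grid, mean), sigma_pct


def compute_dmi(
    suspension: MagnitudeSpectrum,
    liquid_medium: MagnitudeSpectrum,
    interpolate: bool = False,
) -> DMiSpectrum:
    """DMi(f) = (|Z|_S - |Z|_LM) / |Z|_LM pointwise.

    Grids must be identical unless ``interpolate`` is set, in which case the
    liquid-medium spectrum is interpolated (linearly in log frequency) onto
    the suspension grid points inside the overlapping range.
    """
    fs = suspension.grid.frequencies_hz
    fm = liquid_medium.grid.frequencies_hz
    if np.array_equal(fs, fm):
        lm = liquid_medium.mag_ohm
        grid = suspension.grid
        s = suspension.mag_ohm
    elif not interpolate:
        raise ValueError(
            "suspension and liquid-medium grids differ; pass interpolate=True"
        )
    else:
        lo, hi = max(fs[0], fm[0]), min(fs[-1], fm[-1])
        if lo > hi:
            raise ValueError("frequency grids do not overlap")
        keep = (fs >= lo) & (fs <= hi)
        grid = FrequencyGrid(fs[keep])
        s = suspension.mag_ohm[keep]
        lm = np.interp(np.log(grid.frequencies_hz), np.log(fm), liquid_medium.mag_ohm)
    return DMiSpectrum(grid, (s - lm) / lm)


def dmi_at(spectrum: DMiSpectrum, frequency_hz: float, method: str = "nearest") -> float:
    """Scalar DMi read-out at a reporting frequency (default 50 Hz usage).

    On-grid frequencies return the stored value exactly.  Off-grid queries
    use the nearest grid point by default, or linear interpolation in log
    frequency with ``method='loglinear'``.
    """
    f = spectrum.grid.frequencies_hz
    if not f[0] <= frequency_hz <= f[-1]:
        raise ValueError(
            f"frequency {frequency_hz} Hz outside grid range [{f[0]}, {f[-1]}]"
        )
    exact = np.isclose(f, frequency_hz, rtol=1e-9, atol=0.0)
    if exact.any():
        return float(spectrum.dmi[int(np.argmax(exact))])
    if method == "nearest":
        return float(spectrum.dmi[int(np.argmin(np.abs(np.log(f / frequency_hz))))])
    if method == "loglinear":
        return float(np.interp(np.log(frequency_hz), np.log(f), spectrum.dmi))
    raise ValueError(f"unknown method {method!r}")
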