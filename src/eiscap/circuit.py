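"""Forward equivalent-circuit model for low-frequency impedance spectra.

The circuit describes a particle or non-adherent cell suspension measured
between two electrodes in the 10--1000 Hz band, where electrode polarization
and the electrical double layers (EDL) around the dispersed medium dominate:

* ``CPEs`` -- a constant phase element for the bulk suspension,
* ``Ce``   -- the electrode/electrolyte interface capacitance,
* ``Rd`` and ``CPEd`` -- resistance and (non-ideal) capacitance of the
  multiple EDLs around the dispersed particles or cells.

The total impedance is modelled as the bulk CPE in series with the electrode
capacitance in parallel with the dispersed-medium branch::

    Z(w) = Z_CPEs(w) + [ Z_Ce(w) || (Rd + Z_CPEd(w)) ]

The CPE branch is summarised by a single *effective capacitance*

    Cef = Ce + (Td * Rd**(1 - Pd)) ** (1 / Pd)

which is the scalar read-out used downstream for concentration calibration.

All quantities are SI internally (F, Ohm, Hz, radians); microfarads and
degrees appear only at presentation boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "CPEParams",
    "CircuitParams",
    "FrequencyGrid",
    "ComplexSpectrum",
    "cpe_impedance",
    "circuit_impedance",
    "dispersed_capacitance",
    "effective_capacitance",
    "effective_capacitance_from",
]


@dataclass(frozen=True)
class CPEParams:
    """Constant phase element: Z = 1 / (T * (j*w)**P).

    ``T`` is the CPE constant in F s**(P-1); ``P`` in [0, 1] interpolates
    between an ideal resistor (P=0, Z = 1/T) and an ideal capacitor (P=1).
    """

    T: float
    P: float

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"CPE constant T must be positive, got {self.T}")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError(f"CPE exponent P must lie in [0, 1], got {self.P}")


@dataclass(frozen=True)
class CircuitParams:
    """The six element values of the suspension equivalent circuit (SI units).

    ts, ps -- bulk-suspension CPE constant and exponent;
    ce     -- electrode interface capacitance (F);
    rd     -- dispersed-medium EDL resistance (Ohm);
    td, pd -- dispersed-medium CPE constant and exponent.
    """

    ts: float
    ps: float
    ce: float
    rd: float
    td: float
    pd: float

    _POSITIVE = ("ts", "ce", "rd", "td")
    _EXPONENT = ("ps", "pd")

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in self._EXPONENT:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def bulk_cpe(self) -> CPEParams:
        return CPEParams(self.ts, self.ps)

    @property
    def dispersed_cpe(self) -> CPEParams:
        return CPEParams(self.td, self.pd)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CircuitParams":
        return cls(**{k.lower(): float(v) for k, v in d.items()})


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of positive frequencies in Hz."""

    frequencies_hz: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(f <= 0):
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies_hz", f)

    @classmethod
    def log_spaced(
        cls, fmin_hz: float = 10.0, fmax_hz: float = 1000.0, n_points: int = 50
    ) -> "FrequencyGrid":
        """Default simulation grid: 50 log-spaced points over 10-1000 Hz."""
        if not (fmin_hz > 0 and fmax_hz > fmin_hz and n_points >= 2):
            raise ValueError("need 0 < fmin < fmax and n_points >= 2")
        return cls(np.logspace(np.log10(fmin_hz), np.log10(fmax_hz), n_points))

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies (rad/s)."""
        return 2.0 * np.pi * self.frequencies_hz

    def __len__(self) -> int:
        return self.frequencies_hz.size


@dataclass(frozen=True)
class ComplexSpectrum:
    """Complex impedance sampled on a frequency grid (Ohm)."""

    grid: FrequencyGrid
    z: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=complex)
        if z.shape != (len(self.grid),):
            raise ValueError("impedance array must match the grid length")
        object.__setattr__(self, "z", z)

    @property
    def frequencies_hz(self) -> np.ndarray:
        return self.grid.frequencies_hz

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.z))


def cpe_impedance(cpe: CPEParams, frequency_hz):
    """CPE impedance Z = 1 / (T * (j*w)**P) at one or many frequencies (Hz).

    Magnitude is 1/(T*w**P) and the phase is -P*90 degrees at every frequency.
    """
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be strictly positive")
    w = 2.0 * np.pi * f
    z = np.asarray(1.0 / (cpe.T * (1j * w) ** cpe.P), dtype=complex)
    return complex(z) if f.ndim == 0 else z


def _parallel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a * b / (a + b)


def circuit_impedance(params: CircuitParams, grid: FrequencyGrid) -> ComplexSpectrum:
    """Impedance of the full suspension circuit over a frequency grid.

    Z(w) = Z_CPEs(w) + [ Z_Ce(w) || (Rd + Z_CPEd(w)) ], with
    Z_Ce = 1/(j*w*Ce).
    """
    w = grid.omega
    z_bulk = 1.0 / (params.ts * (1j * w) ** params.ps)
    z_ce = 1.0 / (1j * w * params.ce)
    z_branch = params.rd + 1.0 / (params.td * (1j * w) ** params.pd)
    return ComplexSpectrum(grid, z_bulk + _parallel(z_ce, z_branch))


def dispersed_capacitance(rd: float, td: float, pd: float) -> float:
    """Effective capacitance of the dispersed-medium branch (Cole-Cole form).

    Cd = (Td * Rd**(1 - Pd)) ** (1 / Pd).  Undefined at Pd = 0, where the
    CPE degenerates to a resistor and the exponent 1/Pd diverges.
    """
    if not rd > 0 or not td > 0:
        raise ValueError("rd and td must be positive")
    if not 0.0 < pd <= 1.0:
        raise ValueError(f"pd must lie in (0, 1], got {pd}")
    # evaluate in log space: the 1/pd exponent overflows float64 for small pd
    try:
        return math.exp((math.log(td) + (1.0 - pd) * math.log(rd)) / pd)
    except OverflowError:
        return math.inf


def effective_capacitance_from(ce: float, rd: float, td: float, pd: float) -> float:
    """Cef = Ce + Cd for raw element values; Ce = 0 is allowed here."""
    if ce < 0:
        raise ValueError("ce must be non-negative")
    return float(ce + dispersed_capacitance(rd, td, pd))


def effective_capacitance(params: CircuitParams) -> float:
    """Total effective capacitance Cef = Ce + (Td*Rd**(1-Pd))**(1/Pd) in F."""
    return effective_capacitance_from(params.ce, params.rd, params.td, params.pd)
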