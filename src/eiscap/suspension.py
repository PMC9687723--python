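"""Suspension bookkeeping: volume fractions, particle counts, dilutions.

Particles and cells are modelled as monodisperse spheres, so a suspension
of ``c`` particles per microlitre with diameter ``d`` micrometres occupies
a volume fraction  V_f = c * (pi/6) * d**3 / 1e9  (sphere volume in um^3
over the 1e9 um^3 in one uL).
"""

from __future__ import annotations

from dataclasses import dataclass

import math

__all__ = ["SuspensionSpec", "volume_fraction", "particle_count", "serial_dilution"]

_UM3_PER_UL = 1e9


@dataclass(frozen=True)
class SuspensionSpec:
    """A monodisperse suspension in a measurement chamber.

    diameter_um        -- particle/cell diameter (um)
    concentration_per_ul -- particles per uL
    sample_volume_ul   -- chamber fill volume (uL)
    """

    diameter_um: float
    concentration_per_ul: float
    sample_volume_ul: float = 100.0

    def __post_init__(self) -> None:
        for name in ("diameter_um", "concentration_per_ul", "sample_volume_ul"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def volume_fraction(s: SuspensionSpec) -> float:
    """Dispersed-phase volume fraction of the suspension (dimensionless)."""
    sphere_um3 = math.pi / 6.0 * s.diameter_um**3
    return s.concentration_per_ul * sphere_um3 / _UM3_PER_UL


def particle_count(s: SuspensionSpec) -> int:
    """Total number of particles in the sampled chamber volume."""
    return round(s.concentration_per_ul * s.sample_volume_ul)


def serial_dilution(start_per_ul: float, n_steps: int, factor: float = 2.0) -> list[float]:
    """Descending geometric concentration series from a stock suspension.

    ``factor`` is the per-step dilution ratio (2.0 = half-fold); the first
    element is the undiluted ``start_per_ul``.
    """
    if not start_per_ul > 0:
        raise ValueError("start concentration must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not factor > 1:
        raise ValueError("dilution factor must exceed 1")
    return [start_per_ul / factor**i for i in range(n_steps)]
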