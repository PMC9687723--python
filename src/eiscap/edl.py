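"""Gouy-Chapman-Stern (GCS) electrical double-layer capacitance.

The GCS model splits the ion cloud at a charged surface into a compact
Stern layer and a diffuse layer; the two act as capacitors in series:

    1/C_DL = x_OHP/(eps*eps0) + 1/C_dif
    C_dif  = sqrt(2*eps*eps0*z^2*e^2*n0/(kB*T)) * cosh(z*e*psi/(2*kB*T))

where x_OHP is the outer-Helmholtz-plane distance, n0 the ionic number
concentration (m^-3), z the valence, psi the potential at the OHP versus
bulk, and T the absolute temperature.  Capacitances are per unit area
(F m^-2).  The relative permittivity is treated as constant across the
layers, which overestimates the Stern contribution when the field strongly
aligns the solvent dipoles.  Physical constants are CODATA 2018 values as
shipped with scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import constants

__all__ = ["GCSParams", "series_capacitance", "diffuse_capacitance",
           "gcs_capacitance", "number_density"]


def number_density(molarity_mol_per_l: float) -> float:
    """Ion number concentration n0 (m^-3) of a salt at the given molarity."""
    if molarity_mol_per_l <= 0:
        raise ValueError("molarity must be positive")
    return molarity_mol_per_l * constants.N_A * 1e3


@dataclass(frozen=True)
class GCSParams:
    """Inputs of the GCS double-layer capacitance.

    x_ohp   -- Stern-plane (OHP) distance from the surface (m), >= 0
    eps_r   -- relative permittivity of the medium
    n0      -- bulk ionic number concentration (m^-3)
    z_val   -- ion valence (non-zero integer)
    psi     -- potential at the OHP versus bulk (V)
    temp_k  -- absolute temperature (K)
    """

    x_ohp: float
    eps_r: float
    n0: float
    z_val: int
    psi: float
    temp_k: float

    def __post_init__(self) -> None:
        if self.x_ohp < 0:
            raise ValueError("x_ohp must be non-negative")
        if not self.eps_r > 0:
            raise ValueError("eps_r must be positive")
        if not self.n0 > 0:
            raise ValueError("n0 must be positive")
        if self.z_val == 0:
            raise ValueError("z_val must be non-zero")
        if not self.temp_k > 0:
            raise ValueError("temp_k must be positive")


def series_capacitance(c_stern: float, c_diffuse: float) -> float:
    """Two capacitors in series: 1/C = 1/C_S + 1/C_dif.

    Either argument may be ``math.inf`` to denote an infinitely compact
    layer, in which case the other capacitance is returned.
    """
    for c in (c_stern, c_diffuse):
        if not c > 0:
            raise ValueError(f"capacitances must be positive, got {c}")
    if math.isinf(c_stern):
        return c_diffuse
    if math.isinf(c_diffuse):
        return c_stern
    return 1.0 / (1.0 / c_stern + 1.0 / c_diffuse)


def diffuse_capacitance(p: GCSParams) -> float:
    """Diffuse-layer (Gouy-Chapman) capacitance per unit area (F m^-2)."""
    kbt = constants.k * p.temp_k
    c_debye = math.sqrt(
        2.0 * p.eps_r * constants.epsilon_0 * p.z_val**2 * constants.e**2 * p.n0 / kbt
    )
    return c_debye * math.cosh(p.z_val * constants.e * p.psi / (2.0 * kbt))


def gcs_capacitance(p: GCSParams) -> float:
    """Total GCS double-layer capacitance per unit area (F m^-2).

    Series combination of the Stern-layer capacitance eps*eps0/x_OHP and the
    diffuse-layer capacitance.  With x_ohp = 0 the Stern layer is absent and
    the diffuse term alone is returned.
    """
    c_dif = diffuse_capacitance(p)
    if p.x_ohp == 0.0:
        return c_dif
    c_stern = p.eps_r * constants.epsilon_0 / p.x_ohp
    return series_capacitance(c_stern, c_dif)
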