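"""Seeded synthetic spectra with the structure of the suspension experiments.

No raw spectra are publicly deposited for this kind of measurement, so every
downstream stage (DMi, circuit fitting, calibration) is exercised against
synthetic data: forward-model spectra from the equivalent circuit, corrupted
by proportional complex Gaussian noise, plus concentration series in which
the electrode capacitance rises with particle count the way fitted
measurements do.

The module embeds the 15 fitted parameter sets obtained for PMMA particle
suspensions (5 concentrations x 3 diameters) as the single source of
realistic generator values; tests reuse the same table for parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .circuit import CircuitParams, ComplexSpectrum, FrequencyGrid, circuit_impedance

__all__ = [
    "NoiseModel",
    "Table2Row",
    "TABLE2",
    "table2_rows",
    "generate_spectrum",
    "linear_ce_trend",
    "table2_trend",
    "generate_concentration_series",
]


@dataclass(frozen=True)
class NoiseModel:
    """Proportional complex Gaussian noise: Z -> Z*(1 + e_re + j*e_im).

    ``relative_sigma`` is the standard deviation of each of the independent
    real and imaginary perturbations, as a fraction of |Z|.  The 1% default
    sits at the quiet end of the 1-36% replicate spread seen across aliquot
    measurements.
    """

    relative_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sigma < 0:
            raise ValueError("relative_sigma must be non-negative")


@dataclass(frozen=True)
class Table2Row:
    """One fitted parameter set: concentration, diameter, circuit values."""

    concentration_per_ul: float
    diameter_um: float
    params: CircuitParams


def _row(c: float, d: float, ts: float, ps: float, ce: float, rd: float, td: float, pd: float) -> Table2Row:
    return Table2Row(c, d, CircuitParams(ts=ts, ps=ps, ce=ce, rd=rd, td=td, pd=pd))


#: Fitted circuit parameters for PMMA suspensions: 5 concentrations
#: (25..400 p/uL, half-fold) x 3 diameters (6, 15, 48 um).  SI units.
TABLE2: tuple[Table2Row, ...] = (
    _row(25, 6, 0.86e-3, 0.31, 0.57e-6, 3815, 9.9e-7, 0.73),
    _row(25, 15, 1.86e-3, 0.24, 0.74e-6, 6412, 7.1e-7, 0.74),
    _row(25, 48, 0.62e-3, 0.36, 0.84e-6, 7284, 6.9e-7, 0.75),
    _row(50, 6, 1.54e-3, 0.26, 0.62e-6, 3868, 9.4e-7, 0.75),
    _row(50, 15, 1.43e-3, 0.26, 0.82e-6, 3570, 6.9e-7, 0.71),
    _row(50, 48, 0.54e-3, 0.37, 0.85e-6, 6753, 6.7e-7, 0.75),
    _row(100, 6, 0.89e-3, 0.31, 0.66e-6, 3863, 9.3e-7, 0.76),
    _row(100, 15, 8.50e-3, 0.44, 0.72e-6, 1186, 8.6e-7, 0.80),
    _row(100, 48, 1.05e-3, 0.30, 0.86e-6, 7078, 7.2e-7, 0.75),
    _row(200, 6, 1.44e-3, 0.27, 0.71e-6, 4561, 8.2e-7, 0.78),
    _row(200, 15, 5.18e-3, 0.15, 0.76e-6, 1741, 8.3e-7, 0.80),
    _row(200, 48, 0.16e-3, 0.29, 0.88e-6, 7875, 7.7e-7, 0.76),
    _row(400, 6, 3.32e-3, 0.19, 0.76e-6, 5049, 8.0e-7, 0.75),
    _row(400, 15, 6.63e-3, 0.12, 0.77e-6, 1827, 8.0e-7, 0.81),
    _row(400, 48, 0.97e-3, 0.28, 0.90e-6, 10692, 6.6e-7, 0.74),
)


def table2_rows(diameter_um: float | None = None) -> list[Table2Row]:
    """Rows of the embedded parameter table, optionally for one diameter."""
    if diameter_um is None:
        return list(TABLE2)
    rows = [r for r in TABLE2 if r.diameter_um == diameter_um]
    if not rows:
        raise ValueError(f"no rows for diameter {diameter_um} um")
    return rows


def generate_spectrum(
    params: CircuitParams,
    grid: FrequencyGrid,
    noise: NoiseModel | None = None,
) -> ComplexSpectrum:
    """Forward-model spectrum with proportional complex noise.

    Z_obs(f) = Z_model(f) * (1 + e_re + j*e_im), e ~ N(0, relative_sigma),
    independently per frequency and per part.  Deterministic given the seed.
    """
    clean = circuit_impedance(params, grid)
    if noise is None or noise.relative_sigma == 0:
        return clean
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.relative_sigma, (2, len(grid)))
    return ComplexSpectrum(grid, clean.z * (1.0 + eps[0] + 1j * eps[1]))


def linear_ce_trend(
    base: CircuitParams,
    c_lo: float,
    ce_lo: float,
    c_hi: float,
    ce_hi: float,
) -> Callable[[float], CircuitParams]:
    """Trend mapping concentration -> params with Ce linear in concentration.

    All other elements stay at ``base``.  Because Cef = Ce + Cd(Rd, Td, Pd),
    a Ce-linear trend makes the effective capacitance exactly linear in
    concentration -- the behaviour seen in measured calibration curves.
    """
    if c_hi == c_lo:
        raise ValueError("need two distinct anchor concentrations")

    def trend(c: float) -> CircuitParams:
        ce = ce_lo + (ce_hi - ce_lo) * (c - c_lo) / (c_hi - c_lo)
        d = base.as_dict()
        d["ce"] = ce
        return CircuitParams(**d)

    return trend


def table2_trend(diameter_um: float = 6.0) -> Callable[[float], CircuitParams]:
    """Default concentration trend for one particle diameter.

    Ce interpolates linearly between the lowest- and highest-concentration
    fitted values for that diameter; the other five elements are held at
    the per-diameter medians of the fitted table.
    """
    rows = sorted(table2_rows(diameter_um), key=lambda r: r.concentration_per_ul)
    med = {
        name: float(np.median([getattr(r.params, name) for r in rows]))
        for name in ("ts", "ps", "rd", "td", "pd")
    }
    base = CircuitParams(ce=rows[0].params.ce, **med)
    return linear_ce_trend(
        base,
        rows[0].concentration_per_ul, rows[0].params.ce,
        rows[-1].concentration_per_ul, rows[-1].params.ce,
    )


def generate_concentration_series(
    concentrations: Sequence[float],
    trend: Callable[[float], CircuitParams] | None = None,
    noise: NoiseModel | None = None,
    grid: FrequencyGrid | None = None,
) -> list[tuple[float, ComplexSpectrum]]:
    """One synthetic spectrum per concentration.

    ``trend`` maps each concentration to circuit parameters (default: the
    6 um Ce-linear trend).  With noise enabled, each concentration gets an
    independent child seed spawned from ``noise.seed`` so replicate series
    are reproducible yet uncorrelated across concentrations.
    """
    if len(concentrations) == 0:
        raise ValueError("need at least one concentration")
    trend = trend or table2_trend(6.0)
    grid = grid or FrequencyGrid.log_spaced()
    if noise is None or noise.relative_sigma == 0:
        return [(float(c), generate_spectrum(trend(c), grid)) for c in concentrations]
    child_seeds = np.random.SeedSequence(noise.seed).generate_state(len(concentrations))
    out = []
    for c, s in zip(concentrations, child_seeds):
        nm = NoiseModel(noise.relative_sigma, int(s % (2**31)))
        out.append((float(c), generate_spectrum(trend(c), grid, nm)))
    return out
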