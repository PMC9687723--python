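"""Complex nonlinear least-squares estimation of the circuit parameters.

A measured spectrum is fitted by minimising the weighted real and imaginary
residuals of the forward circuit model with a trust-region
Levenberg-Marquardt-style solver (scipy's ``least_squares``, method ``trf``)
under box bounds that keep both CPE exponents in [0, 1].  Scale parameters
(Ts, Ce, Rd, Td) are optimised in log10 space -- they span several decades
-- while the exponents stay linear.  CPE circuits have well-known local
minima, so the solver is restarted from a heuristic initial guess plus a
configurable number of jittered multistarts; the lowest final cost wins.

Modulus weighting (residuals divided by |Z_obs| per frequency) is the
default: |Z| spans about a decade over 10--1000 Hz and relative weighting
keeps the low- and high-frequency ends comparably influential.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .circuit import CircuitParams, ComplexSpectrum, FrequencyGrid, circuit_impedance, effective_capacitance

__all__ = ["FitConfig", "FitResult", "residuals", "initial_guess", "fit_circuit", "CircuitFitter"]

#: Default box bounds per parameter (SI units), generous around the ranges
#: typical of electrode/suspension measurements in this band.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "ts": (1e-8, 10.0),
    "ps": (0.01, 1.0),
    "ce": (1e-9, 1e-3),
    "rd": (1.0, 1e7),
    "td": (1e-9, 1e-2),
    "pd": (0.01, 1.0),
}

_NAMES = ("ts", "ps", "ce", "rd", "td", "pd")
_LOG = ("ts", "ce", "rd", "td")  # optimised as log10


@dataclass(frozen=True)
class FitConfig:
    """Solver settings for :func:`fit_circuit`."""

    weighting: str = "modulus"
    max_iterations: int = 1000
    tolerance: float = 1e-14
    n_starts: int = 8
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        if self.weighting not in ("unit", "modulus"):
            raise ValueError("weighting must be 'unit' or 'modulus'")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        for name in _NAMES:
            lo, hi = self.bounds[name]
            if not (0 <= lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a circuit fit."""

    params: CircuitParams
    cef: float
    cost: float
    converged: bool
    n_evaluations: int
    start_index: int


def residuals(params: CircuitParams, observed: ComplexSpectrum, weighting: str = "modulus") -> np.ndarray:
    """Interleaved weighted residuals [Re, Im] per frequency (length 2n).

    Unit weighting leaves the residuals in Ohm; modulus weighting divides
    both parts by |Z_obs(f)|, making them relative errors.
    """
    zm = circuit_impedance(params, observed.grid).z
    diff = zm - observed.z
    if weighting == "modulus":
        diff = diff / np.abs(observed.z)
    elif weighting != "unit":
        raise ValueError("weighting must be 'unit' or 'modulus'")
    out = np.empty(2 * diff.size)
    out[0::2] = diff.real
    out[1::2] = diff.imag
    return out


def _clip_to_bounds(values: dict[str, float], bounds: dict[str, tuple[float, float]]) -> CircuitParams:
    eps = 1e-12
    clipped = {
        k: float(np.clip(v, bounds[k][0] * (1 + eps) if bounds[k][0] > 0 else eps,
                         bounds[k][1] * (1 - eps)))
        for k, v in values.items()
    }
    return CircuitParams(**clipped)


def initial_guess(observed: ComplexSpectrum, bounds: dict[str, tuple[float, float]] | None = None) -> CircuitParams:
    """Heuristic starting point for the solver; always within bounds.

    Rd from the real-axis extent of the Nyquist arc; Ce from the imaginary
    part at the highest frequency (Ce ~ -1/(w*Im Z)); the bulk CPE exponent
    from the lowest-frequency phase; Td and Pd at the centre of the range
    typical for dispersed-medium double layers.
    """
    bounds = dict(DEFAULT_BOUNDS) if bounds is None else bounds
    z = observed.z
    w = observed.grid.omega
    rd = max(float(np.ptp(z.real)), 10.0)
    im_hi = float(z.imag[-1])
    ce = abs(1.0 / (w[-1] * im_hi)) if im_hi != 0 else 1e-6
    phase_lo = float(np.angle(z[0]))
    ps = float(np.clip(-phase_lo / np.pi, 0.05, 0.95))
    ts = 1.0 / (abs(z[0]) * w[0] ** ps)
    return _clip_to_bounds(
        {"ts": ts, "ps": ps, "ce": ce, "rd": rd, "td": 1e-6, "pd": 0.75}, bounds
    )


def _pack(p: CircuitParams) -> np.ndarray:
    vals = p.as_dict()
    return np.array([np.log10(vals[n]) if n in _LOG else vals[n] for n in _NAMES])


def _unpack(x: np.ndarray) -> CircuitParams:
    vals = {n: (10.0 ** x[i] if n in _LOG else float(x[i])) for i, n in enumerate(_NAMES)}
    return CircuitParams(**vals)


def fit_circuit(
    observed: ComplexSpectrum,
    config: FitConfig | None = None,
    init: CircuitParams | None = None,
) -> FitResult:
    """Fit the six circuit parameters to an observed complex spectrum.

    Runs ``config.n_starts`` bounded trust-region solves (start 0 from the
    heuristic or supplied ``init``, the rest jittered: log-uniform +-0.5
    decade on scale parameters, uniform +-0.1 on exponents) and returns the
    lowest-cost solution.  ``converged`` is False, not an exception, when
    the best run stopped on the iteration cap.
    """
    config = config or FitConfig()
    if len(observed.grid) < 4:
        raise ValueError("need at least 4 frequencies to fit 6 parameters")

    guess = init if init is not None else initial_guess(observed, config.bounds)
    x_guess = _pack(guess)
    lb = np.array([np.log10(config.bounds[n][0]) if n in _LOG else config.bounds[n][0] for n in _NAMES])
    ub = np.array([np.log10(config.bounds[n][1]) if n in _LOG else config.bounds[n][1] for n in _NAMES])
    log_idx = [i for i, n in enumerate(_NAMES) if n in _LOG]
    exp_idx = [i for i, n in enumerate(_NAMES) if n not in _LOG]

    def objective(x: np.ndarray) -> np.ndarray:
        return residuals(_unpack(x), observed, config.weighting)

    rng = np.random.default_rng(config.seed)
    best = None
    best_start = -1
    n_evals = 0
    errors: list[str] = []
    for start in range(config.n_starts):
        x0 = x_guess.copy()
        if start > 0:
            x0[log_idx] += rng.uniform(-0.5, 0.5, len(log_idx))
            x0[exp_idx] += rng.uniform(-0.1, 0.1, len(exp_idx))
        x0 = np.clip(x0, lb, ub)
        try:
            sol = least_squares(
                objective, x0, bounds=(lb, ub), method="trf",
                xtol=config.tolerance, ftol=config.tolerance, gtol=config.tolerance,
                max_nfev=config.max_iterations,
            )
        except Exception as exc:  # keep going; other starts may succeed
            errors.append(f"start {start}: {exc}")
            continue
        n_evals += sol.nfev
        if best is None or sol.cost < best.cost:
            best, best_start = sol, start
    if best is None:
        raise RuntimeError("all fit starts failed: " + "; ".join(errors))

    params = _unpack(best.x)
    return FitResult(
        params=params,
        cef=effective_capacitance(params),
        cost=float(2.0 * best.cost),  # least_squares cost is 0.5*sum(r^2)
        converged=bool(best.status > 0),
        n_evaluations=int(n_evals),
        start_index=int(best_start),
    )


class CircuitFitter(RegressorMixin, BaseEstimator):
    """sklearn-style estimator: frequencies + complex impedance -> circuit.

    ``fit(f, z)`` takes frequencies in Hz (1-D, or a single-column 2-D
    array) and the measured complex impedance per frequency; ``predict(f)``
    evaluates the fitted circuit.  Fitted attributes: ``params_``, ``cef_``,
    ``cost_``, ``converged_``, ``result_``.
    """

    def __init__(
        self,
        weighting: str = "modulus",
        max_iterations: int = 1000,
        tolerance: float = 1e-14,
        n_starts: int = 8,
        seed: int = 0,
        bounds: dict[str, tuple[float, float]] | None = None,
    ):
        self.weighting = weighting
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.n_starts = n_starts
        self.seed = seed
        self.bounds = bounds

    def _config(self) -> FitConfig:
        cfg = FitConfig(
            weighting=self.weighting,
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            n_starts=self.n_starts,
            seed=self.seed,
        )
        if self.bounds is not None:
            cfg = replace(cfg, bounds={**DEFAULT_BOUNDS, **self.bounds})
        return cfg

    @staticmethod
    def _spectrum(X, z) -> ComplexSpectrum:
        f = np.asarray(X, dtype=float)
        if f.ndim == 2 and f.shape[1] == 1:
            f = f[:, 0]
        z = np.asarray(z, dtype=complex)
        order = np.argsort(f)
        return ComplexSpectrum(FrequencyGrid(f[order]), z[order])

    def fit(self, X, y) -> "CircuitFitter":
        result = fit_circuit(self._spectrum(X, y), self._config())
        self.result_ = result
        self.params_ = result.params
        self.cef_ = result.cef
        self.cost_ = result.cost
        self.converged_ = result.converged
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        f = np.asarray(X, dtype=float)
        if f.ndim == 2 and f.shape[1] == 1:
            f = f[:, 0]
        order = np.argsort(f)
        z = circuit_impedance(self.params_, FrequencyGrid(f[order])).z
        out = np.empty_like(z)
        out[order] = z
        return out
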