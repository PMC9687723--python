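"""Concentration calibration: scalar response versus particle concentration.

A calibration run measures one scalar response per suspension concentration
-- either DMi at the reporting frequency or the effective capacitance Cef
from a circuit fit -- and fits an ordinary least-squares line

    response = slope * c + intercept

The slope is reported as the *sensitivity* of the sensor and R^2 as the
goodness of fit.  Inverting the line turns a measured response into a
concentration estimate, with an extrapolation warning outside the
calibrated range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CalibrationCurve",
    "LinearCalibration",
    "ExtrapolationWarning",
    "fit_calibration",
    "predict_concentration",
]


class ExtrapolationWarning(UserWarning):
    """A concentration estimate fell outside the calibrated range."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted linear response-vs-concentration map."""

    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    log_concentration: bool = False

    @property
    def n(self) -> int:
        return int(self.concentrations.size)


def _validate_xy(concentrations, responses) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(concentrations, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if c.size != y.size:
        raise ValueError("concentrations and responses must have equal length")
    if c.size < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.unique(c).size != c.size:
        raise ValueError("concentrations must be distinct")
    if np.ptp(y) == 0:
        raise ValueError("responses have zero variance; nothing to calibrate")
    return c, y


class LinearCalibration(RegressorMixin, BaseEstimator):
    """Ordinary least-squares calibration line, sklearn-style.

    Parameters
    ----------
    log_concentration
        Fit the response against log10(concentration) instead of the raw
        concentration.  Off by default; the raw-linear model is what makes
        the reported sensitivities interpretable as slopes.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted line coefficients (slope in response units per count/uL).
    r_squared_ : float
        1 - SS_res/SS_tot of the fit.
    curve_ : CalibrationCurve
        Frozen summary of the fit.
    """

    def __init__(self, log_concentration: bool = False):
        self.log_concentration = log_concentration

    def _design(self, c: np.ndarray) -> np.ndarray:
        return np.log10(c) if self.log_concentration else c

    def fit(self, X, y) -> "LinearCalibration":
        c, resp = _validate_xy(X, y)
        res = stats.linregress(self._design(c), resp)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.curve_ = CalibrationCurve(
            c, resp, self.slope_, self.intercept_, self.r_squared_,
            self.log_concentration,
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "slope_")
        c = np.asarray(X, dtype=float).ravel()
        return self.slope_ * self._design(c) + self.intercept_

    def predict_concentration(self, response: float) -> float:
        """Invert the calibration line for a measured response."""
        check_is_fitted(self, "slope_")
        return predict_concentration(self.curve_, response)


def fit_calibration(concentrations, responses, log_concentration: bool = False) -> CalibrationCurve:
    """Fit the OLS calibration line and return its frozen summary."""
    est = LinearCalibration(log_concentration=log_concentration)
    return est.fit(concentrations, responses).curve_


def predict_concentration(curve: CalibrationCurve, response: float) -> float:
    """Concentration at which the fitted line yields ``response``.

    Emits :class:`ExtrapolationWarning` when the estimate falls outside the
    calibrated concentration range.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; line is not invertible")
    x = (response - curve.intercept) / curve.slope
    c = 10.0**x if curve.log_concentration else x
    lo, hi = curve.concentrations.min(), curve.concentrations.max()
    if not lo <= c <= hi:
        warnings.warn(
            f"estimated concentration {c:.4g} /uL is outside the calibrated "
            f"range [{lo:g}, {hi:g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(c)
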