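"""Gompertz growth fitting and culture-level conversions.

Growth is modelled with the reparameterised (Zwietering) Gompertz curve
on the log relative cell number y(t) = ln(N_t/N_0):

    y(t) = A * exp(-exp(mu_max*e/A * (lambda - t) + 1))

with A = ln(N_inf/N_0) the maximal log relative population, mu_max the
maximum specific growth rate (the slope of the tangent at the inflection
point, per day) and lambda the lag time (days, the tangent's intercept
with y = 0).

Doubling times are reported in hours.  Two conventions are provided:
``decadic`` (24*log10(2)/mu) and ``natural`` (24*ln(2)/mu).  The decadic
convention is the default because it is the one internally consistent
with the growth-rate/doubling-time pairs this analysis is calibrated
against; see the methods note for the discussion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateInputWarning, LinearRangeWarning

__all__ = [
    "GrowthCurve",
    "GompertzParams",
    "od_to_cells",
    "gompertz_model",
    "GompertzGrowthModel",
    "fit_gompertz",
    "doubling_time",
    "chlorophyll_a",
    "OD_CONVERSION_ML_PER_CELL_CM",
    "CHLA_EXTINCTION_UG_ML_CM",
]

#: spectrophotometer calibration, ml cells-1 cm-1 A
OD_CONVERSION_ML_PER_CELL_CM = 2.95e-9
#: chlorophyll a extinction factor, ug ml-1 cm A-1 (methanol extract, 665 nm)
CHLA_EXTINCTION_UG_ML_CM = 12.9447
#: upper edge of the linear OD750/cell-count region
OD_LINEAR_RANGE_MAX = 0.8


@dataclass(frozen=True)
class GrowthCurve:
    """OD750 growth curve with per-sample dilution factors.

    ``n0_cells_per_ml`` is the reference (inoculum) count used for the
    log relative cell number; when omitted, the first sample is the
    reference, which introduces a small offset whenever the model value
    at the first sampling time is not exactly zero.
    """

    time_days: tuple
    od750: tuple
    dilution_factor: tuple = None
    conversion_ml_per_cell_cm: float = OD_CONVERSION_ML_PER_CELL_CM
    n0_cells_per_ml: float | None = None

    def __post_init__(self):
        t = np.asarray(self.time_days, dtype=float)
        od = np.asarray(self.od750, dtype=float)
        if t.size != od.size:
            raise ValueError("time and OD arrays differ in length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("OD750 must be non-negative")
        dil = self.dilution_factor
        dil = np.ones_like(od) if dil is None else np.asarray(dil, dtype=float)
        if dil.size != od.size:
            raise ValueError("dilution factors must match OD array")
        object.__setattr__(self, "time_days", tuple(t))
        object.__setattr__(self, "od750", tuple(od))
        object.__setattr__(self, "dilution_factor", tuple(dil))

    @property
    def cells_per_ml(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", LinearRangeWarning)
            return np.array([
                od_to_cells(o, self.conversion_ml_per_cell_cm, d)
                for o, d in zip(self.od750, self.dilution_factor)
            ])

    @property
    def log_ratio(self) -> np.ndarray:
        """y = ln(N_t/N_0) relative to the reference (or first) count."""
        n = self.cells_per_ml
        n0 = self.n0_cells_per_ml if self.n0_cells_per_ml else n[0]
        if n0 <= 0:
            raise ValueError("reference cell count must be positive")
        return np.log(n / n0)


@dataclass(frozen=True)
class GompertzParams:
    a_log: float
    mu_max: float
    lambda_lag: float
    a_log_se: float = 0.0
    mu_max_se: float = 0.0
    lambda_lag_se: float = 0.0

    def __post_init__(self):
        if self.a_log <= 0 or self.mu_max <= 0:
            raise ValueError("A and mu_max must be strictly positive")
        if self.lambda_lag < 0:
            raise ValueError("lag time must be non-negative")


def od_to_cells(
    od750: float,
    conversion_ml_per_cell_cm: float = OD_CONVERSION_ML_PER_CELL_CM,
    dilution_factor: float = 1.0,
) -> float:
    """Convert an OD750 reading to cells per ml.

    ``cells/ml = OD750 * dilution / conversion``.  Readings above the
    linear calibration region (OD 0.8) raise :class:`LinearRangeWarning`
    but are still converted.
    """
    if conversion_ml_per_cell_cm <= 0:
        raise ValueError("conversion factor must be positive")
    if od750 < 0:
        raise ValueError("OD750 must be non-negative")
    if od750 > OD_LINEAR_RANGE_MAX:
        warnings.warn(
            f"OD750 reading {od750} is above the linear range "
            f"(<= {OD_LINEAR_RANGE_MAX}); dilute the sample",
            LinearRangeWarning,
            stacklevel=2,
        )
    return od750 * dilution_factor / conversion_ml_per_cell_cm


def gompertz_model(t, a_log: float, mu_max: float, lambda_lag: float):
    """Zwietering Gompertz curve y(t) = ln(N_t/N_0); vectorised in t."""
    t = np.asarray(t, dtype=float)
    if a_log <= 0 or mu_max <= 0:
        raise ValueError("A and mu_max must be strictly positive")
    return a_log * np.exp(
        -np.exp(mu_max * math.e / a_log * (lambda_lag - t) + 1.0)
    )


class GompertzGrowthModel(BaseEstimator):
    """Nonlinear least-squares fit of the Gompertz curve to ln(N_t/N_0).

    Initial values are data driven: A0 = max(y); mu0 = the steepest
    finite-difference slope; lambda0 = the earliest time at which y
    exceeds 5% of A0.  Parameter standard errors come from the fit
    covariance.

    Attributes (after :meth:`fit`): ``a_log_``, ``mu_max_``,
    ``lambda_lag_``, their ``*_se_`` standard errors, ``cov_`` and
    ``params_`` (a :class:`GompertzParams`).
    """

    def __init__(self, maxfev: int = 20000):
        self.maxfev = maxfev

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        yv = np.asarray(y, dtype=float).ravel()
        if t.size != yv.size:
            raise ValueError("time and response differ in length")
        if t.size < 4:
            warnings.warn(
                "fewer than 4 points: the Gompertz fit is ill-conditioned",
                DegenerateInputWarning,
                stacklevel=2,
            )
        a0 = max(yv.max(), 1e-3)
        slopes = np.diff(yv) / np.diff(t)
        mu0 = max(slopes.max(), 1e-3) if slopes.size else 1e-3
        above = t[yv > 0.05 * a0]
        lam0 = float(above[0]) if above.size else 0.0
        try:
            popt, pcov = curve_fit(
                gompertz_model,
                t,
                yv,
                p0=[a0, mu0, lam0],
                maxfev=self.maxfev,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"Gompertz fit did not converge (p0={[a0, mu0, lam0]}): {exc}"
            ) from exc
        se = np.sqrt(np.diag(pcov))
        self.a_log_, self.mu_max_, self.lambda_lag_ = map(float, popt)
        self.a_log_se_, self.mu_max_se_, self.lambda_lag_se_ = map(float, se)
        self.cov_ = pcov
        self.params_ = GompertzParams(
            a_log=self.a_log_,
            mu_max=self.mu_max_,
            lambda_lag=max(self.lambda_lag_, 0.0),
            a_log_se=self.a_log_se_,
            mu_max_se=self.mu_max_se_,
            lambda_lag_se=self.lambda_lag_se_,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "a_log_")
        return gompertz_model(X, self.a_log_, self.mu_max_, self.lambda_lag_)


def fit_gompertz(curve: GrowthCurve) -> GompertzParams:
    """Fit the Gompertz model to a growth curve; convenience wrapper."""
    model = GompertzGrowthModel().fit(curve.time_days, curve.log_ratio)
    return model.params_


def doubling_time(mu_per_day: float, convention: str = "decadic") -> float:
    """Doubling time in hours from a specific growth rate in day-1.

    ``decadic``: 24*log10(2)/mu.  ``natural``: 24*ln(2)/mu.
    """
    if not (mu_per_day > 0):
        raise ValueError("growth rate must be strictly positive")
    if convention == "decadic":
        return 24.0 * math.log10(2.0) / mu_per_day
    if convention == "natural":
        return 24.0 * math.log(2.0) / mu_per_day
    raise ValueError("convention must be 'decadic' or 'natural'")


def chlorophyll_a(
    abs665: float,
    extinction_ug_ml_cm: float = CHLA_EXTINCTION_UG_ML_CM,
    path_cm: float = 1.0,
    extract_dilution: float = 1.0,
) -> float:
    """Chlorophyll a concentration (ug/ml) from methanol-extract A665."""
    if extinction_ug_ml_cm <= 0 or path_cm <= 0:
        raise ValueError("extinction factor and path length must be positive")
    if abs665 < 0:
        raise ValueError("absorbance must be non-negative")
    return abs665 * extinction_ug_ml_cm * extract_dilution / path_cm
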