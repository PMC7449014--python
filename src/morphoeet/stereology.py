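"""Spherocylinder (rod-cell) stereology and binned length-property regression.

A rod-shaped cell is modelled as a cylinder of length ``L - D`` capped by
two hemispheres of diameter ``D``, where ``L`` and ``D`` are the projected
pole-to-pole length and width.  The model gives closed forms for the
geometric outer-membrane surface area and the cell volume:

    A = pi*D*(L - D) + pi*D**2 = pi*D*L
    V = (pi/4)*D**2*(L - D) + (pi/6)*D**3 = (pi/4)*D**2*(L - D/3)

Population-level length->property relationships (width, area,
surface-to-volume ratio as functions of length) are estimated by binning
cells by length, averaging each bin, and fitting an ordinary
least-squares polynomial to the bin means with pointwise 95% confidence
bands on the mean response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (
    DimensionUnderflowError,
    ExtrapolationWarning,
    InsufficientBinsError,
    ShapeViolationError,
)
from .units import nm_to_um

__all__ = [
    "CellDimensions",
    "CellGeometry",
    "rod_area",
    "rod_volume",
    "sv_ratio",
    "cell_geometry",
    "periplasm_correct",
    "LengthPropertyRegressor",
    "bin_regress",
    "predict_mean_property",
    "PROPERTY_NAMES",
]

PROPERTY_NAMES = ("width", "area", "sv_ratio")


@dataclass(frozen=True)
class CellDimensions:
    """Projected dimensions of one rod-shaped cell, in micrometres."""

    length_um: float
    width_um: float

    def __post_init__(self):
        if not (self.width_um > 0):
            raise ShapeViolationError(
                f"width must be positive, got {self.width_um}"
            )
        if self.length_um < self.width_um:
            raise ShapeViolationError(
                "a rod's projected length must be at least its width "
                f"(L={self.length_um}, D={self.width_um})"
            )


@dataclass(frozen=True)
class CellGeometry:
    """Three-dimensional properties inferred from projected dimensions."""

    area_um2: float
    volume_um3: float
    sv_ratio_per_um: float


def rod_area(dims: CellDimensions) -> float:
    """Geometric outer-membrane surface area of a spherocylinder, um2.

    ``A = pi*D*L`` — the lateral cylinder area plus the two hemispherical
    caps collapse to a single product.  At ``L == D`` this is the sphere
    surface ``pi*D**2``.
    """
    return np.pi * dims.width_um * dims.length_um


def rod_volume(dims: CellDimensions) -> float:
    """Spherocylinder volume ``(pi/4)*D**2*(L - D/3)``, um3."""
    d, length = dims.width_um, dims.length_um
    return 0.25 * np.pi * d * d * (length - d / 3.0)


def sv_ratio(dims: CellDimensions) -> float:
    """Surface-to-volume ratio ``A/V = 4L/(D*(L - D/3))``, um-1.

    Decreases monotonically with length at fixed width and approaches the
    infinite-cylinder limit ``4/D``.
    """
    return rod_area(dims) / rod_volume(dims)


def cell_geometry(dims: CellDimensions) -> CellGeometry:
    a = rod_area(dims)
    v = rod_volume(dims)
    return CellGeometry(area_um2=a, volume_um3=v, sv_ratio_per_um=a / v)


def periplasm_correct(
    dims: CellDimensions, thickness_nm: float = 10.0
) -> CellDimensions:
    """Shrink both projected dimensions by twice the periplasm thickness.

    When the mediator is reduced at the plasma membrane rather than the
    outer membrane, the relevant geometry is the cell body inside the
    periplasmic space; each dimension loses twice its thickness (one layer
    per side).  The default 10 nm is the peptidoglycan-layer thickness for
    *Synechococcus*.
    """
    if thickness_nm < 0:
        raise ValueError("thickness must be non-negative")
    delta = 2.0 * nm_to_um(thickness_nm)
    new_l = dims.length_um - delta
    new_d = dims.width_um - delta
    if new_l <= 0 or new_d <= 0:
        raise DimensionUnderflowError(
            f"correcting by 2x{thickness_nm} nm gives a non-positive "
            f"dimension (L={new_l:.4g}, D={new_d:.4g} um)"
        )
    return CellDimensions(length_um=new_l, width_um=new_d)


def _property_values(
    lengths: np.ndarray, widths: np.ndarray, property_name: str
) -> np.ndarray:
    if property_name == "width":
        return widths
    if property_name == "area":
        return np.pi * widths * lengths
    if property_name == "sv_ratio":
        return 4.0 * lengths / (widths * (lengths - widths / 3.0))
    raise ValueError(
        f"unknown property {property_name!r}; expected one of {PROPERTY_NAMES}"
    )


class LengthPropertyRegressor(BaseEstimator, RegressorMixin):
    """Binned OLS regression of a per-cell property against cell length.

    Cells are discretised by length into left-closed, right-open bins of
    ``bin_width_um`` anchored at the minimum observed length.  Bins with
    fewer than ``min_bin_count`` cells are discarded; each remaining bin
    contributes one point (mean member length, mean property).  An
    ordinary least-squares polynomial of ``degree`` is fitted to the bin
    means, and pointwise 95% confidence bands on the mean response are
    exposed through :meth:`predict_interval`.

    Parameters
    ----------
    bin_width_um : float, default 0.4
        Width of the length bins.
    min_bin_count : int, default 50
        Minimum number of cells for a bin to qualify.
    degree : int, default 1
        Polynomial degree of the fitted model (1 = linear).

    Attributes
    ----------
    bin_mean_length_ : ndarray
        Mean member length per qualifying bin.
    bin_mean_property_ : ndarray
        Mean property per qualifying bin.
    bin_count_ : ndarray
        Number of cells per qualifying bin.
    results_ : statsmodels RegressionResults
        The fitted OLS model.
    length_range_ : tuple of float
        (min, max) of the qualifying bin mean lengths; predictions outside
        this range raise :class:`ExtrapolationWarning`.
    """

    def __init__(
        self,
        bin_width_um: float = 0.4,
        min_bin_count: int = 50,
        degree: int = 1,
    ):
        self.bin_width_um = bin_width_um
        self.min_bin_count = min_bin_count
        self.degree = degree

    def _design(self, lengths: np.ndarray) -> np.ndarray:
        return np.vander(np.asarray(lengths, dtype=float), self.degree + 1,
                         increasing=True)

    def fit(self, X, y):
        """Fit from per-cell lengths ``X`` (um) and property values ``y``."""
        lengths = np.asarray(X, dtype=float).ravel()
        values = np.asarray(y, dtype=float).ravel()
        if lengths.shape != values.shape:
            raise ValueError("lengths and property values differ in shape")
        if self.bin_width_um <= 0:
            raise ValueError("bin_width_um must be positive")
        idx = np.floor((lengths - lengths.min()) / self.bin_width_um).astype(int)
        mean_l, mean_y, counts = [], [], []
        for b in np.unique(idx):
            members = idx == b
            n = int(members.sum())
            if n < self.min_bin_count:
                continue
            mean_l.append(lengths[members].mean())
            mean_y.append(values[members].mean())
            counts.append(n)
        if len(mean_l) < 2:
            raise InsufficientBinsError(
                f"only {len(mean_l)} bin(s) hold >= {self.min_bin_count} "
                "cells; at least 2 are required"
            )
        self.bin_mean_length_ = np.asarray(mean_l)
        self.bin_mean_property_ = np.asarray(mean_y)
        self.bin_count_ = np.asarray(counts)
        self.results_ = sm.OLS(
            self.bin_mean_property_, self._design(self.bin_mean_length_)
        ).fit()
        self.length_range_ = (
            float(self.bin_mean_length_.min()),
            float(self.bin_mean_length_.max()),
        )
        return self

    def _warn_extrapolation(self, lengths: np.ndarray) -> np.ndarray:
        lo, hi = self.length_range_
        outside = (lengths < lo) | (lengths > hi)
        if outside.any():
            warnings.warn(
                f"{int(outside.sum())} length(s) outside fitted range "
                f"[{lo:.3g}, {hi:.3g}] um; extrapolating",
                ExtrapolationWarning,
                stacklevel=3,
            )
        return outside

    def predict(self, X):
        check_is_fitted(self, "results_")
        lengths = np.asarray(X, dtype=float).ravel()
        self._warn_extrapolation(lengths)
        return self.results_.predict(self._design(lengths))

    def predict_interval(self, X, alpha: float = 0.05):
        """Prediction and pointwise CI bounds on the mean response.

        Returns ``(predicted, lower, upper)`` arrays.
        """
        check_is_fitted(self, "results_")
        lengths = np.asarray(X, dtype=float).ravel()
        self._warn_extrapolation(lengths)
        pred = self.results_.get_prediction(self._design(lengths))
        ci = pred.conf_int(alpha=alpha)
        return pred.predicted_mean, ci[:, 0], ci[:, 1]


def bin_regress(
    cells: Iterable[CellDimensions],
    property_name: str,
    bin_width_um: float = 0.4,
    min_bin_count: int = 50,
    degree: int = 1,
) -> LengthPropertyRegressor:
    """Fit a binned length->property regression from a cell population.

    ``property_name`` is one of ``width``, ``area`` or ``sv_ratio``; the
    area and surface-to-volume regressions are fitted independently from
    per-cell spherocylinder values rather than derived from the width
    model.
    """
    cells = list(cells)
    lengths = np.array([c.length_um for c in cells])
    widths = np.array([c.width_um for c in cells])
    values = _property_values(lengths, widths, property_name)
    reg = LengthPropertyRegressor(
        bin_width_um=bin_width_um, min_bin_count=min_bin_count, degree=degree
    ).fit(lengths, values)
    reg.property_name = property_name
    return reg


def predict_mean_property(
    reg: LengthPropertyRegressor, lengths: Sequence[float]
):
    """Predict mean property at given lengths with a CI-derived uncertainty.

    The uncertainty of each prediction is the half-width between the
    prediction and its 95% confidence bound on the mean response, the
    convention used when regression curves stand in for directly measured
    population means.

    Returns ``(predicted, uncertainty)`` arrays.
    """
    predicted, lo, hi = reg.predict_interval(lengths)
    half_width = 0.5 * (hi - lo)
    return predicted, half_width
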