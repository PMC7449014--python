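"""Mediated extracellular-electron-transfer (EET) rate analysis.

Under mass-transfer limitation the per-cell ferricyanide reduction rate
obeys Fick's law across the concentration boundary layer,

    r = k * A * ([Fe3+]_b - [Fe3+]_s),

with k the liquid-to-cell mass-transfer coefficient, A the geometric
outer-membrane area, and the bracket the bulk-minus-surface mediator
concentration difference (delta c).  This module estimates r from assay
time courses, inverts the rate law for delta c, decouples the two
opposing effects of cell elongation on r via the chain rule, and
condenses a test-vs-control comparison into the morphology effect ratio

    MER = 1 / (1 + exp(-|delta(k*A)| / |delta(delta c)|)),

a sigmoid-squashed ratio in (0.5, 1): values above ~0.7311 (the sigmoid
at ratio 1) mean morphology-driven mass-transfer changes dominate the
observed EET-rate difference; values below mean physiological or
metabolic changes dominate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DenominatorZeroWarning
from .mass_transfer import MassTransferResult
from .units import (
    cells_per_ml_to_cells_per_l,
    mm_per_min_to_mol_per_l_s,
    um_to_m,
)

__all__ = [
    "AssayTimeSeries",
    "ReductionRate",
    "ConcDifference",
    "CultureSnapshot",
    "MERResult",
    "absorbance_to_conc",
    "reduction_rate",
    "mean_reduction_rate",
    "normalise_by_chla",
    "conc_difference",
    "rate_length_derivative",
    "fractional_differences",
    "morphology_effect_ratio",
    "mer_dominance",
    "correlate_with_properties",
    "compare_rates",
    "MER_BALANCED",
]

#: sigmoid(1): the MER value at which morphology and physiology contribute
#: equally to the observed EET-rate difference.
MER_BALANCED = 1.0 / (1.0 + math.exp(-1.0))


@dataclass(frozen=True)
class AssayTimeSeries:
    """Filtrate mediator concentration vs. time for one assay replicate."""

    times_min: tuple
    concentration_mM: tuple
    cell_conc_per_ml: float

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.concentration_mM, dtype=float)
        if t.size < 2:
            raise ValueError("an assay needs at least two time points")
        if t.size != c.size:
            raise ValueError("times and concentrations differ in length")
        if t[0] != 0:
            raise ValueError("the first sampling time must be 0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times_min", tuple(t))
        object.__setattr__(self, "concentration_mM", tuple(c))


@dataclass(frozen=True)
class ReductionRate:
    rate_mol_per_cell_s: float
    sem: float = 0.0

    def __post_init__(self):
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")


@dataclass(frozen=True)
class ConcDifference:
    delta_c_molm3: float
    sem: float = 0.0
    suspect_negative: bool = False


@dataclass(frozen=True)
class CultureSnapshot:
    """Per-timepoint population summary for one culture condition."""

    day: float
    condition: str
    mean_length_um: float
    sem_length: float
    mean_width_um: float
    mean_area_um2: float
    sem_area: float
    k_ms: float
    sem_k: float
    rate_mol_cell_s: float
    sem_rate: float
    delta_c_molm3: float
    sem_delta_c: float


@dataclass(frozen=True)
class MERResult:
    """Fractional differences (test vs. control) and the MER."""

    dk: float
    dA: float
    dkA: float
    ddc: float
    dr: float
    mer: float
    dominance: str


def absorbance_to_conc(
    absorbance: float,
    extinction_mM_cm: float = 1.05204,
    path_cm: float = 1.0,
) -> float:
    """Beer-Lambert conversion of filtrate absorbance to mM ferricyanide."""
    if extinction_mM_cm <= 0 or path_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    return absorbance / (extinction_mM_cm * path_cm)


def reduction_rate(series: AssayTimeSeries) -> ReductionRate:
    """Per-cell reduction rate from the slope of concentration vs. time.

    The average rate over the assay window is the magnitude of the OLS
    slope of the concentration-vs-time graph (mM/min), converted to
    mol L-1 s-1 and divided by the cell concentration in cells per litre
    to give mol cell-1 s-1.
    """
    if not (series.cell_conc_per_ml > 0):
        raise ValueError("cell concentration must be positive")
    t = np.asarray(series.times_min)
    c = np.asarray(series.concentration_mM)
    slope_mm_min = np.polyfit(t, c, 1)[0]
    rate_mol_l_s = abs(mm_per_min_to_mol_per_l_s(slope_mm_min))
    cells_per_l = cells_per_ml_to_cells_per_l(series.cell_conc_per_ml)
    return ReductionRate(rate_mol_per_cell_s=rate_mol_l_s / cells_per_l)


def mean_reduction_rate(replicates: Iterable[AssayTimeSeries]) -> ReductionRate:
    """Mean per-cell rate across assay replicates, SEM across replicates."""
    rates = [reduction_rate(s).rate_mol_per_cell_s for s in replicates]
    if not rates:
        raise ValueError("need at least one replicate")
    sem = stats.sem(rates) if len(rates) > 1 else 0.0
    return ReductionRate(rate_mol_per_cell_s=float(np.mean(rates)),
                         sem=float(sem))


def normalise_by_chla(rate_pM_min: float, chla_nM: float) -> float:
    """Normalise a pM/min volumetric rate by chlorophyll a in nM.

    Returns the rate in pM nM_ChlA-1 min-1.
    """
    if not (chla_nM > 0):
        raise ValueError("chlorophyll a concentration must be positive")
    return rate_pM_min / chla_nM


def _quadrature_relative(*pairs: Tuple[float, float]) -> float:
    """Combined relative error: sqrt(sum((sigma/x)**2)); pairs (x, sigma)."""
    total = 0.0
    for x, sigma in pairs:
        if sigma:
            total += (sigma / x) ** 2
    return math.sqrt(total)


def conc_difference(
    r: ReductionRate | float,
    k: MassTransferResult | float,
    area_m2: float,
    k_sem: float = 0.0,
    area_sem_m2: float = 0.0,
) -> ConcDifference:
    """Invert the mass-transfer-limited rate law for delta c = r/(k*A).

    The result is in mol m-3 (numerically mM).  Its SEM combines the
    relative errors of r, k and A in quadrature (first order,
    uncorrelated).  A negative delta c is physically suspect under
    mass-transfer limitation and is flagged, not rejected.
    """
    if isinstance(r, ReductionRate):
        r_val, r_sem = r.rate_mol_per_cell_s, r.sem
    else:
        r_val, r_sem = float(r), 0.0
    if isinstance(k, MassTransferResult):
        k_val = k.k_ms
    else:
        k_val = float(k)
    if not (k_val > 0) or not (area_m2 > 0):
        raise ValueError("k and A must be strictly positive")
    delta_c = r_val / (k_val * area_m2)
    if r_val != 0:
        rel = _quadrature_relative(
            (r_val, r_sem), (k_val, k_sem), (area_m2, area_sem_m2)
        )
        sem = abs(delta_c) * rel
    else:
        sem = 0.0
    return ConcDifference(
        delta_c_molm3=delta_c, sem=sem, suspect_negative=delta_c < 0
    )


def rate_length_derivative(
    length_um: float,
    width_um: float,
    k_ms: float,
    area_m2: float,
    delta_c_molm3: float,
    diffusivity_m2s: float = 7.44e-10,
) -> Tuple[float, float, float]:
    """Decouple the two opposing effects of elongation on the EET rate.

    By the chain rule, with A = pi*D*L and k's diffusive term 2*D_AB/L,

        dr/dL = [A * (-2*D_AB/L**2) + k * pi*D] * delta_c

    The first bracketed term (the k channel) is the loss of diffusive flux
    per unit area as the cell lengthens; the second (the A channel) is the
    gain in flux-bearing area.  Inputs are um for dimensions and SI for
    the rest; the derivative is returned per metre of length.

    Returns ``(dr_dL, k_channel, A_channel)``.
    """
    if min(length_um, width_um, k_ms, area_m2) <= 0:
        raise ValueError("all physical inputs must be strictly positive")
    length_m = um_to_m(length_um)
    width_m = um_to_m(width_um)
    expected_area = math.pi * width_m * length_m
    if abs(area_m2 - expected_area) > 1e-6 * expected_area:
        warnings.warn(
            "supplied area is not consistent with pi*D*L for the supplied "
            f"dimensions (got {area_m2:.4g}, expected {expected_area:.4g} m2)",
            UserWarning,
            stacklevel=2,
        )
    k_channel = area_m2 * (-2.0 * diffusivity_m2s / length_m ** 2) * delta_c_molm3
    a_channel = k_ms * math.pi * width_m * delta_c_molm3
    return k_channel + a_channel, k_channel, a_channel


def morphology_effect_ratio(dkA: float, ddc: float) -> float:
    """Sigmoid-squashed ratio |delta(k*A)| / |delta(delta c)|.

    Returns a value in (0.5, 1].  A zero denominator returns the sigmoid
    limit 1.0 and raises :class:`DenominatorZeroWarning`.
    """
    if ddc == 0:
        warnings.warn(
            "zero fractional difference in delta c; MER takes its limit 1",
            DenominatorZeroWarning,
            stacklevel=2,
        )
        return 1.0
    ratio = abs(dkA) / abs(ddc)
    return 1.0 / (1.0 + math.exp(-ratio))


def mer_dominance(mer: float, tol: float = 1e-6) -> str:
    """Classify an MER value against the balanced point sigmoid(1)."""
    if abs(mer - MER_BALANCED) <= tol:
        return "balanced"
    return "morphology" if mer > MER_BALANCED else "physiology"


def fractional_differences(
    test: CultureSnapshot, control: CultureSnapshot
) -> MERResult:
    """Fractional differences (test - control)/control and the MER.

    delta(k*A) is computed multiplicatively as (1+dk)*(1+dA)-1 so that the
    identity (1+dr) = (1+dk)*(1+dA)*(1+d(delta c)) holds exactly whenever
    r = k*A*delta_c holds on both sides.
    """
    for name, value in (
        ("k", control.k_ms),
        ("area", control.mean_area_um2),
        ("rate", control.rate_mol_cell_s),
        ("delta_c", control.delta_c_molm3),
    ):
        if value == 0:
            raise ZeroDivisionError(f"control {name} is zero")
    dk = (test.k_ms - control.k_ms) / control.k_ms
    dA = (test.mean_area_um2 - control.mean_area_um2) / control.mean_area_um2
    dkA = (1.0 + dk) * (1.0 + dA) - 1.0
    ddc = (
        test.delta_c_molm3 - control.delta_c_molm3
    ) / control.delta_c_molm3
    dr = (
        test.rate_mol_cell_s - control.rate_mol_cell_s
    ) / control.rate_mol_cell_s
    mer = morphology_effect_ratio(dkA, ddc) if ddc != 0 else (
        0.5 if dkA == 0 else morphology_effect_ratio(dkA, ddc)
    )
    return MERResult(
        dk=dk, dA=dA, dkA=dkA, ddc=ddc, dr=dr, mer=mer,
        dominance=mer_dominance(mer),
    )


def correlate_with_properties(
    delta_c_series: Sequence[float], property_series: Sequence[float]
) -> Tuple[float, float]:
    """Pearson correlation of delta c against a morphological property.

    Returns ``(r, p)`` with a two-tailed p value.
    """
    x = np.asarray(delta_c_series, dtype=float)
    y = np.asarray(property_series, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_rates(
    test_rates: Sequence[float],
    control_rates: Sequence[float],
    welch: bool = False,
) -> Tuple[float, float]:
    """One-tailed Student's t test (alternative: test > control).

    Pooled-variance by default, Welch optional.  Returns ``(t, p)``.
    """
    res = stats.ttest_ind(
        test_rates, control_rates, equal_var=not welch, alternative="greater"
    )
    return float(res.statistic), float(res.pvalue)
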