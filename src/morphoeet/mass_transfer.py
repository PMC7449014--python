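"""Liquid-to-cell mass-transfer coefficient for suspended microorganisms.

For small particles (1 um < d_p < 600 um) freely suspended in an agitated
vessel, the mass-transfer coefficient from the liquid phase to the
particle surface is well described by a two-term correlation

    k = 2*D_AB/d_p + 0.31 * (D_AB**2 * |rho_p - rho_c| * g / mu_c)**(1/3)

whose first term is molecular diffusion to a sphere of characteristic
size ``d_p`` and whose second term accounts for the free rise/fall of the
particle under gravity.  For rod-shaped cells the characteristic length
is the cell length ``L``, which dominates the evolution of ``k`` over a
growth cycle; the gravitational term is length-independent and, for cells
nearly neutrally buoyant in their medium, an order of magnitude smaller.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from .errors import ValidityRangeWarning
from .units import um_to_m

__all__ = [
    "PhysicalParams",
    "MassTransferResult",
    "mass_transfer_coefficient",
    "validity_check",
    "average_diffusivity",
    "propagate_k_error",
    "order_of_magnitude",
    "VALIDITY_RANGE_UM",
]

#: open interval of characteristic lengths (um) the correlation was fit on
VALIDITY_RANGE_UM = (1.0, 600.0)


@dataclass(frozen=True)
class PhysicalParams:
    """Physical constants for the correlation (defaults: ferricyanide in
    BG11 medium at ~30 C, cells near neutral buoyancy)."""

    diffusivity_m2s: float = 7.44e-10
    rho_p_kgm3: float = 1040.0
    rho_c_kgm3: float = 995.65
    g_ms2: float = 9.80665
    mu_c_kgms: float = 7.9735e-4

    def __post_init__(self):
        for name in (
            "diffusivity_m2s",
            "rho_p_kgm3",
            "rho_c_kgm3",
            "g_ms2",
            "mu_c_kgms",
        ):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class MassTransferResult:
    k_ms: float
    diffusive_term_ms: float
    gravitational_term_ms: float
    characteristic_length_m: float


def validity_check(length_um: float) -> Tuple[bool, str]:
    """Whether ``d_p`` lies inside the correlation's open fitted range."""
    lo, hi = VALIDITY_RANGE_UM
    if length_um <= lo:
        return False, f"characteristic length {length_um} um <= {lo} um"
    if length_um >= hi:
        return False, f"characteristic length {length_um} um >= {hi} um"
    return True, "within validity range"


def gravitational_term(params: PhysicalParams) -> float:
    """Length-independent free-rise/fall term, m/s."""
    delta_rho = abs(params.rho_p_kgm3 - params.rho_c_kgm3)
    return 0.31 * (
        params.diffusivity_m2s ** 2 * delta_rho * params.g_ms2
        / params.mu_c_kgms
    ) ** (1.0 / 3.0)


def mass_transfer_coefficient(
    length_um: float, params: PhysicalParams | None = None
) -> MassTransferResult:
    """Evaluate the two-term correlation at characteristic length ``d_p``.

    ``length_um`` is the cell length in micrometres; it is converted to
    metres internally.  A length outside the fitted (1, 600) um range
    raises :class:`ValidityRangeWarning` but the value is still returned,
    flagged by the warning.
    """
    if params is None:
        params = PhysicalParams()
    if not (length_um > 0):
        raise ValueError("characteristic length must be positive")
    ok, reason = validity_check(length_um)
    if not ok:
        warnings.warn(
            f"correlation applied outside its fitted range: {reason}",
            ValidityRangeWarning,
            stacklevel=2,
        )
    d_p = um_to_m(length_um)
    diff = 2.0 * params.diffusivity_m2s / d_p
    grav = gravitational_term(params)
    return MassTransferResult(
        k_ms=diff + grav,
        diffusive_term_ms=diff,
        gravitational_term_ms=grav,
        characteristic_length_m=d_p,
    )


def average_diffusivity(
    values: Sequence[float | Tuple[float, float]]
) -> float:
    """Arithmetic mean of literature diffusivities.

    Entries may be bare diffusivities (m2/s) or ``(diffusivity,
    temperature_C)`` pairs; temperatures are metadata only and do not
    enter the average.
    """
    values = list(values)
    if not values:
        raise ValueError("need at least one diffusivity")
    d = [v[0] if isinstance(v, (tuple, list)) else v for v in values]
    return float(np.mean(d))


def propagate_k_error(
    length_um: float, length_sem_um: float, params: PhysicalParams | None = None
) -> float:
    """First-order standard error of k from the length standard error.

    Only the diffusive term depends on length, so
    ``sigma_k = (2*D_AB/L**2) * sigma_L`` in SI units.
    """
    if params is None:
        params = PhysicalParams()
    if length_sem_um < 0:
        raise ValueError("length SEM must be non-negative")
    length_m = um_to_m(length_um)
    sem_m = um_to_m(length_sem_um)
    return 2.0 * params.diffusivity_m2s / length_m ** 2 * sem_m


def order_of_magnitude(x: float) -> int:
    """floor(log10(x)) for x > 0."""
    if not (x > 0):
        raise ValueError("order of magnitude requires a positive value")
    return math.floor(math.log10(x))
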