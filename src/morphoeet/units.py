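"""Centralised unit conversions.

All geometry is carried in micrometres and converted to SI (m, m2, m3)
only at the mass-transfer boundary; concentrations are carried in
mol m-3, which is numerically identical to mM.  Every conversion used
anywhere in the package lives here so that unit bookkeeping is audited
in one place.
"""

from __future__ import annotations

M_PER_UM = 1e-6
M2_PER_UM2 = 1e-12
M3_PER_UM3 = 1e-18
UM_PER_NM = 1e-3

#: 1 mM == 1 mol m-3 in coherent SI.
MOL_M3_PER_MM = 1.0

SECONDS_PER_MINUTE = 60.0
SECONDS_PER_HOUR = 3600.0
HOURS_PER_DAY = 24.0

CELLS_PER_L_PER_CELLS_PER_ML = 1e3


def um_to_m(x: float) -> float:
    return x * M_PER_UM


def um2_to_m2(x: float) -> float:
    return x * M2_PER_UM2


def nm_to_um(x: float) -> float:
    return x * UM_PER_NM


def mm_per_min_to_mol_per_l_s(slope_mm_min: float) -> float:
    """Spectrophotometric decay slope (mM/min) to mol L-1 s-1."""
    return slope_mm_min * 1e-3 / SECONDS_PER_MINUTE


def cells_per_ml_to_cells_per_l(c: float) -> float:
    return c * CELLS_PER_L_PER_CELLS_PER_ML


def nmol_per_1e6cells_h_to_mol_cell_s(rate: float) -> float:
    """Literature per-cell rate, nmol (1e6 cells)-1 h-1, to mol cell-1 s-1."""
    return rate * 1e-9 / (1e6 * SECONDS_PER_HOUR)


def mm_per_mm_chla_h_to_pm_per_nm_chla_min(rate: float) -> float:
    """Chlorophyll-a-normalised rate, mM mM_ChlA-1 h-1, to pM nM_ChlA-1 min-1.

    mM -> pM multiplies by 1e9, per-mM -> per-nM divides by 1e6, per-h ->
    per-min divides by 60: the net factor is 1000/60.
    """
    return rate * 1000.0 / 60.0
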