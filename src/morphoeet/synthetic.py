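"""Synthetic fixtures with known ground truth for the full pipeline.

Generates the four input kinds the measurement pipeline consumes:

* per-cell projected dimension tables drawn from a truncated length
  distribution with a linear width-vs-length law,
* rendered fluorescence images of spherocylindrical cells with Gaussian
  point-spread blur and detector noise,
* ferricyanide assay time courses decaying linearly at the slope implied
  by a chosen per-cell rate, with additive spectrophotometric noise,
* Gompertz-shaped OD750 growth curves with multiplicative noise.

Every generator is a pure function of its spec and seed: identical
inputs give bit-identical outputs.  Defaults describe an exponential-
phase *Synechococcus elongatus* population (mean length 3.7 um, width
about 1.2 um, 1 mM mediator, 6.78e8 cells/ml).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .eet import AssayTimeSeries
from .growth import (
    GompertzParams,
    GrowthCurve,
    OD_CONVERSION_ML_PER_CELL_CM,
    gompertz_model,
)
from .stereology import CellDimensions, cell_geometry

__all__ = [
    "PopulationSpec",
    "ImageSpec",
    "sample_population",
    "render_image",
    "simulate_assay",
    "simulate_growth",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a rod-cell population.

    Lengths are drawn from a truncated Normal (or log-Normal) in um;
    widths follow ``D = intercept + slope*L + N(0, noise_sd)``, clipped
    so that ``L >= D > 0`` always holds.
    """

    n_cells: int = 3000
    length_mean_um: float = 3.7
    length_sd_um: float = 0.7
    length_bounds_um: Tuple[float, float] = (1.5, 8.0)
    length_family: str = "truncnorm"
    width_intercept_um: float = 1.02
    width_slope: float = 0.05
    width_noise_sd_um: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_bounds_um
        if not (0 < lo < hi):
            raise ValueError("length bounds must satisfy 0 < lo < hi")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.length_family not in ("truncnorm", "lognorm"):
            raise ValueError("length_family must be truncnorm or lognorm")
        if self.length_family == "truncnorm" and self.length_sd_um > 0:
            a = (lo - self.length_mean_um) / self.length_sd_um
            b = (hi - self.length_mean_um) / self.length_sd_um
            if stats.norm.cdf(b) - stats.norm.cdf(a) < 1e-12:
                raise ValueError("truncation bounds leave empty support")


def _sample_lengths(spec: PopulationSpec, rng: np.random.Generator):
    lo, hi = spec.length_bounds_um
    if spec.length_sd_um == 0:
        return np.full(spec.n_cells, spec.length_mean_um)
    if spec.length_family == "truncnorm":
        a = (lo - spec.length_mean_um) / spec.length_sd_um
        b = (hi - spec.length_mean_um) / spec.length_sd_um
        return stats.truncnorm.rvs(
            a, b, loc=spec.length_mean_um, scale=spec.length_sd_um,
            size=spec.n_cells, random_state=rng,
        )
    # log-Normal parameterised by the target mean/SD of L itself
    sigma2 = math.log(1 + (spec.length_sd_um / spec.length_mean_um) ** 2)
    mu = math.log(spec.length_mean_um) - sigma2 / 2
    out = np.exp(rng.normal(mu, math.sqrt(sigma2), size=spec.n_cells))
    return np.clip(out, lo, hi)


def sample_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a cell population and its ground-truth geometry.

    Returns a DataFrame with columns ``cell_id, length_um, width_um,
    area_um2, volume_um3, sv_ratio_per_um, orientation_rad``.
    """
    rng = np.random.default_rng(spec.seed)
    lengths = _sample_lengths(spec, rng)
    widths = (
        spec.width_intercept_um
        + spec.width_slope * lengths
        + rng.normal(0.0, spec.width_noise_sd_um, size=spec.n_cells)
    )
    # enforce the rod invariant L >= D > 0
    widths = np.clip(widths, 0.2, lengths)
    orientations = rng.uniform(0.0, np.pi, size=spec.n_cells)
    rows = []
    for i, (length, width, theta) in enumerate(
        zip(lengths, widths, orientations)
    ):
        geom = cell_geometry(CellDimensions(length_um=length, width_um=width))
        rows.append(
            {
                "cell_id": i,
                "length_um": length,
                "width_um": width,
                "area_um2": geom.area_um2,
                "volume_um3": geom.volume_um3,
                "sv_ratio_per_um": geom.sv_ratio_per_um,
                "orientation_rad": theta,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ImageSpec:
    """Specification of a rendered fluorescence field of view."""

    shape_px: Tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.1
    min_separation_um: float = 1.0
    allow_overlap: bool = False
    psf_sigma_px: float = 1.0
    background: float = 20.0
    foreground: float = 200.0
    gaussian_noise_sd: float = 5.0
    poisson_noise: bool = False
    margin_px: int = 8
    max_placement_tries: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.shape_px) <= 0 or self.pixel_size_um <= 0:
            raise ValueError("image dimensions and pixel size must be positive")
        if self.gaussian_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def _spherocylinder_mask(
    shape: Tuple[int, int],
    centre_rc: Tuple[float, float],
    length_px: float,
    width_px: float,
    theta: float,
) -> np.ndarray:
    """Rasterise a spherocylinder footprint: pixels within width/2 of the
    central segment of length ``length - width``."""
    half_seg = max(length_px - width_px, 0.0) / 2.0
    radius = width_px / 2.0
    r0, c0 = centre_rc
    # bounding window
    ext = int(np.ceil(length_px / 2 + 2))
    rlo = max(int(r0) - ext, 0)
    rhi = min(int(r0) + ext + 1, shape[0])
    clo = max(int(c0) - ext, 0)
    chi = min(int(c0) + ext + 1, shape[1])
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    # axis unit vector (image rows increase downward; angle vs column axis)
    ur, uc = -math.sin(theta), math.cos(theta)
    dr, dc = rr - r0, cc - c0
    proj = np.clip(dr * ur + dc * uc, -half_seg, half_seg)
    dist2 = (dr - proj * ur) ** 2 + (dc - proj * uc) ** 2
    window = dist2 <= radius ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[rlo:rhi, clo:chi] = window
    return mask


def render_image(
    cells: pd.DataFrame, spec: ImageSpec
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a field of view containing the given cells.

    ``cells`` needs columns ``length_um, width_um`` (and optionally
    ``orientation_rad``).  Cells are placed uniformly at random subject
    to a minimum centre separation unless ``allow_overlap``; footprints
    are rasterised, blurred with a Gaussian PSF and corrupted with noise.

    Returns ``(image, label_mask, placements)`` where ``label_mask``
    holds the ground-truth footprint of cell i as label i+1 and
    ``placements`` records centres and orientations.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    label_mask = np.zeros((h, w), dtype=np.int32)
    clean = np.full((h, w), spec.background, dtype=float)
    min_sep_px = spec.min_separation_um / spec.pixel_size_um
    centres: list[Tuple[float, float]] = []
    records = []
    for i, row in enumerate(cells.itertuples(index=False)):
        length_px = row.length_um / spec.pixel_size_um
        width_px = row.width_um / spec.pixel_size_um
        theta = getattr(row, "orientation_rad", None)
        if theta is None or (isinstance(theta, float) and np.isnan(theta)):
            theta = rng.uniform(0.0, np.pi)
        margin = spec.margin_px + length_px / 2
        if 2 * margin >= min(h, w):
            raise ValueError("cell does not fit the canvas")
        placed = False
        for _ in range(spec.max_placement_tries):
            r0 = rng.uniform(margin, h - margin)
            c0 = rng.uniform(margin, w - margin)
            if not spec.allow_overlap and any(
                (r0 - rr) ** 2 + (c0 - cc) ** 2 < min_sep_px ** 2
                for rr, cc in centres
            ):
                continue
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i} after "
                f"{spec.max_placement_tries} tries; reduce density or "
                "min separation"
            )
        centres.append((r0, c0))
        footprint = _spherocylinder_mask(
            (h, w), (r0, c0), length_px, width_px, theta
        )
        label_mask[footprint] = i + 1
        clean[footprint] = spec.foreground
        records.append(
            {
                "cell_id": i,
                "row": r0,
                "col": c0,
                "orientation_rad": theta,
                "length_um": row.length_um,
                "width_um": row.width_um,
            }
        )
    image = clean
    if spec.psf_sigma_px > 0:
        image = gaussian_filter(image, spec.psf_sigma_px)
    if spec.poisson_noise:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if spec.gaussian_noise_sd > 0:
        image = image + rng.normal(0.0, spec.gaussian_noise_sd, size=image.shape)
    return image, label_mask, pd.DataFrame(records)


def simulate_assay(
    true_rate_mol_cell_s: float,
    cell_conc_per_ml: float = 6.78e8,
    c0_mM: float = 1.0,
    times_min: Sequence[float] = (0.0, 10.0, 30.0, 120.0),
    noise_sd_mM: float = 0.0,
    seed: int = 0,
) -> AssayTimeSeries:
    """Linear-decay assay trace at the slope implied by a per-cell rate.

    The decay slope in mM/min is ``rate * cells_per_L * 60 * 1000``
    (mol L-1 s-1 scaled to mM and minutes).  Gaussian noise is added to
    each concentration; traces that would go negative are clipped at
    zero with a warning.
    """
    if noise_sd_mM < 0:
        raise ValueError("noise SD must be non-negative")
    if true_rate_mol_cell_s < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.asarray(times_min, dtype=float)
    cells_per_l = cell_conc_per_ml * 1e3
    slope_mm_min = true_rate_mol_cell_s * cells_per_l * 60.0 * 1e3
    conc = c0_mM - slope_mm_min * t
    if np.any(conc < 0):
        warnings.warn(
            "decay exhausts the mediator inside the assay window; "
            "concentrations truncated at 0",
            UserWarning,
            stacklevel=2,
        )
        conc = np.clip(conc, 0.0, None)
    if noise_sd_mM > 0:
        conc = np.clip(conc + rng.normal(0.0, noise_sd_mM, size=t.size), 0.0, None)
    return AssayTimeSeries(
        times_min=tuple(t),
        concentration_mM=tuple(conc),
        cell_conc_per_ml=cell_conc_per_ml,
    )


def simulate_growth(
    params: GompertzParams,
    sampling_days: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n0_cells_per_ml: float = 0.1 / OD_CONVERSION_ML_PER_CELL_CM,
) -> GrowthCurve:
    """Gompertz-shaped OD750 growth curve with multiplicative noise.

    OD values follow ``OD = N0*exp(y(t)) * conversion`` with y the
    Gompertz log relative cell number; noise multiplies each OD by
    ``1 + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(sampling_days, dtype=float)
    y = gompertz_model(t, params.a_log, params.mu_max, params.lambda_lag)
    cells = n0_cells_per_ml * np.exp(y)
    od = cells * OD_CONVERSION_ML_PER_CELL_CM
    if noise_sd > 0:
        od = od * (1.0 + rng.normal(0.0, noise_sd, size=t.size))
        od = np.clip(od, 1e-9, None)
    return GrowthCurve(
        time_days=tuple(t), od750=tuple(od),
        n0_cells_per_ml=n0_cells_per_ml,
    )
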