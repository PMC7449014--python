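"""Per-cell morphometry from fluorescence images.

Images are binarised by intensity thresholding, connected components are
labelled with 8-connectivity, and each component is summarised by the
ellipse with the same normalised second central moments as the pixel
set: axis lengths are 4*sqrt(eigenvalue) of the pixel-coordinate
covariance, so a component's projected length and width are the major
and minor axis lengths of that ellipse.  Quality-control rules remove
regions that are out of focus (near-circular), overlapping/dividing
(too wide) or too small to be cells.

Coordinate convention: pixel centres at integer coordinates, row-major,
origin at the top-left corner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats
from skimage import measure
from skimage.filters import threshold_otsu, threshold_triangle

from .errors import DegenerateInputWarning
from .stereology import CellDimensions

__all__ = [
    "LabelledRegion",
    "QCConfig",
    "binarise",
    "fit_ellipses",
    "qc_filter",
    "to_microns",
    "weighted_population_stats",
    "compare_lengths",
]


@dataclass(frozen=True)
class LabelledRegion:
    """One connected component and its moment-ellipse summary."""

    label: int
    centroid_rc: Tuple[float, float]
    area_px: int
    major_axis_px: float
    minor_axis_px: float
    eccentricity: float
    orientation_rad: float
    bbox: Tuple[int, int, int, int]
    touches_border: bool


@dataclass(frozen=True)
class QCConfig:
    """Quality-control cut-offs for morphometry.

    The rules mirror standard practice for rod-cell imaging: a minimum
    eccentricity rejects out-of-focus near-circular blobs, a maximum
    minor-axis length rejects merged (overlapping or dividing) cells, a
    minimum pixel area rejects debris, and border-touching regions are
    excluded because their dimensions are truncated.  The numeric values
    are calibration choices, fully configurable.
    """

    min_eccentricity: float = 0.6
    max_minor_axis_um: float = 2.0
    min_area_px: int = 20
    exclude_border: bool = True

    def __post_init__(self):
        if self.min_eccentricity < 0 or self.max_minor_axis_um < 0:
            raise ValueError("QC thresholds must be non-negative")
        if self.min_area_px < 0:
            raise ValueError("minimum area must be non-negative")


def binarise(
    image: np.ndarray,
    method: str = "triangle",
    manual_threshold: float | None = None,
) -> Tuple[np.ndarray, float]:
    """Threshold an intensity image into a boolean foreground mask.

    Returns ``(mask, threshold)`` so the chosen threshold can be logged
    for provenance.  The default is the triangle method, which stays
    robust when fluorescent cells cover only a small fraction of the
    field of view (the usual confocal situation, where Otsu's equal-
    variance split drifts into the background noise); Otsu and a manual
    threshold are available as alternatives.  A constant image has no
    separable histogram: an empty mask is returned with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual method requires manual_threshold")
        thr = float(manual_threshold)
    elif method in ("triangle", "otsu"):
        if img.min() == img.max():
            warnings.warn(
                "constant image: no threshold separates foreground; "
                "returning an empty mask",
                DegenerateInputWarning,
                stacklevel=2,
            )
            return np.zeros(img.shape, dtype=bool), float(img.min())
        chooser = threshold_triangle if method == "triangle" else threshold_otsu
        thr = float(chooser(img))
    else:
        raise ValueError(f"unknown binarisation method {method!r}")
    return img > thr, thr


def fit_ellipses(mask: np.ndarray) -> List[LabelledRegion]:
    """Label 8-connected components and fit moment-equivalent ellipses.

    Axis lengths follow the 4*sqrt(eigenvalue) convention on the
    normalised second central moments of the member pixels.  Returns an
    empty list for an empty mask.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    h, w = mask.shape
    regions = []
    for rp in measure.regionprops(labels):
        r0, c0, r1, c1 = rp.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        regions.append(
            LabelledRegion(
                label=int(rp.label),
                centroid_rc=tuple(map(float, rp.centroid)),
                area_px=int(rp.area),
                major_axis_px=float(rp.axis_major_length),
                minor_axis_px=float(rp.axis_minor_length),
                eccentricity=float(rp.eccentricity),
                orientation_rad=float(rp.orientation),
                bbox=rp.bbox,
                touches_border=touches,
            )
        )
    return regions


def qc_filter(
    regions: Sequence[LabelledRegion],
    cfg: QCConfig,
    pixel_size_um: float,
) -> Tuple[List[LabelledRegion], List[dict]]:
    """Apply QC rules; return kept regions and an exhaustive rejection log.

    Each rejected region appears exactly once in the log, tagged with the
    first rule it failed (rules are checked in a fixed order: area,
    border, eccentricity, minor axis).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    kept: List[LabelledRegion] = []
    rejected: List[dict] = []
    for region in regions:
        if region.area_px < cfg.min_area_px:
            rejected.append(
                {"region": region, "rule_failed": "min_area_px",
                 "value": region.area_px}
            )
            continue
        if cfg.exclude_border and region.touches_border:
            rejected.append(
                {"region": region, "rule_failed": "exclude_border",
                 "value": True}
            )
            continue
        if region.eccentricity < cfg.min_eccentricity:
            rejected.append(
                {"region": region, "rule_failed": "min_eccentricity",
                 "value": region.eccentricity}
            )
            continue
        minor_um = region.minor_axis_px * pixel_size_um
        if minor_um > cfg.max_minor_axis_um:
            rejected.append(
                {"region": region, "rule_failed": "max_minor_axis_um",
                 "value": minor_um}
            )
            continue
        kept.append(region)
    return kept, rejected


def to_microns(region: LabelledRegion, pixel_size_um: float) -> CellDimensions:
    """Convert a region's ellipse axes to projected cell dimensions."""
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    return CellDimensions(
        length_um=region.major_axis_px * pixel_size_um,
        width_um=region.minor_axis_px * pixel_size_um,
    )


def weighted_population_stats(
    per_image_means: Sequence[float], per_image_counts: Sequence[int]
) -> Tuple[float, float, float]:
    """Count-weighted mean, SD and SEM of the sampling distribution.

    Per-image mean dimensions are samples of the sampling distribution of
    the mean; weighting by per-image cell count corrects for the unequal
    number of cells contributing to each image.  Returns ``(weighted
    mean, weighted SD of the image means, SEM = SD/sqrt(n_images))``.  A
    single image gives a degenerate (zero) SD and is flagged.
    """
    means = np.asarray(per_image_means, dtype=float)
    counts = np.asarray(per_image_counts, dtype=float)
    if means.size == 0:
        raise ValueError("need at least one image")
    if means.shape != counts.shape:
        raise ValueError("means and counts differ in length")
    if np.any(counts < 1):
        raise ValueError("counts must be >= 1")
    wmean = float(np.sum(counts * means) / np.sum(counts))
    if means.size == 1:
        warnings.warn(
            "single image: the SD of the sampling distribution is degenerate",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return wmean, 0.0, 0.0
    wvar = float(np.sum(counts * (means - wmean) ** 2) / np.sum(counts))
    wsd = float(np.sqrt(wvar))
    wsem = wsd / np.sqrt(means.size)
    return wmean, wsd, float(wsem)


def compare_lengths(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> Tuple[float, float]:
    """Two-tailed Student's t test on cell lengths.

    Pooled-variance by default (Welch optional).  Returns ``(t, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both groups have zero variance; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
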