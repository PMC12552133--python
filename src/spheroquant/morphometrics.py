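"""Spheroid segmentation and shape metrics from label-free images.

A spheroid imaged in transmitted light appears as a dark, roughly circular
object on a bright background.  :func:`segment_spheroid` recovers a single
connected mask by global thresholding, hole filling, morphological opening
and largest-component selection; :func:`compute_morphometrics` then reports
the standard shape descriptors:

* area ``A`` (µm²) and perimeter ``P`` (µm; Crofton estimator, which is
  nearly unbiased on smooth rasterized shapes),
* equivalent-area diameter ``2 * sqrt(A / pi)``,
* circularity ``4 * pi * A / P**2`` (1 for a perfect disk),
* aspect ratio = major / minor axis of the best-fit ellipse from second
  image moments (always >= 1).

:func:`growth_curve` maps a time series of images to a diameter-versus-time
curve, recording failed timepoints as missing rather than interpolating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, perimeter_crofton, regionprops
from skimage.morphology import disk, opening

from .errors import ConfigError, SegmentationError

__all__ = [
    "SegmentationParams",
    "SpheroidMask",
    "Morphometrics",
    "GrowthCurve",
    "segment_spheroid",
    "compute_morphometrics",
    "growth_curve",
]

MIN_MASK_PIXELS = 9


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the global-threshold segmentation.

    ``dark_object`` inverts the image first (spheroid darker than
    background).  ``threshold_offset`` is added to the Otsu threshold on the
    working (possibly inverted) image — useful for low-contrast frames.
    ``opening_radius`` is the structuring-disk radius (px) of the smoothing
    opening.  ``border_fraction_limit`` rejects masks that touch at least
    this fraction of the image border.
    """

    dark_object: bool = True
    threshold_offset: float = 0.0
    opening_radius: int = 2
    border_fraction_limit: float = 0.5

    def __post_init__(self) -> None:
        if self.opening_radius < 0:
            raise ConfigError("opening_radius must be >= 0")
        if not 0 < self.border_fraction_limit <= 1:
            raise ConfigError("border_fraction_limit must be in (0, 1]")


@dataclass(frozen=True)
class SpheroidMask:
    """A single-component binary spheroid mask with physical pixel size."""

    mask: np.ndarray
    pixel_size: float
    source: str = ""
    params: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be > 0")
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise SegmentationError("no spheroid detected")
        if label(m).max() != 1:
            raise SegmentationError("mask must contain exactly one component")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class Morphometrics:
    """Shape record of a segmented spheroid (lengths in µm, areas in µm²)."""

    area: float
    perimeter: float
    equivalent_diameter: float
    circularity: float
    aspect_ratio: float
    major_axis: float
    minor_axis: float


@dataclass(frozen=True)
class GrowthCurve:
    """Diameter-versus-time with per-timepoint morphometrics.

    ``diameters`` contains NaN at timepoints where segmentation failed.
    """

    times: np.ndarray
    diameters: np.ndarray
    records: list  # Morphometrics | None per timepoint

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, d, m in zip(self.times, self.diameters, self.records):
            rows.append(
                {
                    "time_d": t,
                    "area_um2": m.area if m else np.nan,
                    "perimeter_um": m.perimeter if m else np.nan,
                    "diameter_um": d,
                    "circularity": m.circularity if m else np.nan,
                    "aspect_ratio": m.aspect_ratio if m else np.nan,
                }
            )
        return pd.DataFrame(rows)


def segment_spheroid(
    image: np.ndarray,
    pixel_size: float = 1.0,
    params: SegmentationParams | None = None,
    source: str = "",
) -> SpheroidMask:
    """Segment a single spheroid from a label-free 2D image.

    Global Otsu threshold (on the inverted image when the object is dark),
    hole filling, morphological opening, then the largest connected
    component.  Raises :class:`SegmentationError` rather than returning an
    empty or border-dominated mask.
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise SegmentationError("expected a nonempty 2D image")

    work = img.max() - img if params.dark_object else img
    if np.ptp(work) == 0:
        raise SegmentationError("no spheroid detected")
    thr = threshold_otsu(work) + params.threshold_offset
    fg = work > thr
    if not fg.any():
        raise SegmentationError("no spheroid detected")

    fg = ndimage.binary_fill_holes(fg)
    if params.opening_radius > 0:
        fg = opening(fg, disk(params.opening_radius))
    if not fg.any():
        raise SegmentationError("no spheroid detected")

    lab = label(fg)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    largest = sizes.argmax()
    mask = lab == largest

    border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    if border.mean() >= params.border_fraction_limit:
        raise SegmentationError("segmentation unreliable")

    return SpheroidMask(mask=mask, pixel_size=pixel_size, source=source, params=params)


def compute_morphometrics(mask: SpheroidMask) -> Morphometrics:
    """Compute shape metrics of a segmented spheroid in physical units."""
    m = mask.mask
    if m.sum() < MIN_MASK_PIXELS:
        raise SegmentationError("mask too small")
    px = mask.pixel_size

    props = regionprops(m.astype(np.uint8))[0]
    area = float(m.sum()) * px**2
    perim = float(perimeter_crofton(m, directions=4)) * px
    eq_diam = 2.0 * np.sqrt(area / np.pi)
    circularity = 4.0 * np.pi * area / perim**2
    major = float(props.axis_major_length) * px
    minor = float(props.axis_minor_length) * px
    aspect = major / minor if minor > 0 else np.inf
    return Morphometrics(
        area=area,
        perimeter=perim,
        equivalent_diameter=eq_diam,
        circularity=circularity,
        aspect_ratio=aspect,
        major_axis=major,
        minor_axis=minor,
    )


def growth_curve(
    images: Sequence[np.ndarray],
    times: Sequence[float],
    pixel_size: float = 1.0,
    params: SegmentationParams | None = None,
) -> GrowthCurve:
    """Diameter-over-time from a label-free time series.

    Diameter is the equivalent-area diameter of the per-timepoint mask.
    Timepoints where segmentation fails are recorded as NaN (missing), never
    interpolated; if every timepoint fails the series is unusable.
    """
    times = np.asarray(times, dtype=float)
    if len(images) != times.size:
        raise ConfigError("one image per timepoint required")
    if times.size < 2:
        raise ConfigError("at least 2 timepoints required")
    if np.any(np.diff(times) <= 0):
        raise ConfigError("times must be strictly increasing")

    diameters = np.full(times.size, np.nan)
    records: list = [None] * times.size
    for i, img in enumerate(images):
        try:
            mask = segment_spheroid(img, pixel_size=pixel_size, params=params)
            morpho = compute_morphometrics(mask)
        except SegmentationError:
            continue
        records[i] = morpho
        diameters[i] = morpho.equivalent_diameter
    if np.all(np.isnan(diameters)):
        raise SegmentationError("no measurable series")
    return GrowthCurve(times=times, diameters=diameters, records=records)
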