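"""Nucleus segmentation and per-nucleus shape measurement.

The chain mirrors the classical ImageJ-style workflow: an FFT band-pass
filter suppresses background illumination (structures larger than
``band_high`` px) and pixel noise (smaller than ``band_low`` px), the result
is thresholded to a binary mask (Otsu by default, nuclei assumed darker than
background), 8-connected components are labelled and measured, and nuclei
are gated to an area range of 50-500 px^2 and circularity > 0.3.

Shape descriptors follow the standard particle-analysis definitions:

* circularity  = 4*pi*area / perimeter^2  (capped at 1.0)
* aspect ratio = major / minor axis of the moment-matched ellipse
* roundness    = 4*area / (pi * major^2)
* solidity     = area / convex area
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _label_components
from skimage.measure import regionprops

AUTO = "auto"

DEFAULT_AREA_MIN = 50.0
DEFAULT_AREA_MAX = 500.0
DEFAULT_CIRCULARITY_MIN = 0.3
DEFAULT_BAND_LOW = 3.0
DEFAULT_BAND_HIGH = 40.0

#: components smaller than this many pixels are not measurable (degenerate
#: moments) and are dropped by the chain before measurement
MIN_MEASURABLE_AREA = 5


class DegenerateInputError(ValueError):
    """Input image carries no structure to threshold."""


class InvalidMeasurementError(ValueError):
    """Region too degenerate for shape measurement."""


@dataclass(frozen=True)
class NucleusMeasurement:
    """Geometry and shape descriptors of one segmented nucleus.

    ``centroid`` is (x, y) in 0-based pixel coordinates (x = column).
    ``major_axis``/``minor_axis`` are full lengths of the ellipse with
    matching second-order central moments.
    """

    area: float
    perimeter: float
    centroid: tuple[float, float]
    major_axis: float
    minor_axis: float
    convex_area: float
    circularity: float
    aspect_ratio: float
    roundness: float
    solidity: float


@dataclass
class SampleNucleusSet:
    """All retained nuclei of one sample, pooled over its images."""

    sample_id: str
    measurements: list[NucleusMeasurement]
    n_images: int
    image_shape: tuple[int, int]


def to_gray(image: np.ndarray, channel: int | None = None) -> np.ndarray:
    """Collapse a multi-channel image to one plane.

    By default Rec. 601 luminance; ``channel`` selects a single plane instead
    (the analysis operates on one slice of the colour image).
    """
    if image.ndim == 2:
        return np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("expected a 2-D or 3-D (H, W, C) image")
    if channel is not None:
        return np.asarray(image[..., channel], dtype=float)
    rgb = np.asarray(image[..., :3], dtype=float)
    return rgb @ np.array([0.299, 0.587, 0.114])


def band_pass(
    image: np.ndarray,
    band_low: float = DEFAULT_BAND_LOW,
    band_high: float = DEFAULT_BAND_HIGH,
) -> np.ndarray:
    """FFT band-pass: difference of Gaussian low-passes in the Fourier domain.

    Structures smaller than ``band_low`` px are smoothed away (sigma =
    band_low/2) and structures larger than ``band_high`` px are subtracted
    (sigma = band_high/2), leaving a zero-mean image responsive to
    nucleus-scale structure.
    """
    if image.ndim != 2:
        raise ValueError("band_pass expects a 2-D image")
    if not band_low < band_high:
        raise ValueError("band_low must be < band_high")
    img = np.asarray(image, dtype=float)
    f = np.fft.rfft2(img)
    n = img.shape[1]
    small = ndimage.fourier_gaussian(f, sigma=band_low / 2.0, n=n)
    large = ndimage.fourier_gaussian(f, sigma=band_high / 2.0, n=n)
    return np.fft.irfft2(small - large, s=img.shape)


def preprocess_to_mask(
    image: np.ndarray,
    band_low: float = DEFAULT_BAND_LOW,
    band_high: float = DEFAULT_BAND_HIGH,
    threshold: float | str = AUTO,
    dark_foreground: bool = True,
    fill_holes: bool = True,
    channel: int | None = None,
) -> np.ndarray:
    """Band-pass then threshold an image into a binary nucleus mask.

    ``threshold=AUTO`` applies Otsu's method to the band-passed image; a float
    overrides it.  With ``dark_foreground`` (the default) pixels *below* the
    threshold are foreground.  A uniform input under AUTO raises
    :class:`DegenerateInputError`.
    """
    img = to_gray(image, channel=channel)
    bp = band_pass(img, band_low, band_high)
    if threshold == AUTO:
        if np.ptp(img) == 0 or np.ptp(bp) < 1e-9:
            raise DegenerateInputError("uniform image: no threshold exists")
        thr = float(threshold_otsu(bp))
    else:
        thr = float(threshold)
    mask = bp < thr if dark_foreground else bp > thr
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


def segment(mask: np.ndarray, connectivity: int = 2) -> list:
    """Label the mask into per-nucleus regions (8-connected by default).

    Returns scikit-image region objects, one per foreground component.
    """
    labeled = _label_components(np.asarray(mask, dtype=bool), connectivity=connectivity)
    return regionprops(labeled)


def shape_descriptors(
    area: float,
    perimeter: float,
    major_axis: float,
    minor_axis: float,
    convex_area: float,
) -> tuple[float, float, float, float]:
    """(circularity, aspect_ratio, roundness, solidity) from raw geometry.

    Circularity is capped at 1.0: discretized boundaries can push
    4*pi*A/P^2 slightly above the continuum bound.
    """
    if perimeter <= 0 or major_axis <= 0:
        raise InvalidMeasurementError("zero perimeter or major axis")
    if minor_axis <= 0 or area <= 0 or convex_area <= 0:
        raise InvalidMeasurementError("non-positive measurement")
    if major_axis < minor_axis:
        raise ValueError("major_axis must be >= minor_axis")
    circularity = min(1.0, 4.0 * np.pi * area / perimeter**2)
    aspect_ratio = major_axis / minor_axis
    roundness = 4.0 * area / (np.pi * major_axis**2)
    solidity = area / convex_area
    return circularity, aspect_ratio, roundness, solidity


def measure_region(region) -> NucleusMeasurement:
    """Measure one labelled region into a :class:`NucleusMeasurement`.

    Area is the pixel count, perimeter comes from boundary tracing, axes from
    the moment-matched ellipse, convex area from the convex hull.  Degenerate
    regions (e.g. single pixels) raise :class:`InvalidMeasurementError`.
    """
    area = float(region.area)
    perimeter = float(region.perimeter)
    major = float(region.axis_major_length)
    minor = float(region.axis_minor_length)
    convex = float(region.area_convex)
    cy, cx = region.centroid
    circ, ar, ro, so = shape_descriptors(area, perimeter, major, minor, convex)
    return NucleusMeasurement(
        area=area,
        perimeter=perimeter,
        centroid=(float(cx), float(cy)),
        major_axis=major,
        minor_axis=minor,
        convex_area=convex,
        circularity=circ,
        aspect_ratio=ar,
        roundness=ro,
        solidity=so,
    )


def filter_nuclei(
    measurements: list[NucleusMeasurement],
    area_min: float = DEFAULT_AREA_MIN,
    area_max: float = DEFAULT_AREA_MAX,
    circularity_min: float = DEFAULT_CIRCULARITY_MIN,
) -> list[NucleusMeasurement]:
    """Retain nuclei with area_min <= area <= area_max (inclusive bounds) and
    circularity strictly greater than ``circularity_min``; order preserved."""
    if area_min > area_max:
        raise ValueError("area bounds out of order")
    return [
        m
        for m in measurements
        if area_min <= m.area <= area_max and m.circularity > circularity_min
    ]


def extract_nuclei(
    image: np.ndarray,
    band_low: float = DEFAULT_BAND_LOW,
    band_high: float = DEFAULT_BAND_HIGH,
    threshold: float | str = AUTO,
    apply_filter: bool = True,
    area_min: float = DEFAULT_AREA_MIN,
    area_max: float = DEFAULT_AREA_MAX,
    circularity_min: float = DEFAULT_CIRCULARITY_MIN,
    channel: int | None = None,
) -> list[NucleusMeasurement]:
    """Full per-image chain: mask -> label -> measure -> (optionally) filter.

    Components below :data:`MIN_MEASURABLE_AREA` pixels (unmeasurable noise
    specks, far below the area gate) are skipped.
    """
    mask = preprocess_to_mask(image, band_low, band_high, threshold, channel=channel)
    regions = segment(mask)
    measurements = [
        measure_region(r) for r in regions if r.area >= MIN_MEASURABLE_AREA
    ]
    if apply_filter:
        measurements = filter_nuclei(measurements, area_min, area_max, circularity_min)
    return measurements


def measure_sample(
    images: list[np.ndarray], sample_id: str, **kwargs
) -> SampleNucleusSet:
    """Pool retained nuclei over all of one sample's images."""
    if not images:
        raise ValueError("at least one image required")
    shape = to_gray(images[0]).shape
    pooled: list[NucleusMeasurement] = []
    for img in images:
        pooled.extend(extract_nuclei(img, **kwargs))
    return SampleNucleusSet(sample_id, pooled, n_images=len(images), image_shape=shape)


def measurements_to_frame(
    nucleus_set: SampleNucleusSet, image_id: str | None = None
) -> pd.DataFrame:
    """One row per retained nucleus, ready for the per-nucleus CSV."""
    rows = []
    for m in nucleus_set.measurements:
        row = {"sample_id": nucleus_set.sample_id, "image_id": image_id}
        for f in fields(NucleusMeasurement):
            v = getattr(m, f.name)
            if f.name == "centroid":
                row["centroid_x"], row["centroid_y"] = v
            else:
                row[f.name] = v
        rows.append(row)
    cols = ["sample_id", "image_id", "area", "perimeter", "centroid_x", "centroid_y",
            "major_axis", "minor_axis", "convex_area", "circularity",
            "aspect_ratio", "roundness", "solidity"]
    return pd.DataFrame(rows, columns=cols)


def frame_to_measurements(frame: pd.DataFrame) -> list[NucleusMeasurement]:
    """Inverse of :func:`measurements_to_frame` for one sample's rows."""
    out = []
    for _, r in frame.iterrows():
        out.append(
            NucleusMeasurement(
                area=float(r["area"]),
                perimeter=float(r["perimeter"]),
                centroid=(float(r["centroid_x"]), float(r["centroid_y"])),
                major_axis=float(r["major_axis"]),
                minor_axis=float(r["minor_axis"]),
                convex_area=float(r["convex_area"]),
                circularity=float(r["circularity"]),
                aspect_ratio=float(r["aspect_ratio"]),
                roundness=float(r["roundness"]),
                solidity=float(r["solidity"]),
            )
        )
    return out
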