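"""2D segmentation primitives shared by the three angle estimators.

Otsu thresholding, binary morphology, bounding boxes, brain-contour
extraction with flood fill, a classical erosion/largest-component skull
strip, centroids, and the three-property ellipse gate that decides which
axial slices are usable for yaw and roll estimation.

Conventions fixed here (the literature leaves them open):

* connectivity for components and flood fill is 8-neighbour in-plane;
* Otsu ties are broken toward the smaller threshold;
* the ellipse gate's ``+-200 units`` area tolerance is 200 pixel-area units
  (mm^2 when spacing is known, px^2 otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, EmptyForegroundError
from .volio import SliceView

#: 8-connected structuring element used for labelling and flood fill
_CONN8 = np.ones((3, 3), dtype=bool)

#: ellipse gate constants
ELLIPSE_RATIO_GATE = 1.2
ELLIPSE_AREA_GATE = 200.0  # in pixel-area units
MIN_CONTOUR_PIXELS = 16


@dataclass
class BinaryMask:
    """A 2D {0,1} mask with provenance back to the slice it came from."""

    pixels: np.ndarray
    provenance: Optional[SliceView] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.provenance is not None and self.pixels.shape != self.provenance.pixels.shape:
            raise ValueError("mask shape differs from its source slice")

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


MaskLike = Union[BinaryMask, np.ndarray]


def _pixels(mask: MaskLike) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    return np.asarray(mask).astype(bool)


def _provenance(mask: MaskLike) -> Optional[SliceView]:
    return mask.provenance if isinstance(mask, BinaryMask) else None


@dataclass
class EllipseMetrics:
    """Moment-derived semi-axes of a solid contour and the three gate flags.

    Semi-axes come from the second central moments of the filled region with
    the ellipse-equivalence scaling (semi-axis = 2 sqrt(eigenvalue)), the same
    eigendecomposition the yaw estimator uses.  A slice is accepted when all
    three flags hold: axis ratio > 1.2, unequal axes, and theoretical ellipse
    area pi*a*b within 200 pixel-area units of the pixel-counted area.
    """

    semi_major_px: float
    semi_minor_px: float
    theoretical_area: float
    actual_area: float
    pixel_area: float
    passes_ratio: bool
    passes_inequality: bool
    passes_area: bool

    @property
    def ratio(self) -> float:
        return self.semi_major_px / self.semi_minor_px

    @property
    def accepted(self) -> bool:
        return self.passes_ratio and self.passes_inequality and self.passes_area


def otsu_threshold(slice_view: SliceView | np.ndarray) -> tuple[float, BinaryMask]:
    """Otsu's threshold of one slice; the mask is ``intensity > threshold``.

    The threshold maximises between-class variance over a 256-bin histogram
    of the slice, with ties broken toward the smaller threshold.  Integer
    slices with range <= 256 get one bin per grey level, so the result agrees
    exactly with an exhaustive search over integer thresholds.

    Raises
    ------
    DegenerateInputError
        For a constant slice (no threshold separates two classes).
    """
    view = slice_view if isinstance(slice_view, SliceView) else None
    px = np.asarray(slice_view.pixels if view is not None else slice_view, dtype=float)
    lo, hi = float(px.min()), float(px.max())
    if not hi > lo:
        raise DegenerateInputError("constant slice: Otsu threshold undefined")
    counts, edges = np.histogram(px, bins=256, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts).astype(float)
    total = w0[-1]
    m0 = np.cumsum(counts * centers)
    mu_t = m0[-1] / total
    # between-class variance for a split after bin k (k = 0..254)
    w0 = w0[:-1]
    m0 = m0[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.full(255, -np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (mu_t * w0 - m0) ** 2
        sigma_b[valid] = num[valid] / (w0[valid] * w1[valid])
    k = int(np.argmax(sigma_b))  # first maximum = smaller threshold
    # place the threshold between the two classes' nearest sample values so
    # that ``px > threshold`` reproduces the argmax split exactly
    bins = np.clip(((px - lo) / (hi - lo) * 256).astype(int), 0, 255)
    low_class = px[bins <= k]
    high_class = px[bins > k]
    threshold = float(low_class.max() + high_class.min()) / 2.0
    mask = BinaryMask(px > threshold, provenance=view)
    if mask.count == 0:
        raise EmptyForegroundError("Otsu produced an empty foreground")
    return threshold, mask


def morphological_opening(mask: MaskLike, se_size: int = 3) -> BinaryMask:
    """Binary opening (erosion then dilation) with a flat square element."""
    if se_size < 1:
        raise ValueError(f"structuring element size must be >= 1, got {se_size}")
    px = _pixels(mask)
    se = np.ones((se_size, se_size), dtype=bool)
    opened = ndimage.binary_opening(px, structure=se)
    return BinaryMask(opened, provenance=_provenance(mask))


def bounding_box(mask: MaskLike) -> tuple[int, int, int, int]:
    """Tight inclusive (row_min, row_max, col_min, col_max) over nonzero pixels."""
    px = _pixels(mask)
    rows = np.flatnonzero(px.any(axis=1))
    cols = np.flatnonzero(px.any(axis=0))
    if rows.size == 0:
        raise EmptyForegroundError("bounding box of an empty mask")
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def _largest_component(px: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(px, structure=_CONN8)
    if n == 0:
        raise EmptyForegroundError("no connected components")
    sizes = ndimage.sum_labels(np.ones_like(px, dtype=np.int64), labels, range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def extract_brain_contour(opened: MaskLike) -> BinaryMask:
    """Solid brain region from a morphologically opened mask.

    Draws the rectangular bounding-box frame, removes foreground pixels that
    coincide with the frame (breaking skull-to-frame bridges), keeps the
    largest 8-connected component, and flood-fills its holes so every
    interior pixel is 1.
    """
    px = _pixels(opened)
    r0, r1, c0, c1 = bounding_box(px)
    frame = np.zeros_like(px)
    frame[r0, c0:c1 + 1] = True
    frame[r1, c0:c1 + 1] = True
    frame[r0:r1 + 1, c0] = True
    frame[r0:r1 + 1, c1] = True
    work = px & ~frame
    if not work.any():
        raise EmptyForegroundError("nothing left after removing the bounding-box frame")
    blob = _largest_component(work)
    # a tight box always touches the region at its tangent pixels; restore
    # removed frame pixels that belong to (are adjacent to) the kept blob
    recapture = px & frame & ndimage.binary_dilation(blob, structure=_CONN8)
    solid = ndimage.binary_fill_holes(blob | recapture, structure=_CONN8)
    return BinaryMask(solid, provenance=_provenance(opened))


def skull_strip(slice_view: SliceView, se_size: int = 3) -> BinaryMask:
    """Inner (brain) compartment of an axial slice.

    Classical recipe: Otsu threshold, erosion with a flat square element to
    cut thin bridges between brain and scalp, keep the largest component,
    dilate by the same element, fill holes.
    """
    try:
        _, mask = otsu_threshold(slice_view)
    except DegenerateInputError as exc:
        raise EmptyForegroundError(f"skull strip: {exc}") from exc
    se = np.ones((se_size, se_size), dtype=bool)
    eroded = ndimage.binary_erosion(mask.pixels, structure=se)
    if not eroded.any():
        raise EmptyForegroundError("skull strip: erosion removed all foreground")
    blob = _largest_component(eroded)
    dilated = ndimage.binary_dilation(blob, structure=se)
    solid = ndimage.binary_fill_holes(dilated, structure=_CONN8)
    return BinaryMask(solid, provenance=slice_view)


def centroid(mask: MaskLike) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the nonzero pixels."""
    px = _pixels(mask)
    rows, cols = np.nonzero(px)
    if rows.size == 0:
        raise EmptyForegroundError("centroid of an empty mask")
    return float(rows.mean()), float(cols.mean())


def region_moments(mask: MaskLike, scale: tuple[float, float] = (1.0, 1.0)
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and eigendecomposition of the second central moments of a region.

    Returns (mean(2,), eigenvalues descending(2,), eigenvectors as columns).
    ``scale`` converts (row, col) pixels to physical units before the moments
    are taken (anisotropic in-plane spacing would otherwise bias the axes).
    """
    px = _pixels(mask)
    rows, cols = np.nonzero(px)
    if rows.size < 2:
        raise DegenerateInputError("second moments need at least 2 pixels")
    coords = np.stack([rows * scale[0], cols * scale[1]], axis=0).astype(float)
    mean = coords.mean(axis=1)
    centered = coords - mean[:, None]
    cov = (centered @ centered.T) / coords.shape[1]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    return mean, evals[order], evecs[:, order]


def ellipse_metrics(contour: MaskLike, pixel_area: float = 1.0) -> EllipseMetrics:
    """Ellipse gate metrics of a solid (flood-filled) contour.

    Semi-axes a, b are 2*sqrt(eigenvalue) of the region's second central
    moments, in pixels; the theoretical area pi*a*b and the pixel-counted
    actual area are compared in pixel-area units with the +-200 gate.
    """
    px = _pixels(contour)
    n = int(px.sum())
    if n < MIN_CONTOUR_PIXELS:
        raise DegenerateInputError(
            f"contour has {n} pixels; at least {MIN_CONTOUR_PIXELS} required")
    _, evals, _ = region_moments(px)
    if evals[1] <= 0:
        raise DegenerateInputError("collinear region: ellipse axes undefined")
    a = 2.0 * float(np.sqrt(evals[0]))
    b = 2.0 * float(np.sqrt(evals[1]))
    theoretical = np.pi * a * b * pixel_area
    actual = n * pixel_area
    return EllipseMetrics(
        semi_major_px=a,
        semi_minor_px=b,
        theoretical_area=theoretical,
        actual_area=actual,
        pixel_area=pixel_area,
        passes_ratio=(a / b) > ELLIPSE_RATIO_GATE,
        passes_inequality=a != b,
        passes_area=abs(theoretical - actual) <= ELLIPSE_AREA_GATE * pixel_area,
    )
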