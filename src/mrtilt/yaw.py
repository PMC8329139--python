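"""Yaw estimation from automatically selected elliptical axial slices.

For every axial slice the pipeline runs skull strip -> morphological
opening -> brain-contour extraction -> ellipse gate; slices passing all
three gate properties contribute a per-slice yaw, estimated in two steps:

* **coarse**: the angle between the dominant eigenvector of the contour's
  second central moments and the anterior axis;
* **fine**: a bilateral-symmetry search — the coarse-corrected intensity
  slice is rotated by each candidate offset in {-5, -4.5, ..., +5} degrees,
  reflected about the vertical (anterior-posterior) midline, and scored by
  the Pearson correlation between image and reflection over the union of
  their foregrounds; the offset with maximal correlation wins.

The volume's yaw is the plain arithmetic mean of the per-slice totals
(coarse + fine), so per-slice head motion is averaged rather than filtered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import segment
from .errors import (DegenerateInputError, DegenerateOrientationError,
                     NoEllipticalSliceError)
from .volio import SliceView, Volume, extract_slice

__all__ = ["SliceYaw", "FINE_DELTAS_DEG", "select_elliptical_slices",
           "pca_coarse_angle", "correlation_fine_angle",
           "fine_correlation_profile", "estimate_yaw", "rotate_image"]

#: the 21-candidate fine-search grid: -5 to +5 degrees in 0.5 degree steps
FINE_DELTAS_DEG = np.round(np.arange(-5.0, 5.0 + 0.25, 0.5), 1)

#: relative eigenvalue gap below which the orientation is undefined
_ORIENTATION_GAP = 1e-3


@dataclass
class SliceYaw:
    """Per-slice yaw audit record."""

    slice_index: int
    coarse_deg: float
    fine_deg: float
    total_deg: float
    corr_peak: float
    metrics: segment.EllipseMetrics
    #: True when the fine search saturated at the +-5 degree window edge
    saturated: bool = False


def rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate image content by ``angle_deg`` about the image centre.

    The angle follows the in-plane yaw convention: a direction along +rows
    (anterior) at angle 0 moves toward -columns for positive angles.
    Bilinear interpolation, constant-0 fill.
    """
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    # inverse content rotation G(-angle) acting on (row, col)
    m = np.array([[c, -s], [s, c]])
    center = (np.asarray(img.shape, dtype=float) - 1.0) / 2.0
    offset = center - m @ center
    return ndimage.affine_transform(img, m, offset=offset, order=1, cval=0.0,
                                    prefilter=False)


def pca_coarse_angle(contour: segment.MaskLike) -> float:
    """Orientation of the contour's major axis relative to the anterior axis.

    Eigendecomposition of the 2x2 covariance of foreground coordinates
    (scaled to mm when the mask carries slice provenance); returns the angle
    of the dominant eigenvector in (-90, 90], positive when the long axis is
    rotated counter-clockwise viewed from superior.
    """
    prov = segment._provenance(contour)
    scale = prov.pixel_spacing if prov is not None else (1.0, 1.0)
    _, evals, evecs = segment.region_moments(contour, scale=scale)
    if evals[0] <= 0 or (evals[0] - evals[1]) / evals[0] < _ORIENTATION_GAP:
        raise DegenerateOrientationError(
            "isotropic second moments: major axis undefined")
    v = evecs[:, 0]
    if v[0] < 0 or (v[0] == 0 and v[1] > 0):
        v = -v  # canonical: anterior component non-negative
    ang = math.degrees(math.atan2(-v[1], v[0]))
    if ang <= -90.0:
        ang += 180.0
    return ang


def _recenter(img: np.ndarray, threshold: float) -> np.ndarray:
    """Shift the image so the foreground centroid sits at the image centre."""
    fg = img > threshold
    if not fg.any():
        raise DegenerateInputError("no foreground above threshold")
    r, c = segment.centroid(fg)
    center = (np.asarray(img.shape, dtype=float) - 1.0) / 2.0
    shift = (center[0] - r, center[1] - c)
    if max(abs(shift[0]), abs(shift[1])) < 1e-12:
        return img
    return ndimage.shift(img, shift, order=1, cval=0.0, prefilter=False)


def fine_correlation_profile(slice_view: SliceView, coarse_deg: float
                             ) -> list[tuple[float, float]]:
    """(delta, Pearson r) for every candidate of the 0.5-degree fine grid.

    Each candidate rotation undoes coarse+delta, reflects the slice about
    its vertical midline and correlates image against reflection over the
    union of the two foregrounds.
    """
    px = np.asarray(slice_view.pixels, dtype=float)
    # light anti-alias blur: candidate rotations smooth the image by
    # different amounts (an exact 0-degree resample smooths not at all),
    # which would bias the correlation toward larger offsets; after this
    # the smoothing differences between candidates are negligible
    px = ndimage.gaussian_filter(px, 0.7)
    try:
        threshold, _ = segment.otsu_threshold(px)
    except DegenerateInputError as exc:
        raise DegenerateInputError(f"fine search: {exc}") from exc
    centered = _recenter(px, threshold)
    profile: list[tuple[float, float]] = []
    for delta in FINE_DELTAS_DEG:
        rot = rotate_image(centered, -(coarse_deg + float(delta)))
        ref = rot[:, ::-1]
        m = (rot > threshold) | (ref > threshold)
        if m.sum() < 2:
            profile.append((float(delta), -np.inf))
            continue
        a, b = rot[m], ref[m]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            profile.append((float(delta), -np.inf))
            continue
        r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        profile.append((float(delta), r))
    if all(not np.isfinite(r) for _, r in profile):
        raise DegenerateInputError("correlation undefined for every fine candidate")
    return profile


def correlation_fine_angle(slice_view: SliceView, coarse_deg: float
                           ) -> tuple[float, float]:
    """Fine yaw offset in [-5, 5] maximising bilateral symmetry, and its r.

    Exact ties are broken toward the offset of smallest magnitude (negative
    first).
    """
    profile = fine_correlation_profile(slice_view, coarse_deg)
    best = max(profile, key=lambda dr: (dr[1], -abs(dr[0]), dr[0]))
    return best[0], best[1]


def select_elliptical_slices(volume: Volume
                             ) -> list[tuple[int, segment.BinaryMask, segment.EllipseMetrics]]:
    """All axial slices whose brain contour passes the three-property gate.

    Slices where any segmentation stage fails (empty foreground, degenerate
    input) are simply rejected.  Raises NoEllipticalSliceError when nothing
    survives — the failure mode of very thick slices, where the contours no
    longer look elliptical.
    """
    accepted = []
    for k in range(volume.shape[2]):
        view = extract_slice(volume, "axial", k)
        try:
            stripped = segment.skull_strip(view)
            opened = segment.morphological_opening(stripped)
            contour = segment.extract_brain_contour(opened)
            metrics = segment.ellipse_metrics(contour, pixel_area=view.pixel_area)
        except (DegenerateInputError, segment.EmptyForegroundError):
            continue
        if metrics.accepted:
            accepted.append((k, contour, metrics))
    if not accepted:
        raise NoEllipticalSliceError(
            "no axial slice passed the ellipse gate; yaw cannot be estimated")
    return accepted


def estimate_yaw(volume: Volume, selection=None) -> tuple[float, list[SliceYaw]]:
    """Volume yaw: mean of per-slice (coarse PCA + fine correlation) angles.

    ``selection`` lets callers reuse a precomputed
    :func:`select_elliptical_slices` result.
    """
    if selection is None:
        selection = select_elliptical_slices(volume)
    per_slice: list[SliceYaw] = []
    for k, contour, metrics in selection:
        try:
            coarse = pca_coarse_angle(contour)
            view = extract_slice(volume, "axial", k)
            fine, peak = correlation_fine_angle(view, coarse)
        except (DegenerateOrientationError, DegenerateInputError):
            continue
        per_slice.append(SliceYaw(
            slice_index=k, coarse_deg=coarse, fine_deg=fine,
            total_deg=coarse + fine, corr_peak=peak, metrics=metrics,
            saturated=abs(fine) >= FINE_DELTAS_DEG[-1]))
    if not per_slice:
        raise NoEllipticalSliceError("every gated slice failed yaw estimation")
    theta = float(np.mean([s.total_deg for s in per_slice]))
    return theta, per_slice
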