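"""Pitch estimation from the mid-sagittal slice.

When the head is aligned, the line joining the Nasion (the depression
between the eyes) to the Inion (the occipital crest) is parallel to the
anterior axis; a rotation about X tilts that line by the same angle.  The
estimator thresholds the mid-sagittal slice, anchors a search band around
the head-contour centroid (half-way from the contour top to the centroid,
and half-way from the centroid to the contour bottom, which excludes the
philtrum and labial commissure), picks the anterior boundary point nearest
the centroid as the Nasion and the posterior boundary point farthest from
it as the Inion, and reads the pitch off the Nasion-Inion line.

Pitch is estimated on the single mid-sagittal slice only; no multi-slice
averaging.  Volumes without facial anatomy (no nasal notch) produce a
warning-tagged result rather than a hard failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import segment
from .errors import DegenerateInputError, LandmarkNotFoundError
from .volio import SliceView, Volume, extract_slice, mid_sagittal_index

__all__ = ["LandmarkResult", "search_row_range", "detect_nasion", "detect_inion",
           "pitch_angle", "estimate_pitch"]

Point = tuple[float, float]  # (row, col)

NO_FACE_WARNING = "nasion candidate sits on the search-range boundary; the volume may lack facial anatomy"


@dataclass
class LandmarkResult:
    """Audit trail of one pitch estimation."""

    nasion: Point
    inion: Point
    centroid: Point
    search_rows: tuple[float, float]
    pitch_deg: float
    slice_index: int = -1
    warnings: list[str] = field(default_factory=list)


def search_row_range(contour: segment.MaskLike, centroid_row: float
                     ) -> tuple[float, float]:
    """Row band [low, high] that encloses the Nasion and Inion.

    low = top + (centroid - top)/2 and high = centroid + (bottom - centroid)/2,
    where top/bottom are the first/last contour rows.  Rows below ``high``
    would reach the philtrum and labial commissure, which also lie close to
    the centroid and would make the Nasion ambiguous.
    """
    top, bottom, _, _ = segment.bounding_box(contour)
    if not (top <= centroid_row <= bottom):
        raise DegenerateInputError(
            f"centroid row {centroid_row} outside contour rows [{top}, {bottom}]")
    low = top + (centroid_row - top) / 2.0
    high = centroid_row + (bottom - centroid_row) / 2.0
    return low, high


def _boundary_candidates(contour: segment.MaskLike, rows: tuple[float, float],
                         anterior: bool) -> np.ndarray:
    """Per-row extreme boundary pixels (N,2 array of row, col) inside the band.

    Anterior boundary points are the minimum-column foreground pixels per
    row; posterior ones the maximum-column pixels.
    """
    px = segment._pixels(contour)
    low, high = rows
    out = []
    r0 = int(math.ceil(low))
    r1 = int(math.floor(high))
    for r in range(max(r0, 0), min(r1, px.shape[0] - 1) + 1):
        cols = np.flatnonzero(px[r])
        if cols.size == 0:
            continue
        out.append((r, cols[0] if anterior else cols[-1]))
    if not out:
        side = "anterior" if anterior else "posterior"
        raise LandmarkNotFoundError(f"no {side} boundary pixels in rows [{low}, {high}]")
    return np.asarray(out, dtype=float)


def _pick(cands: np.ndarray, cpoint: Point, minimise: bool) -> Point:
    d = np.hypot(cands[:, 0] - cpoint[0], cands[:, 1] - cpoint[1])
    best = d.min() if minimise else d.max()
    ties = cands[np.isclose(d, best, rtol=0.0, atol=1e-9)]
    # tie-break: the candidate whose row is nearest the centroid row
    row_dist = np.abs(ties[:, 0] - cpoint[0])
    r, c = ties[int(np.argmin(row_dist))]
    return (float(r), float(c))


def detect_nasion(contour: segment.MaskLike, cpoint: Point,
                  rows: tuple[float, float]) -> Point:
    """Anterior boundary point with minimum Euclidean distance to the centroid."""
    return _pick(_boundary_candidates(contour, rows, anterior=True), cpoint, minimise=True)


def detect_inion(contour: segment.MaskLike, cpoint: Point,
                 rows: tuple[float, float]) -> Point:
    """Posterior boundary point with maximum Euclidean distance to the centroid."""
    return _pick(_boundary_candidates(contour, rows, anterior=False), cpoint, minimise=False)


def pitch_angle(nasion: Point, inion: Point,
                pixel_spacing: tuple[float, float] = (1.0, 1.0)) -> float:
    """Angle (degrees, in (-90, 90]) of the Nasion-Inion line with horizontal.

    Computed as atan2 of the inion-to-nasion displacement in the sagittal
    frame (rows superior->inferior, columns anterior->posterior), scaled to
    mm by ``pixel_spacing`` so anisotropic voxels do not bias the angle.
    Zero iff both landmarks share a row.
    """
    if nasion == inion:
        raise DegenerateInputError("nasion and inion coincide")
    drow = (nasion[0] - inion[0]) * pixel_spacing[0]
    dcol = (nasion[1] - inion[1]) * pixel_spacing[1]
    ang = math.degrees(math.atan2(drow, dcol))
    # map line angle to (-90, 90]
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return ang


def estimate_pitch(volume: Volume) -> tuple[float, LandmarkResult]:
    """Full pitch chain on the mid-sagittal slice.

    mid-sagittal slice -> Otsu -> centroid -> search band -> Nasion/Inion ->
    angle.  If the Nasion candidate lands on the search-band boundary the
    result is tagged with a warning: that is the signature of a volume with
    no nasal notch (e.g. brain-only data without facial anatomy), where the
    reported pitch is not trustworthy.
    """
    idx = mid_sagittal_index(volume)
    view = extract_slice(volume, "sagittal", idx)
    _, mask = segment.otsu_threshold(view)
    cpoint = segment.centroid(mask)
    rows = search_row_range(mask, cpoint[0])
    nasion = detect_nasion(mask, cpoint, rows)
    inion = detect_inion(mask, cpoint, rows)
    omega = pitch_angle(nasion, inion, view.pixel_spacing)
    warnings = []
    low, high = rows
    # notch salience: the Nasion must be a *distinctly* closer anterior point
    # than the rest of the band.  On volumes without facial anatomy the
    # anterior boundary is smooth and the minimum is not salient.
    cands = _boundary_candidates(mask, rows, anterior=True)
    away = np.abs(cands[:, 0] - nasion[0]) > 3
    if min(nasion[0] - low, high - nasion[0]) <= 1.0:
        warnings.append(NO_FACE_WARNING)
    elif away.any():
        d_all = np.hypot(cands[:, 0] - cpoint[0], cands[:, 1] - cpoint[1])
        d_nasion = float(np.hypot(nasion[0] - cpoint[0], nasion[1] - cpoint[1]))
        salience = float(d_all[away].min()) - d_nasion
        if salience < 1.0:  # less than one pixel of notch depth
            warnings.append(NO_FACE_WARNING)
    result = LandmarkResult(nasion=nasion, inion=inion, centroid=cpoint,
                            search_rows=rows, pitch_deg=omega,
                            slice_index=idx, warnings=warnings)
    return omega, result
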