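"""Roll estimation via an orthogonal-regression plane through axial axis points.

Every gated axial slice contributes three points: where the slice's first
principal component meets the first and last nonzero contour rows (top and
bottom), and their midpoint (center).  All three lie on the head's
mid-sagittal plane, so fitting a total-least-squares plane through the
pooled points recovers that plane; its normal's inclination out of the
axial plane is the roll angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import segment
from .errors import (DegenerateInputError, DegenerateOrientationError,
                     InsufficientDataError)
from .volio import Volume
from .yaw import select_elliptical_slices

__all__ = ["AxisPoints", "PlaneFit", "axis_points", "orthogonal_regression",
           "roll_angle", "estimate_roll"]

Point3 = tuple[float, float, float]


@dataclass
class AxisPoints:
    """Top/center/bottom of one slice's principal axis, in voxel (x, y, z)."""

    slice_index: int
    top: Point3
    center: Point3
    bottom: Point3

    def as_array(self) -> np.ndarray:
        return np.array([self.top, self.center, self.bottom], dtype=float)


@dataclass
class PlaneFit:
    """Orthogonal-regression (total-least-squares) plane.

    ``basis`` holds three orthonormal column vectors: the two in-plane
    principal directions of the centered point cloud followed by the normal
    (the least-variance direction, oriented so its z-component is >= 0).
    ``roll_coefficient`` is the coefficient fed to the arctangent: the
    normal rescaled so its component along +X equals -1, read at Z.  That
    scaling reproduces the applied roll exactly for pure rotations about
    the anterior axis (see docs/methods.md).
    """

    basis: np.ndarray
    normal: np.ndarray
    mean_point: np.ndarray
    rms_residual: float

    @property
    def roll_coefficient(self) -> float:
        nx, _, nz = self.normal
        if nx == 0:
            return math.inf if nz > 0 else (-math.inf if nz < 0 else 0.0)
        return -nz / nx


def axis_points(contour: segment.MaskLike, slice_index: int) -> AxisPoints:
    """Intersect a contour's first principal component with its row extremes.

    The principal-axis line through the region centroid is evaluated at the
    contour's first and last nonzero rows; the center is the exact midpoint.
    Coordinates are returned as voxel (x=col, y=row, z=slice_index).
    """
    mean, evals, evecs = segment.region_moments(contour)  # pixel units
    if evals[0] <= 0 or (evals[0] - evals[1]) / evals[0] < 1e-3:
        raise DegenerateOrientationError("isotropic contour: principal axis undefined")
    v = evecs[:, 0]  # (row, col) direction of the first principal component
    r0, r1, _, _ = segment.bounding_box(contour)
    if r0 == r1:
        raise DegenerateInputError("single-row contour")
    if abs(v[0]) < 1e-9:
        raise DegenerateInputError(
            "principal axis parallel to the rows: no row intersection")
    slope = v[1] / v[0]  # dcol/drow

    def at_row(r: float) -> Point3:
        c = mean[1] + (r - mean[0]) * slope
        return (float(c), float(r), float(slice_index))  # (x, y, z)

    top = at_row(r0)
    bottom = at_row(r1)
    center = tuple((np.asarray(top) + np.asarray(bottom)) / 2.0)
    return AxisPoints(slice_index=slice_index, top=top, center=center, bottom=bottom)


def orthogonal_regression(points: Sequence[Point3] | np.ndarray) -> PlaneFit:
    """Total-least-squares plane through >= 3 non-collinear 3D points.

    The basis directions are the principal axes of the centered point cloud
    (SVD); the normal is the least-variance direction, oriented with a
    non-negative z-component.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise InsufficientDataError(
            f"plane fit needs >= 3 points of dimension 3, got shape {pts.shape}")
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= max(1e-12, 1e-9 * svals[0]):
        raise InsufficientDataError("points are collinear: plane undefined")
    basis = vt.T  # columns: descending-variance directions, last = normal
    normal = basis[:, 2]
    if normal[2] < 0 or (normal[2] == 0 and normal[0] > 0):
        normal = -normal
        basis = basis.copy()
        basis[:, 2] = normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(basis=basis, normal=normal, mean_point=mean, rms_residual=rms)


def roll_angle(fit: PlaneFit) -> float:
    """Roll in degrees: arctangent of the plane fit's roll coefficient."""
    return math.degrees(math.atan(fit.roll_coefficient))


def estimate_roll(volume: Volume, selection=None
                  ) -> tuple[float, PlaneFit, list[AxisPoints]]:
    """Full roll chain: gate slices, collect axis points, fit, Eq.-style angle.

    Points are scaled from voxel to mm with the volume spacing before the
    regression so anisotropic voxels do not bias the plane.  Requires at
    least 3 gated slices (9 points).
    """
    if selection is None:
        selection = select_elliptical_slices(volume)
    apts: list[AxisPoints] = []
    for k, contour, _ in selection:
        try:
            apts.append(axis_points(contour, k))
        except (DegenerateInputError, DegenerateOrientationError):
            continue
    if len(apts) < 3:
        raise InsufficientDataError(
            f"roll needs >= 3 gated slices, got {len(apts)}")
    pts = np.concatenate([a.as_array() for a in apts], axis=0)
    pts_mm = pts * np.asarray(volume.spacing, dtype=float)
    fit = orthogonal_regression(pts_mm)
    return roll_angle(fit), fit, apts
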