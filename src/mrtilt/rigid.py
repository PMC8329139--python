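"""The rigid rotation model and trilinear tilt correction.

The rotation matrix is the Z-Y-X composition R = Rz(yaw) Ry(roll) Rx(pitch)
about the volume centre.  Correction applies the *inverse* of the measured
tilt with inverse-mapped trilinear resampling; with ``reshape`` the output
grid grows to the rotated bounding box so no head voxels are clipped.

All three angles are always estimated on the original volume, never
sequentially on partially corrected volumes, so the estimation order does
not matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .errors import (CorrectionImpossibleError, InsufficientDataError,
                     InvalidTransformError, LandmarkNotFoundError,
                     NoEllipticalSliceError, EmptyForegroundError,
                     DegenerateInputError)
from .volio import TiltAngles, Volume

__all__ = ["RotationMatrix", "rotation_matrix", "apply_rotation",
           "estimate_tilt", "correct_tilt"]

_ORTHO_TOL = 1e-8


@dataclass
class RotationMatrix:
    """A proper rotation and, when built from angles, the angles it encodes."""

    m: np.ndarray
    angles: Optional[TiltAngles] = None

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (3, 3):
            raise InvalidTransformError(f"expected 3x3 matrix, got {self.m.shape}")
        if not np.allclose(self.m.T @ self.m, np.eye(3), atol=_ORTHO_TOL):
            raise InvalidTransformError("matrix is not orthonormal")
        if not math.isclose(float(np.linalg.det(self.m)), 1.0, abs_tol=_ORTHO_TOL):
            raise InvalidTransformError("matrix is not a proper rotation (det != +1)")

    def inverse(self) -> "RotationMatrix":
        return RotationMatrix(m=self.m.T)


def _elemental(axis: int, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    if axis == 0:  # X
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if axis == 1:  # Y
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])  # Z


def rotation_matrix(angles: TiltAngles) -> RotationMatrix:
    """R = Rz(yaw) Ry(roll) Rx(pitch); identity for zero angles.

    The composed matrix reproduces the classical printed form of the
    yaw-roll-pitch matrix element for element; its (2,2) entry is
    cos(pitch) cos(yaw) + sin(yaw) sin(roll) sin(pitch), the only reading
    consistent with orthonormality.
    """
    m = (_elemental(2, angles.yaw_deg)
         @ _elemental(1, angles.roll_deg)
         @ _elemental(0, angles.pitch_deg))
    if angles.pitch_deg == angles.yaw_deg == angles.roll_deg == 0.0:
        m = np.eye(3)  # exactly
    return RotationMatrix(m=m, angles=angles)


def apply_rotation(volume: Volume, rot: Union[RotationMatrix, np.ndarray],
                   reshape: bool = True) -> Volume:
    """Rotate a volume about its grid centre with trilinear resampling.

    Inverse-mapped: every output voxel samples the input at the inversely
    rotated position (constant-0 fill).  With ``reshape`` the output extent
    is the ceiling of the rotated input bounding box, padded symmetrically,
    so rotated heads are not clipped; spacing is preserved.
    """
    if not isinstance(rot, RotationMatrix):
        rot = RotationMatrix(m=np.asarray(rot, dtype=float))
    M = rot.m
    spacing = np.asarray(volume.spacing, dtype=float)
    shape_in = np.asarray(volume.shape, dtype=float)
    extent_in = (shape_in - 1.0) * spacing
    if reshape:
        half = extent_in / 2.0
        corners = np.array([[sx, sy, sz]
                            for sx in (-half[0], half[0])
                            for sy in (-half[1], half[1])
                            for sz in (-half[2], half[2])])
        rotated = corners @ M.T
        extent_out = rotated.max(axis=0) - rotated.min(axis=0)
        shape_out = np.ceil(extent_out / spacing).astype(int) + 1
        shape_out = np.maximum(shape_out, volume.shape)
    else:
        shape_out = np.asarray(volume.shape, dtype=int)
    c_in = (shape_in - 1.0) / 2.0
    c_out = (shape_out - 1.0) / 2.0
    # voxel-space inverse map: in = S^-1 M^T S (out - c_out) + c_in
    A = np.diag(1.0 / spacing) @ M.T @ np.diag(spacing)
    offset = c_in - A @ c_out
    data = ndimage.affine_transform(
        volume.data.astype(float), A, offset=offset,
        output_shape=tuple(int(n) for n in shape_out), order=1, cval=0.0,
        prefilter=False)
    return Volume(data=data.astype(volume.data.dtype, copy=False)
                  if np.issubdtype(volume.data.dtype, np.floating) else data,
                  spacing=volume.spacing)


def estimate_tilt(volume: Volume) -> tuple[TiltAngles, dict]:
    """Run all three estimators on the original volume.

    Returns the measured angles (failed estimators contribute 0) plus a
    report dict with per-axis status and audit objects.  Raises
    CorrectionImpossibleError when all three estimators fail.
    """
    from .pitch import estimate_pitch
    from .roll import estimate_roll
    from .yaw import estimate_yaw, select_elliptical_slices

    report: dict = {"pitch": None, "yaw": None, "roll": None,
                    "pitch_estimated": False, "yaw_estimated": False,
                    "roll_estimated": False, "warnings": []}
    try:
        selection = select_elliptical_slices(volume)
    except NoEllipticalSliceError as exc:
        selection = None
        report["warnings"].append(str(exc))

    omega = theta = phi = 0.0
    per_slice = None
    if selection is not None:
        try:
            theta, per_slice = estimate_yaw(volume, selection=selection)
            report["yaw"] = theta
            report["yaw_estimated"] = True
            report["yaw_slices"] = per_slice
        except (NoEllipticalSliceError, DegenerateInputError) as exc:
            report["warnings"].append(f"yaw: {exc}")
        try:
            phi, fit, apts = estimate_roll(volume, selection=selection)
            report["roll"] = phi
            report["roll_estimated"] = True
            report["roll_fit"] = fit
        except (InsufficientDataError, DegenerateInputError) as exc:
            report["warnings"].append(f"roll: {exc}")
    try:
        omega, landmarks = estimate_pitch(volume)
        if landmarks.warnings:
            report["warnings"].extend(landmarks.warnings)
            omega = 0.0  # facial anatomy not found: pitch not trustworthy
        else:
            report["pitch"] = omega
            report["pitch_estimated"] = True
        report["pitch_landmarks"] = landmarks
    except (LandmarkNotFoundError, EmptyForegroundError,
            DegenerateInputError) as exc:
        omega = 0.0
        report["warnings"].append(f"pitch: {exc}")

    if not (report["pitch_estimated"] or report["yaw_estimated"]
            or report["roll_estimated"]):
        raise CorrectionImpossibleError(
            "all three angle estimators failed: " + "; ".join(report["warnings"]))
    angles = TiltAngles(pitch_deg=omega, yaw_deg=theta, roll_deg=phi,
                        per_slice_yaw=[s.total_deg for s in per_slice]
                        if per_slice else None)
    return angles, report


def correct_tilt(volume: Volume,
                 angles: Union[TiltAngles, str] = "auto",
                 reshape: bool = True) -> tuple[Volume, TiltAngles]:
    """Undo a measured (or supplied) tilt by the inverse rotation.

    With ``angles="auto"`` the three estimators run on the original volume;
    a pitch estimate tagged as unreliable (no facial anatomy) is skipped and
    reported as 0.  The corrected volume and the angles that were removed
    are returned.
    """
    if isinstance(angles, str):
        if angles != "auto":
            raise ValueError(f"angles must be TiltAngles or 'auto', got {angles!r}")
        angles, _ = estimate_tilt(volume)
    rot = rotation_matrix(angles)
    corrected = apply_rotation(volume, rot.inverse(), reshape=reshape)
    return corrected, angles
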