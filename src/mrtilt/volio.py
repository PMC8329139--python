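"""Volume I/O, the anatomical frame, and slice extraction.

All of mrtilt works in one fixed anatomical frame (RAS):

* grid axis 0 -> X, pointing to the subject's **right**
* grid axis 1 -> Y, pointing **anterior**
* grid axis 2 -> Z, pointing **superior**

Angles are defined in this frame: pitch (omega) rotates about X, roll (phi)
about Y, yaw (theta) about Z; a positive angle is counter-clockwise when
looking from the positive axis end toward the origin.

Files are reoriented into this frame at load time using the NIfTI affine, so
the estimators never have to carry orientation metadata around.

Slice layouts returned by :func:`extract_slice` follow radiological display
conventions and are what the estimators assume:

* ``sagittal`` (perpendicular to X): rows run superior -> inferior, columns
  run anterior -> posterior.
* ``coronal`` (perpendicular to Y): rows run superior -> inferior, columns
  run left -> right.
* ``axial`` (perpendicular to Z): rows follow the anterior (Y) grid index,
  columns follow the right (X) grid index.

:func:`slice_to_voxel` inverts the mapping so landmark pixels can be lifted
back into 3D voxel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

from .errors import DegenerateInputError, VolumeIOError

PLANES = ("sagittal", "coronal", "axial")
#: grid axis perpendicular to each plane
_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}

MIN_EXTENT = 8  # voxels; below this the estimators have no usable slices
MAX_ANGLE_DEG = 45.0  # method undefined beyond this; the study validates +-30


@dataclass
class Volume:
    """A 3D intensity grid in the canonical RAS frame.

    Parameters
    ----------
    data:
        3D array of finite intensities (arbitrary units).
    spacing:
        Per-axis voxel size in mm, all strictly positive.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if any(n < MIN_EXTENT for n in self.data.shape):
            raise DegenerateInputError(
                f"volume extent {self.data.shape} below the minimum of "
                f"{MIN_EXTENT} voxels per axis"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SliceView:
    """One 2D section of a :class:`Volume` with provenance.

    ``pixel_spacing`` is (row spacing, column spacing) in mm.
    """

    plane: str
    index: int
    pixels: np.ndarray
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")

    @property
    def pixel_area(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass
class TiltAngles:
    """Pitch/yaw/roll in degrees, in the canonical frame.

    pitch (omega) about X, yaw (theta) about Z, roll (phi) about Y.
    ``per_slice_yaw`` optionally records the per-slice yaw values whose
    arithmetic mean is ``yaw_deg``.
    """

    pitch_deg: float = 0.0
    yaw_deg: float = 0.0
    roll_deg: float = 0.0
    per_slice_yaw: Optional[list[float]] = field(default=None)

    def __post_init__(self) -> None:
        for name in ("pitch_deg", "yaw_deg", "roll_deg"):
            v = float(getattr(self, name))
            setattr(self, name, v)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if abs(v) > MAX_ANGLE_DEG:
                raise ValueError(
                    f"|{name}| = {abs(v):.2f} exceeds the {MAX_ANGLE_DEG} deg "
                    "validity range of the method"
                )
        if self.per_slice_yaw is not None:
            mean = float(np.mean(self.per_slice_yaw))
            if abs(mean - self.yaw_deg) > 1e-9:
                raise ValueError("yaw_deg must equal the mean of per_slice_yaw")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pitch_deg, self.yaw_deg, self.roll_deg)


def load_volume(path: str | Path) -> Volume:
    """Load a NIfTI-1 volume and reorient it into the canonical RAS frame.

    Raises
    ------
    VolumeIOError
        If the file cannot be read.
    DegenerateInputError
        If any axis has fewer than 8 voxels.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)  # reorient to RAS
        data = np.asanyarray(img.dataobj)
    except DegenerateInputError:
        raise
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise VolumeIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing)  # validates extent/spacing


def save_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with an identity orientation scaled by spacing.

    Integer data round-trips exactly; floats are stored as float32.
    """
    path = Path(path)
    data = volume.data
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeIOError(f"cannot write NIfTI volume {path}: {exc}") from exc


def extract_slice(volume: Volume, plane: str, index: int) -> SliceView:
    """Extract one slice in the display layout documented in the module header."""
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    axis = _PLANE_AXIS[plane]
    n = volume.shape[axis]
    if not (0 <= index < n):
        raise IndexError(f"{plane} index {index} out of range [0, {n})")
    sx, sy, sz = volume.spacing
    if plane == "sagittal":
        # rows: superior -> inferior (z reversed); cols: anterior -> posterior (y reversed)
        pixels = volume.data[index, :, :].T[::-1, ::-1]
        spacing = (sz, sy)
    elif plane == "coronal":
        # rows: superior -> inferior; cols: left -> right (x ascending)
        pixels = volume.data[:, index, :].T[::-1, :]
        spacing = (sz, sx)
    else:  # axial
        # rows: anterior index ascending; cols: right index ascending
        pixels = volume.data[:, :, index].T
        spacing = (sy, sx)
    return SliceView(plane=plane, index=index, pixels=np.ascontiguousarray(pixels),
                     pixel_spacing=spacing)


def slice_to_voxel(plane: str, index: int, row: float, col: float,
                   shape: Sequence[int]) -> tuple[float, float, float]:
    """Map a (row, col) pixel of an extracted slice back to voxel (i, j, k)."""
    nx, ny, nz = shape
    if plane == "sagittal":
        return (float(index), ny - 1.0 - col, nz - 1.0 - row)
    if plane == "coronal":
        return (float(col), float(index), nz - 1.0 - row)
    if plane == "axial":
        return (float(col), float(row), float(index))
    raise ValueError(f"unknown plane {plane!r}")


def mid_sagittal_index(volume: Volume) -> int:
    """Index of the mid-sagittal slice: the sagittal extent floor-divided by 2."""
    return volume.shape[0] // 2
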