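"""Synthetic whole-head phantoms with known tilt, landmarks and noise.

The phantom emulates the features the estimators rely on in real whole-head
MR volumes:

* an ellipsoidal head elongated along the anterior-posterior axis, with a
  thin bright scalp shell over a dark skull/CSF gap and a bright inner
  brain compartment (giving the bimodal background/tissue histogram the
  Otsu step assumes, and letting the erosion/largest-component skull strip
  separate brain from scalp);
* a nasal region on the mid-sagittal anterior surface: a protruding nose
  with a notch above it whose deepest point is the Nasion, plus optional
  philtrum/labial-commissure distractor bumps further down to exercise the
  pitch search-range logic;
* an occipital crest (Inion) on the posterior surface at the same height as
  the Nasion, so the untilted Nasion-Inion line is horizontal;
* a known rigid tilt, applied **analytically**: the implicit geometry is
  evaluated on rotated coordinates, so ground truth involves no resampling
  at all and shares no code path with the trilinear corrector;
* zero-mean Gaussian noise with sigma = noise_pct/100 x brain intensity
  (the BrainWeb "% noise" convention), and slab-averaged slice-thickness
  degradation via :func:`resample_thickness`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import UnsupportedConfigurationError
from .volio import TiltAngles, Volume

__all__ = ["PhantomSpec", "PhantomTruth", "make_phantom", "resample_thickness"]


@dataclass
class PhantomSpec:
    """Geometry, intensities, degradation and tilt of one synthetic head.

    The defaults describe the study conditions used throughout the test
    harness: a 128^3 grid at 1 mm isotropic spacing holding a head with
    anterior-posterior elongation 55/40 ~ 1.38 (comfortably above the 1.2
    ellipse-ratio gate), a 6 mm nasion notch and an 8 mm inion crest.
    The geometric rationale behind the inner column's z-structure is laid
    out in docs/methods.md.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    head_semi_axes_mm: tuple[float, float, float] = (40.0, 55.0, 66.0)
    brain_semi_axes_mm: tuple[float, float, float] = (33.5, 49.0, 40.0)
    #: head-normalised radius where the bright scalp shell begins
    scalp_inner_frac: float = 0.96
    #: z-offset (mm from head centre) of the nasion notch / inion crest
    nasion_offset_mm: float = 0.0
    inion_offset_mm: float = 0.0
    notch_depth_mm: float = 6.0
    crest_height_mm: float = 8.0
    #: nose protrusion below the notch
    nose_offset_mm: float = -14.0
    nose_height_mm: float = 8.0
    #: philtrum / labial-commissure distractor bumps below the nose
    include_distractors: bool = True
    #: where the inner column's taper ends (mm): beyond the oblique reach
    #: of the default acquisition, so the column has no visible end cap
    column_end_mm: float = 92.0
    #: where the deep sulcal grooves begin (mm): grooved sections fail the
    #: area gate even when truncated by an acquisition boundary
    groove_start_mm: float = 76.0
    #: (background, skull/scalp, brain) intensity levels; the scalp (fat)
    #: shell is the brightest tissue, as in T1 weighting, and the skull/CSF
    #: gap takes 15% of the scalp level
    intensities: tuple[float, float, float] = (0.0, 120.0, 100.0)
    noise_pct: float = 0.0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    applied_tilt: TiltAngles = field(default_factory=TiltAngles)
    seed: int = 0

    def __post_init__(self) -> None:
        ax, ay, az = self.head_semi_axes_mm
        bx, by, bz = self.brain_semi_axes_mm
        if ay / ax < 1.3:
            raise ValueError(
                f"head elongation a_y/a_x = {ay / ax:.2f} must be >= 1.3 so that "
                "mid-volume axial slices clear the 1.2 ellipse-ratio gate")
        if not (bx < ax and by < ay and bz < az):
            raise ValueError("brain compartment must lie inside the head")
        if not (0.0 <= self.noise_pct < 100.0):
            raise ValueError(f"noise_pct must be in [0, 100), got {self.noise_pct}")
        if not (0.5 < self.scalp_inner_frac < 1.0):
            raise ValueError("scalp_inner_frac must be in (0.5, 1)")


@dataclass
class PhantomTruth:
    """Ground truth of one generated phantom (coordinates after tilt)."""

    nasion_voxel: tuple[float, float, float]
    inion_voxel: tuple[float, float, float]
    centroid_voxel: tuple[float, float, float]
    applied_tilt: TiltAngles
    head_mask: np.ndarray
    brain_mask: np.ndarray
    spec: PhantomSpec


def _tilt_matrix(angles: TiltAngles) -> np.ndarray:
    """World rotation of the applied tilt, Rz(yaw) Ry(roll) Rx(pitch).

    Built with scipy's Rotation (intrinsic Z-Y-X Euler angles), deliberately
    independent of :mod:`mrtilt.rigid`'s own composition.
    """
    return Rotation.from_euler(
        "ZYX", [angles.yaw_deg, angles.roll_deg, angles.pitch_deg], degrees=True
    ).as_matrix()


def _anterior_bumps(spec: PhantomSpec) -> list[tuple[float, float, float, float]]:
    """(amplitude_mm, z_center_mm, sigma_x_mm, sigma_z_mm) on the anterior face."""
    bumps = [
        (-spec.notch_depth_mm, spec.nasion_offset_mm, 5.0, 3.0),  # nasion notch
        (spec.nose_height_mm, spec.nose_offset_mm, 5.0, 4.5),     # nose
    ]
    if spec.include_distractors:
        bumps.append((3.0, spec.nose_offset_mm - 12.0, 5.0, 3.0))  # philtrum
        bumps.append((3.0, spec.nose_offset_mm - 19.0, 6.0, 3.0))  # labial commissure
    return bumps


def _head_outline_radius(semi_axes: tuple[float, float, float],
                         u: np.ndarray,
                         z1_frac: float = 0.55,
                         blend_frac: float = 0.25) -> np.ndarray:
    """Normalised radius of the outer head surface.

    Ellipsoidal through the mid-band (the sagittal outline the pitch
    landmarks need: boundary distance to the centroid shrinks away from the
    equator, so the inion crest is the unique maximum), with the in-plane
    aspect blending to circular toward crown and base.  Round caps matter:
    axial cuts tangent to the skin near the crown form solid discs, and
    only near-circular discs are reliably rejected by the ellipse gate
    under any tilt.
    """
    a_x, a_y, a_z = semi_axes
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    e0 = a_y / a_x
    m0 = np.sqrt(a_x * a_y)
    za = np.abs(z)
    s = np.sqrt(np.clip(1.0 - (z / a_z) ** 2, 0.0, None))
    t = np.clip((za - z1_frac * a_z) / (blend_frac * a_z), 0.0, 1.0)
    g = 0.5 * (1.0 + np.cos(np.pi * t))
    aspect = 1.0 + (e0 - 1.0) * g
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.sqrt((x * np.sqrt(aspect) / (m0 * s)) ** 2
                      + (y / (m0 * s * np.sqrt(aspect))) ** 2)
    return np.where((za >= a_z) | (s <= 0), np.inf, rho)


def _brain_column_radius(semi_axes: tuple[float, float, float],
                         u: np.ndarray,
                         column_end_mm: float = 92.0,
                         groove_start_mm: float = 76.0,
                         prism_frac: float = 0.875,
                         waist_frac: float = 1.25,
                         waist_depth: float = 0.35,
                         waist_sigma_mm: float = 12.0) -> np.ndarray:
    """Normalised radius of the inner brain compartment.

    The z-structure encodes the validity conditions of the axial-slice
    estimators, which real brains satisfy approximately and a smooth
    ellipsoid does not:

    * every cross-section of the column |z| <= z2 has the same elongated
      (a_x, a_y) outline centred on the mid-sagittal plane, so under a roll
      tilt each axial cut — even one that obliquely mixes several section
      shapes — is centred on the rolled mid-sagittal plane x = z tan(phi),
      the signal the orthogonal-regression plane fit reads;
    * away from the mid-band an interhemispheric-fissure *waist* deepens:
      the midline (x ~ 0) indents from the anterior and posterior ends,
      exactly as the fissure appears in superior axial slices of a real
      head.  A waisted section is concave, its moment-ellipse area
      overshoots the pixel count by far more than the gate's 200 px^2
      tolerance, so the ellipse gate confines the accepted band to a
      contiguous mid-volume band.  The waist sits at the midline, so the
      area it removes is laterally symmetric and adds no centroid pull to
      oblique cuts;
    ``a_z`` sets only the waist ramp scale: ``z1 = prism_frac * a_z``
    (waist-free band) and ``z2 = waist_frac * a_z`` (full depth).
    """
    a_x, a_y, a_z = semi_axes
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    z1 = prism_frac * a_z
    z2 = waist_frac * a_z
    za = np.abs(z)
    # fissure waist: 0 in the mid-band, saturating at full depth from z2
    # outward.  The full depth is chosen inside the gate's dead zone:
    # blunting the y-tips drops the moment axis ratio of a
    # 1.5-aspect section below 1.2 without flipping it into lateral
    # elongation, so blunted sections are rejected at every tilt.  The
    # column itself runs through the whole axial field of view (the
    # brainstem/neck continuation inferiorly); a column end inside the FOV
    # would produce oblique cone cuts — elongated, gate-passing almonds
    # with off-plane centres — under large roll.
    t = np.clip((za - z1) / (z2 - z1), 0.0, 1.0)
    d = waist_depth * 0.5 * (1.0 - np.cos(np.pi * t))
    waist = 1.0 - d * np.exp(-(x ** 2) / (2.0 * waist_sigma_mm ** 2))
    # the column ends with a gentle elliptical taper far outside the
    # acquisition's oblique reach: cuts through a column end are elongated,
    # gate-passing almonds with off-plane centres, so the end must never be
    # visible to any slice of the frames the estimators run in
    t1 = column_end_mm
    t0 = t1 - 16.0
    ss = np.sqrt(np.clip(1.0 - ((za - t0) / (t1 - t0)) ** 2, 0.0, None))
    ss = np.where(za <= t0, 1.0, ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.sqrt((x / (a_x * ss)) ** 2 + (y / (a_y * ss * waist)) ** 2)
        # deep sulcal grooves on the far sections (|z| > z2 - 4): concave
        # sections fail the +-200 px^2 area gate *robustly* — truncating or
        # obliquely mixing a grooved section preserves its concavity, so
        # cuts through the column ends or through an acquisition boundary
        # can never be revived into gate-passing ellipses
        phi = np.arctan2(y / (a_y * ss * waist), x / (a_x * ss))
        groove = np.zeros_like(rho)
        for pk in (0.25 * np.pi, 0.75 * np.pi, -0.25 * np.pi, -0.75 * np.pi):
            dphi = np.mod(phi - pk + np.pi, 2.0 * np.pi) - np.pi
            groove += np.exp(-dphi ** 2 / (2.0 * np.radians(16.0) ** 2))
        tg = np.clip((za - groove_start_mm) / 6.0, 0.0, 1.0)
        gd = 0.5 * 0.5 * (1.0 - np.cos(np.pi * tg))
        rho = rho + gd * groove
        # narrow sulcal clefts at every height: thin enough that the skull
        # strip's dilation + flood fill seals them at native resolution
        # (contours stay exact ellipses), but thick-slab acquisition plus a
        # software rotation ghosts them into wide open notches that the
        # +-200 px^2 area gate rejects — the thick-slice failure mode
        slots = np.zeros_like(rho)
        for pk_deg in (20.0, 50.0, 75.0, 105.0, 130.0, 160.0,
                       -20.0, -50.0, -75.0, -105.0, -130.0, -160.0):
            dphi = np.mod(phi - np.radians(pk_deg) + np.pi, 2.0 * np.pi) - np.pi
            slots += np.exp(-dphi ** 2 / (2.0 * np.radians(1.8) ** 2))
        rho = rho + 0.25 * slots
    return np.where((za >= t1) | (ss <= 0), np.inf, rho)


def _head_radius(spec: PhantomSpec, u: np.ndarray) -> np.ndarray:
    """Normalised head radius with surface bumps subtracted.

    ``u`` is (..., 3) in untilted head-centred mm.  A point is inside the
    head where the returned value is <= 1.  Bumps displace the surface by
    roughly their amplitude in mm (converted to normalised units with the
    anterior semi-axis, since all bumps sit on the +-Y faces).
    """
    ay = spec.head_semi_axes_mm[1]
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    rho = _head_outline_radius(spec.head_semi_axes_mm, u)
    for amp, zc, sx, sz in _anterior_bumps(spec):
        g = np.exp(-(x ** 2) / (2 * sx ** 2) - ((z - zc) ** 2) / (2 * sz ** 2))
        rho = rho - (amp / ay) * g * (y > 0)
    # inion crest on the posterior face
    g = np.exp(-(x ** 2) / (2 * 7.0 ** 2)
               - ((z - spec.inion_offset_mm) ** 2) / (2 * 3.0 ** 2))
    rho = rho - (spec.crest_height_mm / ay) * g * (y < 0)
    return rho


def _brain_radius(spec: PhantomSpec, u: np.ndarray) -> np.ndarray:
    return _brain_column_radius(spec.brain_semi_axes_mm, u,
                                column_end_mm=spec.column_end_mm,
                                groove_start_mm=spec.groove_start_mm)


def _surface_y(spec: PhantomSpec, z_mm: float, anterior: bool) -> float:
    """y of the head surface on the mid-sagittal line x=0 at height z (mm)."""
    ay = spec.head_semi_axes_mm[1]
    ys = np.arange(0.0, ay + spec.nose_height_mm + 2.0, 0.01)
    if not anterior:
        ys = -ys
    pts = np.zeros((ys.size, 3))
    pts[:, 1] = ys
    pts[:, 2] = z_mm
    inside = _head_radius(spec, pts) <= 1.0
    idx = np.flatnonzero(inside)
    if idx.size == 0:
        raise UnsupportedConfigurationError("no head surface on the mid-sagittal line")
    return float(ys[idx[-1]])


def make_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Generate one tilted, noisy phantom and its ground truth.

    The untilted implicit geometry is evaluated at R^T w for every voxel
    world coordinate w (head-centred mm), i.e. the tilt is exact up to voxel
    sampling.  The same seed always reproduces the same volume bit for bit.
    """
    for name, v in (("pitch", spec.applied_tilt.pitch_deg),
                    ("yaw", spec.applied_tilt.yaw_deg),
                    ("roll", spec.applied_tilt.roll_deg)):
        if abs(v) > 45.0:
            raise UnsupportedConfigurationError(f"|{name}| > 45 deg is unsupported")

    nx, ny, nz = spec.shape
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    center = (np.asarray(spec.shape, dtype=float) - 1.0) / 2.0
    R = _tilt_matrix(spec.applied_tilt)

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij", sparse=False)
    w = np.stack([ii, jj, kk], axis=-1).astype(np.float32)
    w = (w - center) * spacing  # world mm, head-centred
    u = w @ R  # == (R.T @ w^T)^T : untilted coordinates

    rho_head = _head_radius(spec, u)
    rho_brain = _brain_radius(spec, u)
    brain_mask = rho_brain <= 1.0
    # the head mask is the full imaged-tissue union (outer head surface plus
    # the inner column, which runs past the crown region)
    head_mask = (rho_head <= 1.0) | brain_mask

    bg, skull, brain = spec.intensities
    data = np.full(spec.shape, bg, dtype=np.float32)
    scalp_zone = head_mask & (rho_head > spec.scalp_inner_frac)
    gap_zone = head_mask & ~scalp_zone & ~brain_mask
    data[scalp_zone] = skull
    data[gap_zone] = bg + 0.15 * (skull - bg)  # dark skull/CSF gap
    data[brain_mask] = brain

    if spec.noise_pct > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_pct / 100.0 * brain
        data = data + rng.normal(0.0, sigma, size=data.shape).astype(np.float32)
        np.clip(data, 0.0, None, out=data)  # magnitude images are non-negative

    def _world_to_voxel(p_untilted: np.ndarray) -> tuple[float, float, float]:
        p_world = R @ np.asarray(p_untilted, dtype=float)
        vox = p_world / spacing + center
        return (float(vox[0]), float(vox[1]), float(vox[2]))

    y_nasion = _surface_y(spec, spec.nasion_offset_mm, anterior=True)
    y_inion = _surface_y(spec, spec.inion_offset_mm, anterior=False)
    truth = PhantomTruth(
        nasion_voxel=_world_to_voxel([0.0, y_nasion, spec.nasion_offset_mm]),
        inion_voxel=_world_to_voxel([0.0, y_inion, spec.inion_offset_mm]),
        centroid_voxel=_world_to_voxel([0.0, 0.0, 0.0]),
        applied_tilt=spec.applied_tilt,
        head_mask=head_mask,
        brain_mask=brain_mask,
        spec=spec,
    )
    return Volume(data=data, spacing=tuple(spacing)), truth


def resample_thickness(volume: Volume, new_thickness_mm: float) -> Volume:
    """Degrade axial resolution to ``new_thickness_mm`` by slab averaging.

    Consecutive axial slices are averaged in groups of the (integer) ratio
    new/current; a trailing remainder of slices is dropped (floor policy).
    No slice-profile modelling, no upsampling.
    """
    sz = volume.spacing[2]
    ratio = new_thickness_mm / sz
    if ratio < 1.0 - 1e-9:
        raise UnsupportedConfigurationError(
            f"cannot upsample: requested {new_thickness_mm} mm < current {sz} mm")
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-6:
        raise UnsupportedConfigurationError(
            f"slice thickness {new_thickness_mm} mm is not an integer multiple "
            f"of the current {sz} mm spacing")
    if factor == 1:
        return Volume(data=volume.data.copy(), spacing=volume.spacing)
    nz = volume.shape[2]
    m = nz // factor
    trimmed = volume.data[:, :, :m * factor]
    slabs = trimmed.reshape(volume.shape[0], volume.shape[1], m, factor).mean(axis=3)
    return Volume(data=slabs.astype(volume.data.dtype, copy=False),
                  spacing=(volume.spacing[0], volume.spacing[1], sz * factor))
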