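import math

import numpy as np
import pytest

from mrtilt import errors
from mrtilt.phantom import PhantomSpec, make_phantom
from mrtilt.rigid import (RotationMatrix, apply_rotation, correct_tilt,
                          estimate_tilt, rotation_matrix)
from mrtilt.volio import TiltAngles, Volume


def printed_matrix(omega_deg, theta_deg, phi_deg):
    """Elementwise closed form of the yaw-roll-pitch matrix (oracle)."""
    w, t, p = (math.radians(a) for a in (omega_deg, theta_deg, phi_deg))
    cw, sw = math.cos(w), math.sin(w)
    ct, st = math.cos(t), math.sin(t)
    cp, sp = math.cos(p), math.sin(p)
    return np.array([
        [cp * ct, ct * sw * sp - cw * st, cw * ct * sp + sw * st],
        [st * cp, cw * ct + st * sp * sw, cw * st * sp - sw * ct],
        [-sp, sw * cp, cw * cp],
    ])


class TestRotationMatrix:
    def test_zero_angles_give_exact_identity(self):
        assert np.array_equal(rotation_matrix(TiltAngles()).m, np.eye(3))

    def test_quarter_turn_about_z_permutes_x_to_y(self):
        m = rotation_matrix(TiltAngles(0, 45, 0))  # validity cap is 45 deg
        v = m.m @ np.array([1.0, 0.0, 0.0])
        assert v == pytest.approx([math.cos(math.radians(45)),
                                   math.sin(math.radians(45)), 0.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_printed_elementwise_form(self, seed):
        rng = np.random.default_rng(seed)
        w, t, p = rng.uniform(-45, 45, size=3)
        m = rotation_matrix(TiltAngles(w, t, p)).m
        np.testing.assert_allclose(m, printed_matrix(w, t, p), atol=1e-12)

    def test_third_row_closed_forms(self):
        w, t, p = 11.0, -23.0, 37.0
        m = rotation_matrix(TiltAngles(w, t, p)).m
        assert m[2, 0] == pytest.approx(-math.sin(math.radians(p)), abs=1e-12)
        assert m[2, 1] == pytest.approx(
            math.sin(math.radians(w)) * math.cos(math.radians(p)), abs=1e-12)
        assert m[2, 2] == pytest.approx(
            math.cos(math.radians(w)) * math.cos(math.radians(p)), abs=1e-12)

    def test_reversed_negated_composition_equals_inverse(self):
        from mrtilt.rigid import _elemental
        w, t, p = 9.0, -17.0, 25.0
        forward = rotation_matrix(TiltAngles(w, t, p)).m
        backward = (_elemental(0, -w) @ _elemental(1, -p) @ _elemental(2, -t))
        np.testing.assert_allclose(backward, forward.T, atol=1e-12)

    def test_rejects_improper_matrix(self):
        with pytest.raises(errors.InvalidTransformError):
            RotationMatrix(m=np.diag([1.0, 1.0, -1.0]))


class TestApplyRotation:
    def test_identity_rotation_reproduces_the_grid(self):
        rng = np.random.default_rng(0)
        vol = Volume(data=rng.normal(size=(10, 11, 12)), spacing=(1, 1, 1))
        out = apply_rotation(vol, rotation_matrix(TiltAngles()), reshape=False)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_quarter_turn_equals_axis_permutation(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(15, 15, 8))
        vol = Volume(data=data, spacing=(1, 1, 1))
        quarter = RotationMatrix(m=np.array([[0.0, -1.0, 0.0],
                                             [1.0, 0.0, 0.0],
                                             [0.0, 0.0, 1.0]]))
        out = apply_rotation(vol, quarter, reshape=False)
        # +90 deg about Z maps +X to +Y; verify against the numpy rot oracle
        np.testing.assert_allclose(out.data, np.rot90(data, k=1, axes=(0, 1)),
                                   atol=1e-9)

    def test_round_trip_error_is_small_on_smooth_volume(self):
        zz = np.mgrid[0:48, 0:48, 0:48]
        r2 = sum(((a - 23.5) / 15.0) ** 2 for a in zz)
        data = 100.0 * np.exp(-r2)
        vol = Volume(data=data, spacing=(1, 1, 1))
        rot = rotation_matrix(TiltAngles(5, 20, -10))
        there = apply_rotation(vol, rot, reshape=False)
        back = apply_rotation(there, rot.inverse(), reshape=False)
        core = (slice(8, 40),) * 3  # ignore edges that left the grid
        rms = np.sqrt(np.mean((back.data[core] - data[core]) ** 2))
        assert rms <= 0.02 * (data.max() - data.min())

    def test_reshape_preserves_foreground_mass(self):
        zz = np.mgrid[0:40, 0:40, 0:40]
        r2 = (((zz[0] - 19.5) / 10) ** 2 + ((zz[1] - 19.5) / 14) ** 2
              + ((zz[2] - 19.5) / 12) ** 2)
        vol = Volume(data=np.where(r2 <= 1, 100.0, 0.0), spacing=(1, 1, 1))
        before = (vol.data > 50).sum()
        out = apply_rotation(vol, rotation_matrix(TiltAngles(10, 30, -20)),
                             reshape=True)
        after = (out.data > 50).sum()
        assert abs(after - before) / before < 0.02

    def test_non_orthonormal_matrix_rejected(self):
        vol = Volume(data=np.zeros((8, 8, 8)), spacing=(1, 1, 1))
        with pytest.raises(errors.InvalidTransformError):
            apply_rotation(vol, np.diag([1.0, 2.0, 1.0]))


class TestCorrectTilt:
    def test_already_aligned_phantom_needs_no_correction(self, untilted_volume):
        corrected, used = correct_tilt(untilted_volume, "auto", reshape=False)
        assert abs(used.yaw_deg) <= 0.5
        assert abs(used.roll_deg) <= 0.5
        assert abs(used.pitch_deg) <= 1.0

    def test_supplied_angles_are_applied_inverse(self, untilted_volume):
        angles = TiltAngles(0, 10, 0)
        corrected, used = correct_tilt(untilted_volume, angles, reshape=False)
        assert used is angles
        from mrtilt.yaw import estimate_yaw
        theta, _ = estimate_yaw(corrected)
        assert theta == pytest.approx(-10.0, abs=0.6)

    def test_faceless_volume_reports_pitch_not_estimated(self, faceless):
        vol, _ = faceless
        angles, report = estimate_tilt(vol)
        assert not report["pitch_estimated"]
        assert report["yaw_estimated"] and report["roll_estimated"]
        assert angles.pitch_deg == 0.0

    def test_all_estimators_failing_is_an_error(self):
        rng = np.random.default_rng(5)
        vol = Volume(data=rng.normal(size=(16, 16, 16)) * 0.0, spacing=(1, 1, 1))
        vol.data[8, 8, 8] = 1.0
        with pytest.raises((errors.CorrectionImpossibleError,
                            errors.MrTiltError)):
            correct_tilt(vol, "auto")
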