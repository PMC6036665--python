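"""Dual-arm orientation, registration and SNR-normalizing overlap."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.transform import rotate as sk_rotate

from asoct import (
    MisuseError,
    RegistrationError,
    RigidTransform,
    orient_arm2,
    overlap_frames,
    register_frames,
    single_arm_sensitivity_linear,
)
from asoct.fusion import BScanFrame


@pytest.fixture(scope="module")
def structured_frame():
    """Synthetic anatomy-like raster: bright arc, planar stripe, noise."""
    rng = np.random.default_rng(0)
    img = np.full((512, 400), -40.0)
    yy, xx = np.mgrid[0:512, 0:400]
    img += 30 * np.exp(-((yy - (200 + (xx - 200) ** 2 / 180)) ** 2) / 8)
    img[300:304, :] += 35
    return img + rng.normal(0, 0.3, img.shape)


def frame_of(raster, arm_id=1, placement="top"):
    return BScanFrame(np.asarray(raster, float), arm_id, placement, 0.01, 0.01)


class TestOrientArm2:
    def test_double_flip_is_identity(self, structured_frame):
        f = frame_of(structured_frame, arm_id=2)
        twice = orient_arm2(orient_arm2(f))
        np.testing.assert_array_equal(twice.raster, f.raster)
        assert twice.zero_delay_placement == f.zero_delay_placement

    def test_placement_metadata_toggles(self, structured_frame):
        f = frame_of(structured_frame, arm_id=2, placement="bottom")
        assert orient_arm2(f).zero_delay_placement == "top"

    def test_wrong_arm_rejected(self, structured_frame):
        with pytest.raises(MisuseError):
            orient_arm2(frame_of(structured_frame, arm_id=1))

    def test_oriented_arm2_of_symmetric_pair_matches_arm1(
        self, small_bscan_set, arm_geometry
    ):
        """The simulator places the anatomy mirrored about the two zero-delay
        planes; after orientation both frames show the iris at the same
        anatomical depth (strongest common feature)."""
        from asoct import nominal_row_offset

        b1, b2 = small_bscan_set
        o2 = orient_arm2(b2)
        assert o2.raster.shape == b1.raster.shape
        # after orientation the common features line up at the nominal offset:
        # registration finds essentially zero residual misalignment
        r0 = nominal_row_offset(arm_geometry, b1.depth_per_pixel, b1.n_depth)
        t = register_frames(b1, o2, r0, rotation_span=0.0)
        assert t.correlation > 0.3
        assert abs(t.translation[0]) < 3
        assert abs(t.translation[1]) < 3


class TestRegisterFrames:
    def test_identical_frames_identity_transform(self, structured_frame):
        f1 = frame_of(structured_frame)
        f2 = frame_of(structured_frame.copy(), arm_id=2)
        t = register_frames(f1, f2, nominal_offset_px=0)
        assert t.correlation > 0.99
        assert abs(t.rotation) <= 0.05
        assert np.hypot(*t.translation) < 0.5

    def test_known_shift_and_rotation_recovered(self, structured_frame):
        f1 = frame_of(structured_frame)
        moved = sk_rotate(structured_frame, 0.5, preserve_range=True, cval=-40.0)
        moved = ndimage.shift(moved, (7, 3), cval=-40.0)
        t = register_frames(f1, frame_of(moved, arm_id=2), nominal_offset_px=0)
        # content displaced by (+7, +3) must be placed back by (-7, -3)
        assert t.translation[0] == pytest.approx(-7, abs=1.0)
        assert t.translation[1] == pytest.approx(-3, abs=1.0)
        assert t.rotation == pytest.approx(0.5, abs=0.1)

    def test_pure_noise_raises_registration_error(self):
        rng = np.random.default_rng(1)
        f1 = frame_of(rng.normal(-40, 1, (512, 400)))
        f2 = frame_of(rng.normal(-40, 1, (512, 400)), arm_id=2)
        with pytest.raises(RegistrationError):
            register_frames(f1, f2, nominal_offset_px=0)

    def test_degrades_gracefully_at_20db_snr(self, structured_frame):
        rng = np.random.default_rng(2)
        noisy = structured_frame + rng.normal(0, 3.0, structured_frame.shape)
        moved = ndimage.shift(noisy, (5, -2), cval=-40.0)
        t = register_frames(frame_of(structured_frame), frame_of(moved, arm_id=2), 0,
                            rotation_span=0.0)
        assert t.translation[0] == pytest.approx(-5, abs=2.0)
        assert t.translation[1] == pytest.approx(2, abs=2.0)


class TestOverlapFrames:
    def test_uniform_sensitivity_blend_preserves_identical_input(self):
        img = np.full((200, 64), -10.0)
        f1 = frame_of(img)
        f2 = frame_of(img.copy(), arm_id=2)
        fused = overlap_frames(
            f1, f2, RigidTransform(0.0, (0.0, 0.0)),
            nominal_offset_px=0, sensitivity_model=lambda d: np.ones_like(np.asarray(d, float)),
        )
        np.testing.assert_allclose(fused.raster[:200], img, atol=1e-9)

    def test_linear_rolloff_hand_case_30db_v_profile(self):
        """60 dB of linear single-arm roll-off over 11 mm with an 11 mm arm
        offset folds into a V-shaped combined profile: 30 dB drop at
        mid-depth."""
        dpp = 11.0 / 1000
        f1 = BScanFrame(np.full((1000, 64), -20.0), 1, "top", dpp, 0.01)
        f2 = BScanFrame(np.full((1000, 64), -20.0), 2, "top", dpp, 0.01)
        model = lambda d: 10.0 ** (-(60.0 / 11.0) * np.abs(np.asarray(d, float)) / 10.0)
        fused = overlap_frames(
            f1, f2, RigidTransform(0.0, (0.0, 0.0)),
            nominal_offset_px=1, sensitivity_model=model,
        )
        assert fused.combined_dropoff_db == pytest.approx(30.0, abs=0.2)
        profile = fused.sensitivity_profile
        assert np.argmin(profile) == pytest.approx(len(profile) / 2, abs=2)

    def test_combined_profile_dominates_each_single_arm(self):
        f1 = frame_of(np.full((500, 64), -20.0))
        f2 = frame_of(np.full((500, 64), -20.0), arm_id=2)
        zmax = 500 * 0.01
        fused = overlap_frames(f1, f2, RigidTransform(0.0, (0.0, 0.0)),
                               nominal_offset_px=400, z_max=zmax)
        depths = fused.depth_axis
        s1 = 10 * np.log10(single_arm_sensitivity_linear(depths, zmax))
        s2 = 10 * np.log10(
            single_arm_sensitivity_linear(np.abs(fused.arm2_zero_depth - depths), zmax)
        )
        assert np.all(fused.sensitivity_profile >= s1 - 1e-9)
        assert np.all(fused.sensitivity_profile >= s2 - 1e-9)

    def test_combined_dropoff_below_single_arm(self):
        """With the arm offset matched to the depth range, the fused drop-off
        is strictly smaller than what a single arm suffers over that range."""
        f1 = frame_of(np.full((500, 64), -20.0))
        f2 = frame_of(np.full((500, 64), -20.0), arm_id=2)
        zmax = 500 * 0.01
        fused = overlap_frames(f1, f2, RigidTransform(0.0, (0.0, 0.0)),
                               nominal_offset_px=450, z_max=zmax)
        s_single = 10 * np.log10(single_arm_sensitivity_linear(fused.depth_axis, zmax))
        single_drop = s_single.max() - s_single[fused.depth_axis <= fused.arm2_zero_depth].min()
        assert fused.combined_dropoff_db < single_drop

    def test_end_to_end_fused_shows_all_four_boundaries(
        self, small_bscan_set, phantom, arm_geometry, system3, source
    ):
        """Arm 1 alone loses the posterior lens; the fused image shows all
        four cornea/lens boundaries at >= 6 dB above the floor."""
        from asoct import fuse_pair, max_scan_depth, optical_path_traces

        b1, b2 = small_bscan_set
        zmax = max_scan_depth(source.center_wavelength, system3.delta_lambda)
        fused = fuse_pair(b1, b2, arm_geometry, z_max=zmax, rotation_span=0.0)
        col = b1.n_alines // 2 + 27  # ~1 mm off-center, inside the pupil
        x = (col - (b1.n_alines - 1) / 2) * b1.lateral_per_pixel
        truth = optical_path_traces(phantom, np.array([x]), arm_geometry, arm=1)
        floor = np.median(fused.raster[:, col])
        for label, d in truth.items():
            j = int(round(float(d[0]) / fused.depth_per_pixel))
            peak = fused.raster[j - 3 : j + 4, col].max()
            assert peak >= floor + 6.0, label
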