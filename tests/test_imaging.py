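"""Perspective model, silhouette measurement and stress computation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryogel.imaging import (
    CameraModel,
    SegmentationError,
    compute_stress,
    depth_offset,
    measure_frame,
    process_sequence,
    scale_at,
)
from cryogel.synthetic import TrajectorySpec, compression_trajectory, render_cylinder_sequence


class TestCameraModel:
    def test_symmetry_plane_identity(self, camera):
        assert scale_at(camera, 0.0) == camera.base_scale

    def test_halfway_doubles(self, camera):
        assert scale_at(camera, camera.working_distance / 2) == pytest.approx(
            2 * camera.base_scale
        )

    def test_beyond_lens_rejected(self, camera):
        with pytest.raises(ValueError):
            scale_at(camera, camera.working_distance)

    @given(st.floats(min_value=0.0, max_value=299.0))
    @settings(max_examples=50, deadline=None)
    def test_px_mm_round_trip(self, d):
        cam = CameraModel(base_scale=40.0, working_distance=300.0)
        s = scale_at(cam, d)
        mm = 123.0
        assert (mm * s) / s == pytest.approx(mm, abs=1e-12)

    def test_invalid_camera_rejected(self):
        with pytest.raises(ValueError):
            CameraModel(base_scale=-1.0, working_distance=300.0)


class TestDepthOffset:
    @pytest.mark.parametrize("R,Rc,d", [(10.0, 10.0, 0.0), (10.0, 0.0, 10.0), (10.0, 6.0, 8.0)])
    def test_circular_cross_section(self, R, Rc, d):
        assert depth_offset(R, Rc) == pytest.approx(d, abs=1e-12)

    def test_offset_beyond_radius_rejected(self):
        with pytest.raises(ValueError):
            depth_offset(10.0, 10.5)


class TestStress:
    def test_reference_magnitude(self):
        # 0.848 N on a 20 mm diameter cross-section
        expected = 0.848 / (math.pi * 20.0 ** 2 / 4.0) * 1000.0
        assert compute_stress(0.848, 20.0) == pytest.approx(expected, rel=1e-12)
        assert compute_stress(0.848, 20.0) == pytest.approx(2.70, abs=0.01)

    def test_zero_force(self):
        assert compute_stress(0.0, 20.0) == 0.0

    def test_area_scaling(self):
        assert compute_stress(1.0, 40.0) == pytest.approx(compute_stress(1.0, 20.0) / 4.0)

    def test_linearity(self):
        F = np.array([0.0, 0.5, 1.0, 2.0])
        s = compute_stress(F, 20.0)
        np.testing.assert_allclose(s, F * s[2], rtol=1e-12)

    def test_bad_diameter_rejected(self):
        with pytest.raises(ValueError):
            compute_stress(1.0, 0.0)


class TestMeasureFrame:
    def _render_single(self, camera, h=10.0, d=20.0, seed=0, noise=0.0):
        spec = TrajectorySpec(lambda t: h, lambda t: d, duration=0.0,
                              camera=camera, image_size=(960, 1280),
                              noise_sigma=noise)
        imgs, truth, _ = render_cylinder_sequence(spec, seed=seed)
        return imgs[0], truth[0]

    def test_telecentric_limit_recovery(self):
        cam = CameraModel(base_scale=40.0, working_distance=1e6)
        img, truth = self._render_single(cam)
        m = measure_frame(img, cam)
        assert m.height_mm == pytest.approx(truth.height_mm, rel=0.005)
        assert m.diameter_mm == pytest.approx(truth.diameter_mm, rel=0.005)

    def test_perspective_corrected_recovery(self, camera):
        img, truth = self._render_single(camera)
        m = measure_frame(img, camera)
        assert m.height_mm == pytest.approx(truth.height_mm, rel=0.005)
        assert abs(m.height_uncorrected_mm - truth.height_mm) > abs(
            m.height_mm - truth.height_mm
        )

    def test_blank_image_rejected(self, camera):
        with pytest.raises(SegmentationError):
            measure_frame(np.full((100, 100), 200, dtype=np.uint8), camera)

    def test_border_touching_rejected(self, camera):
        with pytest.raises(SegmentationError):
            measure_frame(np.zeros((100, 100), dtype=np.uint8) + 10, camera,
                          threshold=128.0)

    def test_noise_tolerant_with_otsu(self, camera):
        img, truth = self._render_single(camera, noise=8.0, seed=3)
        m = measure_frame(img, camera)
        assert m.height_mm == pytest.approx(truth.height_mm, rel=0.01)


class TestProcessSequence:
    def test_constant_geometry_zero_volume_change(self, camera):
        spec = TrajectorySpec(lambda t: 10.0, lambda t: 20.0, duration=3.0,
                              camera=camera, frame_interval=1.0,
                              image_size=(960, 1280))
        imgs, _, times = render_cylinder_sequence(spec)
        rec = process_sequence(imgs, times, camera)
        assert np.allclose(rec.volume_change_mL, 0.0, atol=1e-9)

    def test_incompressible_compression_widens_diameter(self, camera):
        """10% axial strain at constant volume: d scales by (1/0.9)^0.5."""
        h_fn, d_fn = compression_trajectory(10.0, 20.0, strain=0.10,
                                            delta_V_mL=0.0, ramp_time=2.0)
        spec = TrajectorySpec(h_fn, d_fn, duration=4.0, camera=camera,
                              frame_interval=1.0, image_size=(960, 1280))
        imgs, _, times = render_cylinder_sequence(spec)
        rec = process_sequence(imgs, times, camera)
        d0, d1 = rec.frames[0].diameter_mm, rec.frames[-1].diameter_mm
        assert d1 / d0 == pytest.approx((1 / 0.9) ** 0.5, rel=0.005)

    def test_water_release_volume_change(self, camera):
        h_fn, d_fn = compression_trajectory(10.0, 20.0, strain=0.10,
                                            delta_V_mL=0.4, ramp_time=3.0)
        spec = TrajectorySpec(h_fn, d_fn, duration=6.0, camera=camera,
                              frame_interval=1.0, image_size=(960, 1280))
        imgs, truth, times = render_cylinder_sequence(spec, seed=11)
        rec = process_sequence(imgs, times, camera)
        true_dv = truth[-1].volume_mL - truth[0].volume_mL
        assert rec.volume_change_mL[-1] == pytest.approx(true_dv, rel=0.02)

    def test_stress_series_attached(self, camera):
        spec = TrajectorySpec(lambda t: 10.0, lambda t: 20.0, duration=2.0,
                              camera=camera, frame_interval=1.0,
                              image_size=(960, 1280))
        imgs, _, times = render_cylinder_sequence(spec)
        ft = np.linspace(0.0, 2.0, 21)
        rec = process_sequence(imgs, times, camera, forces=0.848 * np.ones(21),
                               force_times=ft)
        d0 = rec.initial_diameter_mm
        assert rec.stress_kPa[0] == pytest.approx(
            0.848 / (math.pi * d0 ** 2 / 4.0) * 1000.0, rel=1e-9
        )

    def test_shadow_zone_frames_flagged_not_deleted(self, camera):
        spec = TrajectorySpec(lambda t: 10.0, lambda t: 20.0, duration=10.0,
                              camera=camera, frame_interval=1.0,
                              image_size=(960, 1280))
        imgs, _, times = render_cylinder_sequence(spec)
        # corrupt one frame: a 'shadow' hides the lower third of the sample
        bad = imgs[5].copy()
        rows = np.flatnonzero((bad < 100).any(axis=1))
        bad[rows[-rows.size // 3:], :] = 230
        imgs[5] = bad
        rec = process_sequence(imgs, times, camera)
        assert rec.flags[5]
        assert len(rec.frames) == len(imgs)
        assert not rec.flags[[0, 1, 2, 3, 4, 6, 7, 8, 9, 10]].any()

    def test_mismatched_inputs_rejected(self, camera):
        with pytest.raises(ValueError):
            process_sequence([], [], camera)
        img = np.full((50, 50), 200, dtype=np.uint8)
        with pytest.raises(ValueError):
            process_sequence([img], [0.0, 1.0], camera)
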