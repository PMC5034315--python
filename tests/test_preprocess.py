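import numpy as np
import pytest

from glowtrack.preprocess import (
    DetectionError,
    GeometryError,
    LayoutSpec,
    align_tray,
    detect_tubes,
    estimate_global_background,
    local_background,
    local_background_rows,
    preprocess_stack,
    rotate_frame,
    rotate_points,
)
from glowtrack.pipeline import simulated_layout
from glowtrack.simulate import SimConfig, render_stack


class TestGlobalBackground:
    def test_uniform_frame(self):
        assert estimate_global_background(np.full((100, 100), 7.0)) == 7.0

    def test_all_zero_frame(self):
        assert estimate_global_background(np.zeros((64, 64))) == 0.0

    def test_known_patch_mean(self):
        rng = np.random.default_rng(0)
        frame = np.zeros((128, 128))
        patch = rng.poisson(20.0, size=(64, 64)).astype(float)
        frame[-64:, -64:] = patch
        assert estimate_global_background(frame) == pytest.approx(
            patch.mean(), abs=1e-12)

    def test_frame_smaller_than_patch_errors(self):
        with pytest.raises(ValueError, match="64"):
            estimate_global_background(np.zeros((32, 32)))


def _marker_frame(markers, shape=(128, 128)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    f = np.zeros(shape)
    for x, y in markers:
        f += 1000.0 * np.exp(-0.5 * (((xx - x) / 1.5) ** 2
                                     + ((yy - y) / 1.5) ** 2))
    return f


class TestAlign:
    MARKERS = [(20.0, 20.0), (100.0, 20.0), (20.0, 90.0)]

    def test_axis_aligned_markers_no_rotation(self):
        f = _marker_frame(self.MARKERS)
        out, rot, _ = align_tray(f, self.MARKERS)
        assert rot == pytest.approx(0.0, abs=0.05)
        np.testing.assert_allclose(out, f, atol=1e-9)

    @pytest.mark.parametrize("deg", [5.0, -3.0])
    def test_recovers_rendered_rotation(self, deg):
        rotated_markers = rotate_points(self.MARKERS, deg, (128, 128))
        f = _marker_frame(rotated_markers)
        approx = [(round(x), round(y)) for x, y in rotated_markers]
        _, rot, markers_out = align_tray(f, approx)
        assert rot == pytest.approx(-deg, abs=0.1)
        for (mx, my), (ox, oy) in zip(markers_out, self.MARKERS):
            assert (mx, my) == pytest.approx((ox, oy), abs=0.3)

    def test_marker_order_invariance(self):
        rotated = rotate_points(self.MARKERS, 4.0, (128, 128))
        f = _marker_frame(rotated)
        rots = []
        for order in [(0, 1, 2), (2, 0, 1), (1, 2, 0)]:
            _, rot, _ = align_tray(f, [rotated[i] for i in order])
            rots.append(rot)
        assert max(rots) - min(rots) < 1e-6

    def test_collinear_markers_rejected(self):
        f = np.zeros((64, 64))
        with pytest.raises(GeometryError, match="collinear"):
            align_tray(f, [(10, 10), (20, 20), (30, 30)], refine=False)

    def test_duplicate_markers_rejected(self):
        f = np.zeros((64, 64))
        with pytest.raises(GeometryError):
            align_tray(f, [(10, 10), (10, 10), (30, 20)], refine=False)

    def test_two_markers_rejected(self):
        with pytest.raises(GeometryError, match="three"):
            align_tray(np.zeros((64, 64)), [(1, 1), (50, 1)], refine=False)


class TestDetectTubes:
    def test_simulated_tray_centres_within_one_pixel(self, control_stack,
                                                     control_pipeline):
        _, _, geom = control_pipeline
        for det, true in zip(geom.tube_rects, control_stack.geometry.tube_rects):
            det_c = (det.x_min + det.x_max) / 2
            true_c = (true.x_min + true.x_max) / 2
            assert abs(det_c - true_c) <= 1.0
            assert abs(det.y_min - true.y_min) <= 2.0

    def test_every_rectangle_is_17_px_wide(self, control_pipeline):
        _, _, geom = control_pipeline
        assert all(t.x_max - t.x_min + 1 == 17 for t in geom.tube_rects)

    def test_blank_frame_raises_detection_error(self):
        with pytest.raises(DetectionError):
            detect_tubes(np.zeros((256, 256)),
                         LayoutSpec(n_columns=4, n_rows=1))

    def test_wrong_column_count_reports_peaks(self, control_stack):
        stack = control_stack.stack[:12].astype(float)
        ref = stack.mean(axis=0) - estimate_global_background(stack.mean(axis=0))
        with pytest.raises(DetectionError, match="column peaks"):
            detect_tubes(ref, LayoutSpec(n_columns=5, n_rows=1),
                         exclude_points=control_stack.markers_in_frame)

    def test_geometry_stable_between_early_and_late_reference(self,
                                                              control_stack):
        layout = simulated_layout(control_stack.config)
        spans = []
        for sl in (slice(0, 144), slice(-144, None)):
            sub = control_stack.stack[sl].astype(float)
            ref = sub.mean(axis=0)
            ref -= estimate_global_background(ref)
            geom = detect_tubes(ref, layout,
                                exclude_points=control_stack.markers_in_frame)
            spans.append(geom)
        a, b = spans
        for ta, tb in zip(a.tube_rects, b.tube_rects):
            assert abs(ta.x_min - tb.x_min) <= 1
            assert abs(ta.y_min - tb.y_min) <= 1


class TestLocalBackground:
    def test_flat_frame_returns_value(self, control_pipeline):
        _, _, geom = control_pipeline
        frame = np.full((256, 480), 3.0)
        assert local_background(frame, 0, geom) == pytest.approx(3.0)

    def test_bg_rect_outside_frame_errors(self, control_pipeline):
        _, _, geom = control_pipeline
        with pytest.raises(ValueError, match="outside"):
            local_background(np.zeros((40, 40)), 0, geom)

    def test_tracks_smooth_vignette_field(self, control_pipeline):
        # render the simulator's background model alone and compare the
        # estimate with the field value at the bg_rect centre
        _, _, geom = control_pipeline
        h, w = 256, 480
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((yy - h / 2) ** 2 + (xx - w / 2) ** 2) / ((h / 2) ** 2 + (w / 2) ** 2)
        field = 5.0 * (1.0 - 0.3 * r2)
        for tube_id in (0, 5, 11):
            rect = geom.bg_rects[tube_id]
            cx = (rect.x_min + rect.x_max) / 2
            cy = (rect.y_min + rect.y_max) / 2
            true_val = 5.0 * (1.0 - 0.3 * (
                ((cy - h / 2) ** 2 + (cx - w / 2) ** 2)
                / ((h / 2) ** 2 + (w / 2) ** 2)))
            est = local_background(field, tube_id, geom)
            assert est == pytest.approx(true_val, rel=0.05)

    def test_row_profile_removes_along_tube_gradient(self, control_pipeline):
        _, _, geom = control_pipeline
        h, w = 256, 480
        grad = np.tile(np.linspace(0.0, 10.0, h)[:, None], (1, w))
        rows = local_background_rows(grad, 0, geom, smooth_sigma_px=2.0)
        tube = geom.tube_rects[0]
        expected = grad[tube.y_min:tube.y_max + 1, 0]
        np.testing.assert_allclose(rows, expected, atol=0.2)


class TestPreprocessStack:
    def test_alignment_idempotent_on_aligned_stack(self, control_stack):
        frame = control_stack.stack[0].astype(float)
        out, rot, _ = align_tray(frame, control_stack.markers_in_frame)
        assert abs(rot) < 0.2
        if rot == 0.0:
            np.testing.assert_array_equal(out, frame)
        else:
            # interpolation tolerance only
            assert np.median(np.abs(out - frame)) < 2.0

    def test_rotated_stack_recovered(self):
        cfg = SimConfig(n_days=0.05, image_size=(256, 200), n_columns=4,
                        n_rows=1, col_pitch_px=36, rotation_deg=5.0, seed=6)
        rs = render_stack(cfg)
        approx = [(round(x), round(y)) for x, y in rs.markers_in_frame]
        pre, geom = preprocess_stack(rs.stack, approx, simulated_layout(cfg))
        assert geom.rotation_deg == pytest.approx(-5.0, abs=0.1)
        for det, true in zip(geom.tube_rects, rs.geometry.tube_rects):
            assert abs((det.x_min + det.x_max) / 2
                       - (true.x_min + true.x_max) / 2) <= 1.5
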