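import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from glowtrack.geometry import N_BINS
from glowtrack.quantify import (
    QUALITY_NEGATIVE_MEAN,
    QUALITY_OK,
    QUALITY_TOO_DIM,
    PeakSet,
    TubeProfile,
    detect_rest_peaks,
    enhance_contrast,
    interpolate_bad_frames,
    partition_frame_time,
    profile_tube,
    tube_bioluminescence,
)


def profile_from(bin_sum):
    bin_sum = np.asarray(bin_sum, dtype=float)
    return TubeProfile(bin_sum=bin_sum, bin_max=bin_sum / 68.0)


class TestEnhance:
    def test_identity_on_full_range_without_percentile_clip(self):
        v = np.linspace(0, 65535, 1000)
        out = enhance_contrast(v, p_low=0.0, p_high=100.0)
        np.testing.assert_allclose(out, v, atol=1e-6)

    @given(hnp.arrays(np.float64, 300,
                      elements=st.floats(0, 1e4, allow_nan=False)))
    def test_monotone_rank_preservation(self, v):
        out = enhance_contrast(v)
        order = np.argsort(v)  # increasing input pairs must not invert
        assert np.all(np.diff(out[order]) >= -1e-9)

    def test_positive_affine_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.random(500) * 100.0
        a, b = 3.0, 40.0
        np.testing.assert_allclose(
            enhance_contrast(v), enhance_contrast(a * v + b), atol=1e-6)

    def test_constant_frame_no_op(self):
        v = np.full(100, 42.0)
        np.testing.assert_array_equal(enhance_contrast(v), v)


class TestProfile:
    def test_uniform_tube(self, control_pipeline):
        _, _, geom = control_pipeline
        frame = np.full((256, 480), 5.0)
        prof = profile_tube(frame, 0, geom, local_bg=0.0)
        np.testing.assert_allclose(prof.bin_sum, 17 * 4 * 5.0)
        assert prof.tube_sd == 0.0
        assert len(prof.bin_sum) == N_BINS == 46

    def test_single_bright_pixel_hits_one_bin_max(self, control_pipeline):
        _, _, geom = control_pipeline
        frame = np.zeros((256, 480))
        tube = geom.tube_rects[0]
        frame[tube.y_min + 30, tube.x_min + 4] = 123.0
        prof = profile_tube(frame, 0, geom, local_bg=0.0)
        assert np.count_nonzero(prof.bin_max == 123.0) == 1

    def test_short_tube_errors(self, control_pipeline):
        from dataclasses import replace

        _, _, geom = control_pipeline
        import copy

        bad = copy.deepcopy(geom)
        t = bad.tube_rects[0]
        bad.tube_rects[0] = replace(t, y_max=t.y_min + 99)
        with pytest.raises(ValueError, match="shorter"):
            profile_tube(np.zeros((256, 480)), 0, bad, local_bg=0.0)


class TestPeaks:
    def test_flat_profile_has_no_peaks(self):
        assert len(detect_rest_peaks(profile_from(np.full(46, 10.0)))) == 0

    def test_single_bright_bin(self):
        s = np.full(46, 10.0)
        s[17] = 1000.0
        ps = detect_rest_peaks(profile_from(s))
        assert len(ps) == 1
        assert ps.peaks[0].start_bin == ps.peaks[0].end_bin == 17
        assert ps.peaks[0].anchor_bin == pytest.approx(17.0)

    def test_two_separated_bins_two_peaks_adjacent_merge(self):
        s = np.full(46, 10.0)
        s[[10, 12]] = 1000.0  # one sub-threshold bin between
        assert len(detect_rest_peaks(profile_from(s))) == 2
        s2 = np.full(46, 10.0)
        s2[[10, 11]] = 1000.0  # adjacent: merged
        ps = detect_rest_peaks(profile_from(s2))
        assert len(ps) == 1
        assert (ps.peaks[0].start_bin, ps.peaks[0].end_bin) == (10, 11)
        assert ps.peaks[0].anchor_bin == pytest.approx(10.5)

    def test_threshold_is_mean_plus_sd(self):
        s = np.full(46, 10.0)
        s[5] = 100.0
        prof = profile_from(s)
        thr = prof.tube_mean + prof.tube_sd
        flagged = s > thr
        ps = detect_rest_peaks(prof)
        assert set(ps.bins().tolist()) == set(np.flatnonzero(flagged).tolist())


class TestPartition:
    def test_no_peaks_means_fully_active(self):
        p = partition_frame_time(profile_from(np.full(46, 10.0)), PeakSet())
        assert p.time_active_s == 300.0
        assert p.time_rest_s == 0.0
        assert p.quality_flag == QUALITY_OK

    def test_immobile_fly_dark_elsewhere_fully_resting(self):
        s = np.zeros(46)
        s[20] = 900.0
        ps = detect_rest_peaks(profile_from(s))
        p = partition_frame_time(profile_from(s), ps)
        assert p.time_rest_s == pytest.approx(300.0)

    def test_equal_areas_split_evenly(self):
        # active rectangle: mean_without_peaks * 46; choose a peak whose
        # excess area equals it exactly
        s = np.full(46, 10.0)
        s[8] = 10.0 + 46 * 10.0  # excess over mean-without-peaks = 460
        ps = PeakSet()
        from glowtrack.quantify import Peak

        ps.peaks.append(Peak(start_bin=8, end_bin=8, anchor_bin=8.0,
                             area=s[8]))
        p = partition_frame_time(profile_from(s), ps)
        assert p.time_active_s == pytest.approx(150.0)
        assert p.time_rest_s == pytest.approx(150.0)

    def test_negative_mean_flagged(self):
        p = partition_frame_time(profile_from(np.full(46, -5.0)), PeakSet())
        assert p.quality_flag == QUALITY_NEGATIVE_MEAN

    def test_all_zero_profile_too_dim(self):
        p = partition_frame_time(profile_from(np.zeros(46)), PeakSet())
        assert p.quality_flag == QUALITY_TOO_DIM

    @given(hnp.arrays(np.float64, 46, elements=st.floats(0.1, 1e4)))
    def test_time_conservation_property(self, s):
        prof = profile_from(s)
        p = partition_frame_time(prof, detect_rest_peaks(prof))
        if p.quality_flag == QUALITY_OK:
            assert p.time_active_s + p.time_rest_s == pytest.approx(300.0,
                                                                    abs=1e-9)
            assert p.time_active_s >= 0.0 and p.time_rest_s >= 0.0


class TestBioluminescence:
    def test_all_zero_tube(self, control_pipeline):
        _, _, geom = control_pipeline
        assert tube_bioluminescence(np.zeros((256, 480)), 0, geom,
                                    local_bg=0.0) == 0.0

    def test_additive_offset_removed_by_local_background(self,
                                                         control_pipeline):
        _, _, geom = control_pipeline
        rng = np.random.default_rng(3)
        frame = rng.random((256, 480)) * 10.0
        base = tube_bioluminescence(frame, 2, geom)
        shifted = tube_bioluminescence(frame + 7.0, 2, geom)
        assert shifted == pytest.approx(base, abs=1e-6 * abs(base) + 1e-6)

    def test_recovers_photon_rate_on_noise_free_stack(self,
                                                      small_noise_free_stack):
        rs = small_noise_free_stack
        truth = rs.truths[0]
        geom = rs.geometry
        for f in range(truth.n_frames):
            got = tube_bioluminescence(rs.stack[f], 0, geom, local_bg=0.0)
            assert got == pytest.approx(truth.photon_rate[f] * 300.0, rel=0.01)


class TestInterpolation:
    def test_single_bad_frame_midpoint(self):
        out = interpolate_bad_frames([100.0, -1.0, 200.0],
                                     ["ok", "negative_mean", "ok"])
        assert out[1] == pytest.approx(150.0)

    def test_no_bad_frames_unchanged(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(
            interpolate_bad_frames(v, ["ok"] * 3), v)

    def test_run_of_three_bad_frames_linear(self):
        out = interpolate_bad_frames(
            [0.0, 9.0, 9.0, 9.0, 400.0],
            ["ok", "too_dim", "too_dim", "too_dim", "ok"])
        np.testing.assert_allclose(out, [0.0, 100.0, 200.0, 300.0, 400.0])

    def test_leading_and_trailing_bad_take_nearest(self):
        out = interpolate_bad_frames(
            [9.0, 50.0, 9.0], ["too_dim", "ok", "too_dim"])
        np.testing.assert_allclose(out, [50.0, 50.0, 50.0])

    def test_all_bad_errors(self):
        with pytest.raises(ValueError, match="every frame"):
            interpolate_bad_frames([1.0, 2.0], ["too_dim", "negative_mean"])
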