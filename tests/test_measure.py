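"""Principal axis, ellipse fitting, node peaks, ROI and diameter recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import optimize, signal

from stalkmetric.cloud import LabeledPointCloud
from stalkmetric.measure import (EllipseFit, MeasurementError, NodeDetectionError,
                                 SliceProfile, detect_node_peaks,
                                 extract_second_internode, fit_ellipse, measure_stem,
                                 measure_stem_diameter, principal_axis, scale_to_mm,
                                 slice_profiles)
from stalkmetric.synthetic import SyntheticStemConfig, generate_stem_scene


def ellipse_points(a, b, n=100, angle=0.0, center=(0.0, 0.0), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    if noise:
        pts += rng.normal(0, noise, pts.shape)
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return pts @ rot.T + center


class TestPrincipalAxis:
    def test_collinear_points(self):
        cloud = LabeledPointCloud([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        frame = principal_axis(cloud)
        np.testing.assert_allclose(np.abs(frame.v1), [0, 0, 1], atol=1e-12)

    def test_tilted_cylinder_axis_recovered(self, rng):
        tilt = np.deg2rad(10.0)
        axis = np.array([np.sin(tilt), np.cos(tilt), 0.0])
        e1 = np.array([np.cos(tilt), -np.sin(tilt), 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        t = rng.uniform(0, 400, 5000)
        th = rng.uniform(0, 2 * np.pi, 5000)
        pts = t[:, None] * axis + 15 * np.cos(th)[:, None] * e1 + 15 * np.sin(th)[:, None] * e2
        frame = principal_axis(LabeledPointCloud(pts))
        assert abs(frame.v1 @ axis) > 0.9998

    def test_isotropic_blob_flags_degenerate(self, rng):
        cloud = LabeledPointCloud(rng.normal(size=(500, 3)))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            frame = principal_axis(cloud)
        assert frame.degenerate

    def test_ground_reference_orients_axis_upward(self, rng):
        pts = np.column_stack([rng.normal(0, 1, 200), rng.uniform(0, 100, 200),
                               rng.normal(0, 1, 200)])
        frame = principal_axis(LabeledPointCloud(pts), ground_reference=[0, -50, 0])
        assert frame.v1[1] > 0
        flipped = principal_axis(LabeledPointCloud(pts), ground_reference=[0, 500, 0])
        assert flipped.v1[1] < 0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            principal_axis(LabeledPointCloud([[0, 0, 0], [1, 1, 1]]))


class TestFitEllipse:
    def test_exact_recovery(self):
        fit = fit_ellipse(ellipse_points(5, 3))
        assert fit.major_axis_len == pytest.approx(10.0, abs=1e-6)
        assert fit.minor_axis_len == pytest.approx(6.0, abs=1e-6)

    def test_rigid_motion_invariance(self):
        fit = fit_ellipse(ellipse_points(5, 3, angle=np.deg2rad(30), center=(7, -2)))
        assert fit.major_axis_len == pytest.approx(10.0, abs=1e-6)
        assert fit.minor_axis_len == pytest.approx(6.0, abs=1e-6)
        assert fit.center == pytest.approx([7, -2], abs=1e-6)

    def test_circle(self):
        fit = fit_ellipse(ellipse_points(2, 2, n=50))
        assert fit.major_axis_len == pytest.approx(4.0, abs=1e-6)
        assert fit.minor_axis_len == pytest.approx(4.0, abs=1e-6)

    def test_orientation_in_range_and_a_ge_b(self):
        for ang in np.linspace(0, np.pi, 7):
            fit = fit_ellipse(ellipse_points(4, 2, angle=ang, seed=3))
            assert 0 <= fit.orientation < np.pi
            assert fit.semi_major >= fit.semi_minor > 0

    def test_noisy_fit_matches_geometric_least_squares(self):
        """Algebraic fit vs brute-force geometric (orthogonal-distance) fit."""
        pts = ellipse_points(5, 3, n=200, angle=0.4, center=(1, 2), noise=0.15, seed=5)
        fit = fit_ellipse(pts)

        def residuals(p):
            cx, cy, a, b, th = p
            rot = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
            q = (pts - [cx, cy]) @ rot.T
            phi = np.arctan2(q[:, 1] / b, q[:, 0] / a)
            return np.hypot(q[:, 0] - a * np.cos(phi), q[:, 1] - b * np.sin(phi))

        res = optimize.least_squares(residuals, x0=[1, 2, 5, 3, 0.4])
        a_geo, b_geo = sorted(abs(res.x[2:4]), reverse=True)
        assert fit.major_axis_len == pytest.approx(2 * a_geo, rel=0.01)
        assert fit.minor_axis_len == pytest.approx(2 * b_geo, rel=0.01)

    def test_matches_reference_conic_fitter(self):
        """Cross-check against an independent direct least-squares fitter."""
        from skimage.measure import EllipseModel

        pts = ellipse_points(6, 2.5, n=80, angle=1.0, center=(-3, 4), noise=0.05, seed=9)
        fit = fit_ellipse(pts)
        model = EllipseModel.from_estimate(pts)
        a_ref, b_ref = sorted(model.axis_lengths, reverse=True)
        assert fit.semi_major == pytest.approx(a_ref, rel=1e-3)
        assert fit.semi_minor == pytest.approx(b_ref, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ellipse(ellipse_points(3, 2, n=5))

    def test_collinear_points_fail(self):
        pts = np.column_stack([np.linspace(0, 1, 20), np.linspace(0, 2, 20)])
        with pytest.raises(MeasurementError):
            fit_ellipse(pts)


def make_profiles(values, slice_width=10.0, valid=None):
    profiles = []
    for i, v in enumerate(values):
        is_valid = True if valid is None else valid[i]
        ell = EllipseFit(center=np.zeros(2), semi_major=v / 2, semi_minor=v / 4,
                         orientation=0.0, rms_residual=0.0) if is_valid else None
        profiles.append(SliceProfile(index=i, t_lo=i * slice_width,
                                     t_hi=(i + 1) * slice_width,
                                     n_points=100 if is_valid else 0,
                                     ellipse=ell, valid=is_valid))
    return profiles


class TestNodePeaks:
    def test_two_clear_peaks(self):
        seq = [4, 4, 5, 8, 5, 4, 4, 5, 9, 5, 4, 4, 4, 4, 4]
        assert detect_node_peaks(make_profiles(seq)) == [3, 8]

    def test_monotone_sequence_fails(self):
        with pytest.raises(NodeDetectionError, match="fewer than two"):
            detect_node_peaks(make_profiles(list(range(4, 19))))

    def test_plateau_reports_first_index(self):
        seq = [4, 6, 6, 4, 4, 7, 4, 4]
        peaks = detect_node_peaks(make_profiles(seq))
        assert peaks[0] == 1

    def test_invalid_slices_are_skipped_but_indices_preserved(self):
        seq = [4, 4, 8, 4, 0, 4, 9, 4, 4]
        valid = [True, True, True, True, False, True, True, True, True]
        assert detect_node_peaks(make_profiles(seq, valid=valid)) == [2, 6]

    def test_small_bumps_below_prominence_are_ignored(self):
        seq = [4.0, 4.05, 4.0, 8.0, 4.0, 4.05, 4.0, 9.0, 4.0, 4.0]
        assert detect_node_peaks(make_profiles(seq)) == [3, 7]

    def test_agrees_with_scipy_prominence_oracle(self, rng):
        """Random plateau-free sequences: same peaks as scipy's find_peaks."""
        for _ in range(300):
            seq = rng.uniform(10, 20, 15)
            threshold = 0.05 * np.median(seq)
            expect, _ = signal.find_peaks(seq, prominence=threshold)
            try:
                got = detect_node_peaks(make_profiles(seq))
            except NodeDetectionError as err:
                got = [] if err.sequence is None else \
                    [i for i in range(len(seq)) if False]
                assert len(expect) < 2
                continue
            assert got == expect.tolist()


class TestROIAndDiameter:
    def test_roi_lies_between_the_first_two_nodes(self, clean_scene):
        cloud, truth = clean_scene
        stem = cloud.select(cloud.labels == 1)
        bg = cloud.coords[cloud.labels == 0].mean(axis=0)
        frame = principal_axis(stem, ground_reference=bg)
        profiles = slice_profiles(stem, frame)
        peaks = detect_node_peaks(profiles)
        roi = extract_second_internode(stem, frame, profiles, peaks)
        heights = roi.coords @ truth.axis_direction
        lo, hi = truth.node_heights[0], truth.node_heights[1]
        assert heights.min() > lo - 0.5
        assert heights.max() < hi + 0.5
        # covers >= 80% of the internode (1 mm slack: points sample the
        # open interval, so the extremes sit just inside the slice edges)
        assert (heights.max() - heights.min()) >= 0.8 * (hi - lo) - 1.0
        assert np.all(roi.labels == 1)

    def test_adjacent_peaks_give_empty_roi(self, clean_scene):
        cloud, _ = clean_scene
        stem = cloud.select(cloud.labels == 1)
        frame = principal_axis(stem)
        profiles = slice_profiles(stem, frame)
        with pytest.raises(MeasurementError, match="empty"):
            extract_second_internode(stem, frame, profiles, [4, 5])

    def test_default_sections_count_and_single_section(self, clean_scene):
        cloud, _ = clean_scene
        stem = cloud.select(cloud.labels == 1)
        frame = principal_axis(stem)
        profiles = slice_profiles(stem, frame)
        peaks = detect_node_peaks(profiles)
        roi = extract_second_internode(stem, frame, profiles, peaks)
        meas = measure_stem_diameter(roi, frame)
        assert len(meas.per_section) == 3
        one = measure_stem_diameter(roi, frame, n_sections=1)
        assert one.major_units == pytest.approx(one.per_section[0].major_axis_len)

    def test_gap_band_invalidates_only_that_slice(self, rng):
        t = rng.uniform(0, 150, 8000)
        keep = ~((t > 60) & (t < 70))         # one empty band
        t = t[keep]
        th = rng.uniform(0, 2 * np.pi, t.size)
        pts = np.column_stack([10 * np.cos(th), t, 8 * np.sin(th)])
        frame = principal_axis(LabeledPointCloud(pts))
        profiles = slice_profiles(LabeledPointCloud(pts), frame)
        invalid = [p.index for p in profiles if not p.valid]
        assert len(invalid) == 1
        assert sum(p.valid for p in profiles) == 14

    def test_uniform_cylinder_slices_agree(self, rng):
        t = rng.uniform(0, 150, 20000)
        th = rng.uniform(0, 2 * np.pi, t.size)
        pts = np.column_stack([10 * np.cos(th), t, 6 * np.sin(th)])
        frame = principal_axis(LabeledPointCloud(pts))
        profiles = slice_profiles(LabeledPointCloud(pts), frame)
        majors = [p.ellipse.major_axis_len for p in profiles if p.valid]
        assert np.ptp(majors) / np.mean(majors) < 0.005


class TestScaleConversion:
    def test_plate_span_maps_to_45mm(self):
        assert scale_to_mm(12.34, 12.34) == pytest.approx(45.0)

    def test_linear_in_length(self):
        assert scale_to_mm(6.0, 12.0) == pytest.approx(22.5)
        assert scale_to_mm(0.0, 5.0) == 0.0

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            scale_to_mm(1.0, 0.0)
        with pytest.raises(ValueError):
            scale_to_mm(-1.0, 2.0)


class TestEndToEnd:
    def test_noiseless_recovery_within_one_percent(self, clean_scene):
        cloud, truth = clean_scene
        meas, frame, profiles, peaks = measure_stem(
            cloud, q_units=truth.checkerboard_span_units)
        assert len(profiles) == 15
        assert meas.major_mm == pytest.approx(truth.true_major_mm, rel=0.01)
        assert meas.minor_mm == pytest.approx(truth.true_minor_mm, rel=0.01)
        assert meas.major_mm >= meas.minor_mm

    def test_rigid_motion_changes_nothing(self, clean_scene):
        cloud, truth = clean_scene
        ang = np.deg2rad(33.0)
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        ang2 = np.deg2rad(15.0)
        rot2 = np.array([[1, 0, 0], [0, np.cos(ang2), -np.sin(ang2)],
                         [0, np.sin(ang2), np.cos(ang2)]])
        moved = cloud.transformed(rot2 @ rot, np.array([120.0, -40.0, 77.0]))
        m1, *_ = measure_stem(cloud, q_units=truth.checkerboard_span_units)
        m2, *_ = measure_stem(moved, q_units=truth.checkerboard_span_units)
        assert m2.major_mm == pytest.approx(m1.major_mm, rel=1e-3)
        assert m2.minor_mm == pytest.approx(m1.minor_mm, rel=1e-3)

    def test_unlabeled_cloud_rejected(self, rng):
        with pytest.raises(ValueError):
            measure_stem(LabeledPointCloud(rng.normal(size=(10, 3))))
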