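"""Per-particle statistics, contacts and per-cell summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_track, truth_to_track
from punctatrack.kinematics import (
    ContactConfig,
    bb_contacts,
    compute_track_metrics,
    directionality,
    displacement,
    max_speed,
    mean_area,
    rotate_to_cell_axis,
    summarize_pr,
    trajectory_length,
)
from punctatrack.synthetic import MotionConfig, make_geometry, simulate_tracks

walks = st.integers(min_value=0, max_value=2**32 - 1).map(
    lambda s: np.random.default_rng(s).normal(0, 2.0, size=(np.random.default_rng(s).integers(2, 30), 2)).cumsum(axis=0)
)


class TestRotation:
    def test_identity_at_zero(self):
        pts = np.array([[1.5, -2.0], [0.0, 3.0]])
        assert np.allclose(rotate_to_cell_axis(pts, 0.0), pts)

    def test_quarter_turn_maps_xy_to_y_minus_x(self):
        out = rotate_to_cell_axis((2.0, 5.0), math.pi / 2)
        assert out == pytest.approx((5.0, -2.0))

    def test_distances_preserved(self, rng):
        pts = rng.uniform(-50, 50, size=(20, 2))
        theta = rng.uniform(-math.pi, math.pi)
        rot = rotate_to_cell_axis(pts, theta)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d1 = np.linalg.norm(rot[:, None] - rot[None, :], axis=2)
        assert np.allclose(d0, d1, rtol=1e-9, atol=1e-9)


class TestDisplacement:
    def test_single_frame_is_zero(self):
        assert displacement(make_track([(3.0, 4.0)])) == 0.0

    def test_three_four_five(self):
        tr = make_track([(0.0, 0.0), (1.0, 1.0), (3.0, 4.0)])
        assert displacement(tr) == pytest.approx(1050.0)  # 5 px * 210 nm

    def test_equals_endpoint_formula(self, rng):
        pts = rng.uniform(0, 30, size=(15, 2))
        tr = make_track(pts)
        expected = math.hypot(*(pts[-1] - pts[0])) * 210.0
        assert displacement(tr) == pytest.approx(expected)


class TestTrajectory:
    def test_single_frame_is_zero(self):
        assert trajectory_length(make_track([(3.0, 4.0)])) == 0.0

    def test_closed_square_loop(self):
        pts = [(0, 0), (2, 0), (2, 2), (0, 2), (0, 0)]
        tr = make_track(pts)
        assert trajectory_length(tr) == pytest.approx(8 * 0.21)  # 1.68 um
        assert displacement(tr) == 0.0

    def test_equals_stepwise_sum(self, rng):
        pts = rng.uniform(0, 30, size=(25, 2))
        tr = make_track(pts)
        expected = sum(
            math.hypot(*(b - a)) for a, b in zip(pts, pts[1:])
        ) * 210.0 / 1000.0
        assert trajectory_length(tr) == pytest.approx(expected)


class TestMaxSpeed:
    def test_uniform_motion(self):
        pts = [(0.0, float(i)) for i in range(5)]
        assert max_speed(make_track(pts), 1.0) == pytest.approx(210.0)

    def test_largest_step_wins(self):
        pts = [(0.0, 0.0), (1.0, 0.0), (6.0, 0.0), (8.0, 0.0)]
        assert max_speed(make_track(pts), 1.0) == pytest.approx(1050.0)

    def test_frame_interval_scales(self):
        pts = [(0.0, 0.0), (1.0, 0.0)]
        assert max_speed(make_track(pts), 2.0) == pytest.approx(105.0)

    def test_single_frame_undefined(self):
        assert max_speed(make_track([(0.0, 0.0)])) is None

    def test_equals_bruteforce_max(self, rng):
        pts = rng.uniform(0, 30, size=(40, 2))
        expected = max(math.hypot(*(b - a)) for a, b in zip(pts, pts[1:])) * 210.0
        assert max_speed(make_track(pts), 1.0) == pytest.approx(expected)


class TestDirectionality:
    def test_pure_axial_motion_is_zero(self):
        pts = [(5.0, float(i)) for i in range(10)]
        assert directionality(make_track(pts), 0.0) == 0.0

    def test_equal_spans_is_one(self):
        pts = [(0.0, 0.0), (3.0, 3.0)]
        assert directionality(make_track(pts), 0.0) == pytest.approx(1.0)

    def test_zero_axial_span_undefined(self):
        pts = [(0.0, 2.0), (5.0, 2.0)]
        assert directionality(make_track(pts), 0.0) is None

    def test_translation_invariant(self, rng):
        pts = rng.uniform(0, 10, size=(12, 2))
        a = directionality(make_track(pts), 0.7)
        b = directionality(make_track(pts + [100.0, -40.0]), 0.7)
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("theta", [-1.2, -0.4, 0.3, 1.0, 2.1])
    def test_rotation_equivariance(self, theta, rng):
        """Rotating the track and theta together leaves the ratio unchanged."""
        pts = rng.uniform(0, 10, size=(15, 2))
        base = directionality(make_track(pts), 0.0)
        rotated_pts = rotate_to_cell_axis(pts, -theta)  # place track in a cell tilted by theta
        rotated = directionality(make_track(rotated_pts), theta)
        assert rotated == pytest.approx(base, abs=1e-9)


class TestMeanArea:
    def test_ten_pixels_is_044(self):
        tr = make_track(np.zeros((4, 2)), pixel_counts=[10, 10, 10, 10])
        assert mean_area(tr, 210.0) == pytest.approx(0.441)
        assert round(mean_area(tr, 210.0), 2) == 0.44

    def test_one_pixel(self):
        tr = make_track(np.zeros((2, 2)), pixel_counts=[1, 1])
        assert mean_area(tr, 210.0) == pytest.approx(0.0441)

    def test_mean_of_two_and_four(self):
        tr = make_track(np.zeros((2, 2)), pixel_counts=[2, 4])
        assert mean_area(tr, 210.0) == pytest.approx(0.1323)


class TestContacts:
    def _geometry(self):
        return make_geometry(0.0, cell_length_px=40, cell_width_px=14)

    def test_boundary_inclusive(self):
        g = self._geometry()
        bx, by = g.bb_position
        tr = make_track([(bx + 3.0, by)])
        contacted, n = bb_contacts(tr, g, ContactConfig())
        assert contacted and n == 1

    def test_beyond_radius_no_contact(self):
        g = self._geometry()
        bx, by = g.bb_position
        tr = make_track([(bx + 4.0, by), (bx, by + 5.0)])
        contacted, n = bb_contacts(tr, g, ContactConfig())
        assert not contacted and n == 0

    def test_equals_per_frame_distance_oracle(self, rng):
        g = self._geometry()
        pts = rng.uniform(0, 20, size=(50, 2))
        tr = make_track(pts)
        contacted, n = bb_contacts(tr, g, ContactConfig())
        expected = sum(
            1 for x, y in pts
            if math.hypot(x - g.bb_position[0], y - g.bb_position[1]) <= 3.0
        )
        assert n == expected
        assert contacted == (expected >= 1)

    def test_radius_nm_derivation(self):
        assert ContactConfig(radius_px=3, pixel_size_nm=210).radius_nm == 630.0


class TestSummaries:
    def _metrics(self, geometry, tracks):
        return [compute_track_metrics(tr, geometry) for tr in tracks]

    def test_single_track_summary_echoes_metrics(self):
        g = make_geometry(0.0)
        tr = make_track([(2.0, 2.0), (3.0, 5.0), (4.0, 9.0)] * 4)
        [m] = self._metrics(g, [tr])
        s = summarize_pr([m], "PR0", "wt")
        assert s.n_tracks == 1
        assert s.mean_displacement_nm == pytest.approx(m.displacement_nm)
        assert s.contact_proportion in (0.0, 1.0)

    def test_mean_of_two_displacements(self):
        g = make_geometry(0.0)
        # purely axial runs of 800 and 1000 nm
        t1 = make_track([(5.0, 2.0), (5.0, 2.0 + 800 / 210)])
        t2 = make_track([(5.0, 2.0), (5.0, 2.0 + 1000 / 210)])
        s = summarize_pr(self._metrics(g, [t1, t2]), "PR0")
        assert s.mean_displacement_nm == pytest.approx(900.0)

    def test_grand_mean_is_two_level_average(self, rng):
        g = make_geometry(0.0)
        per_pr_means = []
        all_summaries = []
        for i in range(13):
            tracks = [make_track(rng.uniform(2, 12, size=(11, 2)), track_id=j)
                      for j in range(int(rng.integers(2, 6)))]
            metrics = self._metrics(g, tracks)
            per_pr_means.append(np.mean([m.displacement_nm for m in metrics]))
            all_summaries.append(summarize_pr(metrics, f"PR{i}"))
        grand = np.mean([s.mean_displacement_nm for s in all_summaries])
        assert grand == pytest.approx(np.mean(per_pr_means))

    def test_zero_tracks_flagged(self):
        s = summarize_pr([], "PR0", "wt")
        assert s.n_tracks == 0
        assert math.isnan(s.mean_displacement_nm)

    def test_undefined_directionality_excluded(self):
        g = make_geometry(0.0)
        ok = make_track([(2.0, 2.0), (3.0, 6.0)])
        flat = make_track([(2.0, 3.0), (6.0, 3.0)])  # zero axial span
        s = summarize_pr(self._metrics(g, [ok, flat]), "PR0")
        assert s.n_tracks == 2
        assert s.n_undefined_directionality == 1
        assert s.mean_directionality == pytest.approx(
            directionality(ok, 0.0)
        )


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_triangle_and_speed_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        pts = rng.normal(0, 3.0, size=(n, 2)).cumsum(axis=0)
        tr = make_track(pts)
        d = displacement(tr)
        traj_nm = trajectory_length(tr) * 1000.0
        assert d <= traj_nm + 1e-6
        v = max_speed(tr, 1.0)
        assert v * (n - 1) * 1.0 >= d - 1e-6

    def test_trajectory_estimator_recovers_rayleigh_mean(self):
        """Unconfined isotropic walks: mean trajectory -> 599 * sigma * sqrt(pi/2)."""
        sigma = 50.0
        g = make_geometry(0.0, cell_length_px=200, cell_width_px=120)
        cfg = MotionConfig(n_particles=20, sigma_axial_nm=sigma, sigma_lateral_nm=sigma,
                           bb_excursion_prob=0, mean_lifetime_frames=1e9,
                           birth_rate_per_frame=0, seed=77)
        truth = simulate_tracks(cfg, g, 600)
        trajs = np.array([
            trajectory_length(truth_to_track(t)) for t in truth
        ])
        expected = 599 * sigma * math.sqrt(math.pi / 2) / 1000.0
        se = trajs.std(ddof=1) / math.sqrt(len(trajs))
        assert abs(trajs.mean() - expected) < 3 * se
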