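"""Tests for the trajectory and intensity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moundsim import (
    ModelParameters,
    Track,
    TrajectorySet,
    classify_by_intensity,
    decompose_velocity,
    generate_rotation_frame,
    linear_fit,
    migration_speed,
    pearson_correlation,
    rotational_order,
    sorting_index,
    speed_vs_radius_profile,
    standardize_intensities,
)
from moundsim.analysis import analyze_tracks, read_tracks
from moundsim.fixtures import FixtureSpec, generate_tracks, write_tracks_csv
from conftest import rotate


def make_track(points, interval=1.0, **kw):
    return Track(cell_id=0, positions=np.asarray(points, dtype=float),
                 sampling_interval=interval, **kw)


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        z = standardize_intensities([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0)
        assert z.std() == pytest.approx(1.0)

    def test_sample_mean_maps_to_zero(self):
        z = standardize_intensities([4.0, 6.0, 8.0])
        assert z[1] == pytest.approx(0.0)

    def test_population_sd_convention(self):
        # population sd of [10, 20] is 5, so the scaled values are ±1
        np.testing.assert_allclose(standardize_intensities([10.0, 20.0]),
                                   [-1.0, 1.0])

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError):
            standardize_intensities([5.0, 5.0, 5.0])


class TestClassification:
    @pytest.mark.parametrize("z, label", [
        (0.6, "rich"), (-0.6, "poor"), (0.0, "unclassified"),
        (0.5, "unclassified"), (-0.5, "unclassified"), (2.3, "rich"),
    ])
    def test_thresholds(self, z, label):
        assert classify_by_intensity(z) == label

    @given(st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_partition(self, z):
        assert classify_by_intensity(z) in {"rich", "poor", "unclassified"}


class TestMigrationSpeed:
    def test_straight_track(self):
        pts = np.column_stack([np.arange(31) * 5.0, np.zeros(31)])
        assert migration_speed(make_track(pts)) == pytest.approx(5.0)

    def test_stationary_track(self):
        assert migration_speed(make_track([(1, 1), (1, 1), (1, 1)])) == 0.0

    def test_hand_value(self):
        # displacements 5 then 0 over two 1-min intervals
        assert migration_speed(make_track([(0, 0), (3, 4), (3, 4)])) == 2.5

    def test_respects_sampling_interval(self):
        track = make_track([(0, 0), (6, 0)], interval=2.0)
        assert migration_speed(track) == pytest.approx(3.0)

    @given(theta=st.floats(0, 2 * np.pi), dx=st.floats(-50, 50),
           dy=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, theta, dx, dy):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-10, 10, size=(8, 2))
        moved = rotate(pts, theta) + np.array([dx, dy])
        assert migration_speed(make_track(moved)) == pytest.approx(
            migration_speed(make_track(pts)), rel=1e-9)


class TestDecomposeVelocity:
    @pytest.mark.parametrize("track, expected_c, expected_t", [
        ([(100, 0), (99, 0)], 1.0, 0.0),    # pure inward motion
        ([(100, 0), (100, 1)], 0.0, 1.0),   # pure tangential motion
        ([(100, 0), (99, 1)], 1.0, 1.0),    # mixed, projected at interval start
    ])
    def test_hand_values(self, track, expected_c, expected_t):
        dec = decompose_velocity(make_track(track))
        assert dec.centripetal_speed == pytest.approx(expected_c, abs=1e-12)
        assert dec.tangential_speed == pytest.approx(expected_t, abs=1e-12)

    def test_outward_motion_is_negative_centripetal(self):
        dec = decompose_velocity(make_track([(100, 0), (102, 0)]))
        assert dec.centripetal_speed == pytest.approx(-2.0)

    def test_interval_starting_at_centre_is_skipped(self):
        dec = decompose_velocity(make_track([(0, 0), (3, 0), (2, 0)]))
        assert dec.centripetal_speed == pytest.approx(1.0)

    def test_track_entirely_at_centre_rejected(self):
        with pytest.raises(ValueError):
            decompose_velocity(make_track([(0, 0), (0, 0), (1, 0)]))

    @given(x=st.floats(-100, 100), y=st.floats(-100, 100),
           ux=st.floats(-5, 5), uy=st.floats(-5, 5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pythagorean_identity_per_interval(self, x, y, ux, uy):
        """centripetal² + tangential² equals the interval speed² exactly."""
        if np.hypot(x, y) < 1e-6:
            return
        track = make_track([(x, y), (x + ux, y + uy)])
        dec = decompose_velocity(track)
        speed = migration_speed(track)
        assert dec.centripetal_speed**2 + dec.tangential_speed**2 == \
            pytest.approx(speed**2, rel=1e-9, abs=1e-12)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, sig = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert sig

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_value(self):
        r, sig = pearson_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert not sig            # n=4, r=0.6 is far from the 5% critical value

    @given(a=st.floats(0.1, 5), b=st.floats(-10, 10))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=(2, 20))
        r0, _ = pearson_correlation(x, y)
        r_scaled, _ = pearson_correlation(x, a * y + b)
        r_neg, _ = pearson_correlation(x, -a * y + b)
        assert r_scaled == pytest.approx(r0, rel=1e-9)
        assert r_neg == pytest.approx(-r0, rel=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2])


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        assert linear_fit(x, 3 * x - 2) == pytest.approx((3.0, -2.0))

    def test_constant_y(self):
        slope, intercept = linear_fit([0, 1, 2], [4.0, 4.0, 4.0])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(4.0)

    def test_hand_value(self):
        assert linear_fit([0, 1, 2], [0, 0, 3]) == pytest.approx((1.5, -0.5))

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            linear_fit([2, 2, 2], [1, 2, 3])


class TestRotationalOrder:
    def test_rigid_counterclockwise_is_plus_one(self):
        p0, p1 = generate_rotation_frame(200, omega=0.05, radius=100.0,
                                         rng=np.random.default_rng(1))
        assert rotational_order(p0, p1) == pytest.approx(1.0, abs=0.01)

    def test_rigid_clockwise_is_minus_one(self):
        p0, p1 = generate_rotation_frame(200, omega=-0.05, radius=100.0,
                                         rng=np.random.default_rng(1))
        assert rotational_order(p0, p1) == pytest.approx(-1.0, abs=0.01)

    def test_isotropic_directions_average_to_zero(self):
        rng = np.random.default_rng(4)
        n = 4000
        p0 = rng.uniform(-100, 100, size=(n, 2))
        ang = rng.uniform(0, 2 * np.pi, size=n)
        p1 = p0 + np.column_stack([np.cos(ang), np.sin(ang)])
        assert abs(rotational_order(p0, p1)) < 3.0 / np.sqrt(n) * 2

    def test_opposing_halves_cancel(self):
        p0 = np.array([(10.0, 0.0), (-10.0, 0.0)])
        p1 = np.array([(10.0, 1.0), (-10.0, 1.0)])  # one CCW, one CW
        assert rotational_order(p0, p1) == pytest.approx(0.0, abs=1e-12)

    def test_stationary_cells_rejected(self):
        p = np.array([(10.0, 0.0)])
        with pytest.raises(ValueError):
            rotational_order(p, p)


class TestSortingIndex:
    def test_fully_sorted(self):
        rng = np.random.default_rng(0)
        rich = rng.normal(0, 3, size=(50, 2))
        poor = rng.normal(0, 3, size=(200, 2)) + 100.0
        pos = np.vstack([rich, poor])
        labels = np.arange(250) < 50
        assert sorting_index(pos, labels) == 1.0

    def test_random_labels_score_rich_fraction(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(-100, 100, size=(5000, 2))
        labels = rng.random(5000) < 0.1
        idx = sorting_index(pos, labels)
        assert idx == pytest.approx(0.1, abs=0.04)

    def test_k_equals_n_gives_exact_fraction(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-10, 10, size=(40, 2))
        labels = np.arange(40) < 8
        assert sorting_index(pos, labels, k=40) == pytest.approx(0.2)


class TestSpeedRadiusProfile:
    @staticmethod
    def _rigid_rotation_traj(omega=0.05, n=400, radius=120.0, n_frames=5):
        rng = np.random.default_rng(6)
        theta = rng.uniform(0, 2 * np.pi, n)
        r = radius * np.sqrt(rng.uniform(0, 1, n))
        frames = [np.column_stack([r * np.cos(theta + omega * k),
                                   r * np.sin(theta + omega * k)])
                  for k in range(n_frames)]
        return TrajectorySet(np.arange(n_frames, dtype=float),
                             np.array(frames), np.arange(n),
                             np.zeros(n, dtype=bool), ModelParameters())

    def test_rigid_rotation_profile_matches_chord_formula(self):
        omega = 0.05
        traj = self._rigid_rotation_traj(omega)
        prof = speed_vs_radius_profile(traj, bin_width=20.0)
        # chord per minute at radius r is 2 r sin(ω/2); the expected bin mean
        # uses the actual radii of the samples falling in each bin
        r = np.hypot(*traj.positions[0].T)
        expected = [2 * np.sin(omega / 2)
                    * r[(r >= m - 10.0) & (r < m + 10.0)].mean()
                    for m in prof.radius_mid]
        np.testing.assert_allclose(prof.mean_speed_um_min, expected, rtol=1e-9)
        assert prof.mean_speed_um_min.is_monotonic_increasing

    def test_stationary_cells_give_zero(self):
        traj = self._rigid_rotation_traj(omega=0.0)
        prof = speed_vs_radius_profile(traj, bin_width=20.0)
        np.testing.assert_allclose(prof.mean_speed_um_min, 0.0, atol=1e-12)

    def test_empty_window_rejected(self):
        traj = self._rigid_rotation_traj()
        with pytest.raises(ValueError):
            speed_vs_radius_profile(traj, t_start=3.0, t_end=2.0)


class TestTrackIO:
    def test_round_trip_through_csv(self, tmp_path):
        spec = FixtureSpec(n_rich=3, n_poor=3, track_length_min=5.0, seed=5)
        tracks = generate_tracks(spec)
        path = tmp_path / "tracks.csv"
        write_tracks_csv(tracks, path)
        loaded = read_tracks(path)
        assert len(loaded) == 6
        for a, b in zip(tracks, loaded):
            assert a.cell_id == b.cell_id
            np.testing.assert_allclose(a.positions, b.positions, atol=1e-5)
            assert b.intensity == pytest.approx(a.intensity, abs=1e-5)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("cell_id,time_min,x_um\n0,0,1\n0,1,2\n")
        with pytest.raises(ValueError):
            read_tracks(path)

    def test_nonuniform_sampling_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("cell_id,time_min,x_um,y_um\n0,0,0,0\n0,1,1,0\n0,3,2,0\n")
        with pytest.raises(ValueError):
            read_tracks(path)

    def test_analyze_tracks_table(self, tmp_path):
        spec = FixtureSpec(n_rich=20, n_poor=20, track_length_min=10.0, seed=2)
        table = analyze_tracks(generate_tracks(spec), center=(0.0, 0.0))
        assert list(table.columns) == ["cell_id", "intensity_std", "class",
                                       "speed_um_min", "v_centripetal",
                                       "v_tangential"]
        assert len(table) == 40
        # intensities are bimodal at ±1 with sd 0.3, so classes are recovered
        assert (table["class"][:20] == "rich").mean() > 0.9
        assert (table["class"][20:] == "poor").mean() > 0.9
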