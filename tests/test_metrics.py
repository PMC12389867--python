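import math

import numpy as np
import pytest

from spemlab import (
    ColocalityParams,
    ScreenGeometry,
    Trajectory,
    colocality,
    disk_intersection_cardinality,
    gauss_disk_cardinality,
    normalize_area_cohort,
    polygon_area_index,
    regression_direction_index,
    sample_direction_index,
    shoelace_area,
    step_angles,
)

#: geometry with a 1 mm = 1 px pitch so radii can be stated in pixels
UNIT_GEO = ScreenGeometry(
    width_px=1000, height_px=1000, diagonal_mm=math.hypot(1000, 1000)
)


def _traj(points):
    return Trajectory(np.asarray(points, dtype=float))


def _brute_intersection(c1, r1, c2, r2):
    lo_x = int(min(c1[0] - r1, c2[0] - r2)) - 1
    hi_x = int(max(c1[0] + r1, c2[0] + r2)) + 1
    lo_y = int(min(c1[1] - r1, c2[1] - r2)) - 1
    hi_y = int(max(c1[1] + r1, c2[1] + r2)) + 1
    n = 0
    for x in range(lo_x, hi_x + 1):
        for y in range(lo_y, hi_y + 1):
            if (x - c1[0]) ** 2 + (y - c1[1]) ** 2 <= r1 * r1 and (
                x - c2[0]
            ) ** 2 + (y - c2[1]) ** 2 <= r2 * r2:
                n += 1
    return n


class TestLatticeDisks:
    @pytest.mark.parametrize("r,expected", [(0, 1), (1, 5), (2, 13)])
    def test_small_disk_cardinalities(self, r, expected):
        assert gauss_disk_cardinality(r) == expected

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            r = rng.uniform(0, 12)
            n = sum(
                1
                for x in range(-13, 14)
                for y in range(-13, 14)
                if x * x + y * y <= r * r
            )
            assert gauss_disk_cardinality(r) == n

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            gauss_disk_cardinality(-1)

    def test_intersection_nesting_and_disjoint(self):
        assert disk_intersection_cardinality((5, 5), 4.0, (5, 5), 2.0) == gauss_disk_cardinality(2.0)
        assert disk_intersection_cardinality((0, 0), 2.0, (10, 0), 2.0) == 0

    def test_intersection_symmetric_and_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            c1 = tuple(rng.integers(-10, 10, 2))
            c2 = tuple(rng.integers(-10, 10, 2))
            r1, r2 = rng.uniform(0, 8, 2)
            got = disk_intersection_cardinality(c1, r1, c2, r2)
            assert got == disk_intersection_cardinality(c2, r2, c1, r1)
            assert got == _brute_intersection(c1, r1, c2, r2)


class TestColocality:
    def test_identical_trajectories_nested_balls(self, target):
        traj = target.trajectory
        assert colocality(traj, traj, ColocalityParams(5.0, 2.0)) == 1.0

    def test_distant_gaze_scores_zero(self):
        o = _traj([[100, 100]] * 5)
        g = _traj([[500, 500]] * 5)
        assert colocality(o, g, ColocalityParams(5.0, 2.0)) == 0.0

    def test_single_frame_matches_direct_intersection(self):
        p = ColocalityParams(2.0, 2.0, geometry=UNIT_GEO)
        got = colocality(_traj([[10, 10]]), _traj([[12, 10]]), p)
        assert got == disk_intersection_cardinality((10, 10), 2.0, (12, 10), 2.0) / 13

    def test_brute_force_oracle_random_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.choice([1, 10]))
            o = rng.integers(20, 60, (n, 2)).astype(float)
            g = o + rng.integers(-10, 11, (n, 2))
            r1, r2 = rng.uniform(1, 8), rng.uniform(1, 6)
            p = ColocalityParams(
                r1 * UNIT_GEO.mm_per_px, r2 * UNIT_GEO.mm_per_px, geometry=UNIT_GEO
            )
            num = sum(_brute_intersection(a, p.r1_px, b, p.r2_px) for a, b in zip(o, g))
            den = n * gauss_disk_cardinality(p.r2_px)
            assert colocality(_traj(o), _traj(g), p) == pytest.approx(num / den, abs=1e-12)

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(5)
        o = rng.integers(100, 200, (20, 2)).astype(float)
        g = o + rng.integers(-15, 16, (20, 2))
        p = ColocalityParams(5.0, 2.0)
        base = colocality(_traj(o), _traj(g), p)
        shift = np.array([37.0, -12.0])
        assert colocality(_traj(o + shift), _traj(g + shift), p) == base
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        assert colocality(_traj(o @ rot.T), _traj(g @ rot.T), p) == base

    def test_monotone_in_target_radius(self):
        rng = np.random.default_rng(6)
        o = rng.integers(100, 200, (30, 2)).astype(float)
        g = o + rng.integers(-25, 26, (30, 2))
        values = [
            colocality(_traj(o), _traj(g), ColocalityParams(r1, 2.0))
            for r1 in (5.0, 10.0, 15.0)
        ]
        assert values[0] <= values[1] <= values[2]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            colocality(_traj([[0, 0]]), _traj([[0, 0], [1, 1]]), ColocalityParams())


class TestDirection:
    def test_cardinal_step_angles(self):
        theta, ok = step_angles(_traj([[0, 0], [1, 0], [1, 1], [1, 1]]))
        assert theta[0] == 0.0
        assert theta[1] == pytest.approx(math.pi / 2)
        assert ok.tolist() == [True, True, False]

    def test_identical_trajectories_fully_coherent(self, target):
        traj = target.trajectory
        assert sample_direction_index(traj, traj) == 0.0

    def test_constant_angular_offset_still_coherent(self):
        n = 200
        t = np.arange(n, dtype=float)
        o = np.column_stack([t, np.zeros(n)])
        g = np.column_stack([t * math.cos(0.4), t * math.sin(0.4)])
        assert sample_direction_index(_traj(o), _traj(g)) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_random_differences_approach_one(self):
        # M = 10,000 uniform angle differences: resultant ~ Rayleigh, so the
        # index is 1 within ~2/sqrt(M)
        rng = np.random.default_rng(12)
        m = 10_000
        o = np.column_stack([np.arange(m + 1, dtype=float), np.zeros(m + 1)])
        ang = rng.uniform(-math.pi, math.pi, m)
        g = np.vstack([[0, 0], np.cumsum(np.column_stack([np.cos(ang), np.sin(ang)]), axis=0)])
        got = sample_direction_index(_traj(o), _traj(g))
        assert got == pytest.approx(1.0, abs=0.02)

    def test_no_joint_motion_rejected(self):
        o = _traj([[0, 0], [0, 0], [0, 0]])
        g = _traj([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError):
            sample_direction_index(o, g)

    def test_regression_index_identity_is_zero(self, target):
        traj = target.trajectory
        val, nseg = regression_direction_index(traj, traj, segments=target.segments())
        assert val == pytest.approx(0.0, abs=1e-9)
        assert nseg == len(target.segments())

    def test_regression_index_recovers_known_tilt(self):
        n = 100
        t = np.arange(n, dtype=float)
        o = np.column_stack([t, np.zeros(n)])
        g = np.column_stack([t * math.cos(0.3), t * math.sin(0.3)])
        val, _ = regression_direction_index(_traj(o), _traj(g), segments=[(0, n - 1)])
        assert val == pytest.approx(0.3, abs=1e-9)

    def test_regression_index_small_under_isotropic_noise(self):
        # 300-sample straight segment, sigma = 2 px gaze noise: the fitted
        # orientation stays within 0.05 rad in at least 95/100 seeded runs
        n = 300
        t = np.arange(n, dtype=float) * 250 / 60
        o = np.column_stack([t, np.zeros(n)])
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = o + rng.normal(0, 2.0, (n, 2))
            val, _ = regression_direction_index(_traj(o), _traj(g), segments=[(0, n - 1)])
            hits += val < 0.05
        assert hits >= 95

    def test_coincident_gaze_segment_skipped_with_warning(self):
        o = _traj([[0, 0], [1, 0], [2, 0], [3, 0], [3, 1], [3, 2], [3, 3]])
        g = np.array([[5.0, 5.0]] * 4 + [[0, 0], [1, 1], [2, 2]])
        with pytest.warns(UserWarning, match="coincident"):
            val, nseg = regression_direction_index(
                o, _traj(g), segments=[(0, 3), (3, 6)]
            )
        assert nseg == 1
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            regression_direction_index(o, _traj(np.zeros((7, 2))), segments=[(0, 3)])


class TestPolygonArea:
    def test_textbook_polygons(self):
        signed, absolute = shoelace_area([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert absolute == 1.0 and signed == 1.0
        assert shoelace_area([(0, 0), (4, 0), (0, 3)])[1] == 6.0
        assert shoelace_area([(0, 0), (1, 1), (2, 2), (3, 3)])[1] == 0.0
        with pytest.raises(ValueError):
            shoelace_area([(0, 0), (1, 1)])

    def test_orientation_sets_sign(self):
        cw = [(0, 0), (0, 1), (1, 1), (1, 0)]
        assert shoelace_area(cw)[0] == -1.0

    def test_shapely_oracle_on_random_simple_polygons(self):
        # star-shaped polygons (sorted angles around a center) are simple;
        # shapely's area is an independent triangulation-based oracle
        from shapely.geometry import Polygon

        rng = np.random.default_rng(13)
        for _ in range(200):
            k = int(rng.integers(3, 12))
            ang = np.sort(rng.uniform(0, 2 * math.pi, k))
            rad = rng.uniform(0.5, 10.0, k)
            pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
            assert shoelace_area(pts)[1] == pytest.approx(
                Polygon(pts).area, rel=1e-9
            )

    def test_straight_trajectory_has_zero_area(self, straight_line):
        assert polygon_area_index(straight_line, 15) == 0.0

    def test_unit_square_cycles(self):
        cycle = [(0, 0), (1, 0), (1, 1), (0, 1)]
        pos = np.array(cycle * 5, dtype=float)
        assert polygon_area_index(Trajectory(pos), 4) == 1.0

    def test_windowing_matches_independent_reimplementation(self):
        rng = np.random.default_rng(14)
        pos = np.cumsum(rng.normal(0, 3, (200, 2)), axis=0)
        traj = Trajectory(pos)
        for w in (15, 30, 90):
            expected = np.mean(
                [
                    abs(
                        0.5
                        * np.sum(
                            pos[i : i + w, 0] * np.roll(pos[i : i + w, 1], -1)
                            - pos[i : i + w, 1] * np.roll(pos[i : i + w, 0], -1)
                        )
                    )
                    for i in range(0, (200 // w) * w, w)
                ]
            )
            assert polygon_area_index(traj, w) == pytest.approx(expected, rel=1e-12)

    def test_area_scales_quadratically(self):
        rng = np.random.default_rng(15)
        pos = np.cumsum(rng.normal(0, 3, (90, 2)), axis=0)
        a1 = polygon_area_index(Trajectory(pos), 15)
        a3 = polygon_area_index(Trajectory(3.0 * pos), 15)
        assert a3 == pytest.approx(9.0 * a1, rel=1e-12)

    def test_window_errors(self, straight_line):
        with pytest.raises(ValueError):
            polygon_area_index(straight_line, 121)
        with pytest.raises(ValueError):
            polygon_area_index(straight_line, 2)


class TestAreaNormalization:
    def test_divides_by_cohort_max(self):
        np.testing.assert_allclose(
            normalize_area_cohort([2.0, 4.0, 8.0]), [0.25, 0.5, 1.0]
        )
        np.testing.assert_allclose(normalize_area_cohort([3.0]), [1.0])

    def test_order_preserved(self):
        rng = np.random.default_rng(16)
        v = rng.uniform(0, 100, 30)
        out = normalize_area_cohort(v)
        assert np.array_equal(np.argsort(out), np.argsort(v))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_area_cohort([0.0, 0.0])
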