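import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memstep.familiarity import (
    RasterGrid,
    TSLVState,
    burn_in_initialize,
    centroid,
    directional_bias,
    min_distance_to_path,
    occurrence_distribution,
    od_contour_indicator,
    stratified_ods,
    tslv_advance,
    tslv_lookup,
)
from memstep.trajectory import Location, Track


def _track(points, dt=1.0):
    return Track(id="t", locations=[Location(i * dt, float(x), float(y)) for i, (x, y) in enumerate(points)])


class TestOccurrenceDistribution:
    def test_point_mass_limit(self, unit_grid):
        # single fix at the center of cell (5, 5); bandwidth << res
        tr = _track([(55.0, 55.0)])
        od = occurrence_distribution(tr, (0.0, 1.0), unit_grid, bandwidth=0.5)
        assert od.values[5, 5] >= 0.99

    def test_normalization(self, unit_grid):
        tr = _track([(23, 41), (88, 12), (140, 160), (55, 99)])
        od = occurrence_distribution(tr, (0.0, 10.0), unit_grid, bandwidth=25.0)
        assert od.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(od.values >= 0)

    def test_reflection_symmetry(self, unit_grid):
        # two fixes mirrored about the grid's vertical midline x = 100
        tr = _track([(60.0, 95.0), (140.0, 95.0)])
        od = occurrence_distribution(tr, (0.0, 10.0), unit_grid, bandwidth=20.0)
        assert np.allclose(od.values, od.values[:, ::-1], atol=1e-12)

    def test_empty_window_is_error(self, unit_grid):
        tr = _track([(50, 50)])
        with pytest.raises(ValueError, match="window"):
            occurrence_distribution(tr, (5.0, 6.0), unit_grid, bandwidth=5.0)

    def test_bad_bandwidth(self, unit_grid):
        with pytest.raises(ValueError, match="bandwidth"):
            occurrence_distribution(_track([(50, 50)]), (0, 1), unit_grid, bandwidth=0.0)


class TestContourIndicator:
    def _uniform_od(self, spec, k):
        v = np.zeros(spec.n_rows * spec.n_cols)
        v[:k] = 1.0 / k
        return RasterGrid(spec=spec, values=v.reshape(spec.n_rows, spec.n_cols))

    def test_full_support_at_level_one(self, unit_grid):
        od = self._uniform_od(unit_grid, 37)
        ind = od_contour_indicator(od, 1.0)
        assert ind.values.sum() == 37
        assert np.array_equal(ind.values > 0, od.values > 0)

    def test_uniform_od_takes_ceil_of_level(self, unit_grid):
        k = 40
        ind = od_contour_indicator(self._uniform_od(unit_grid, k), 0.95)
        assert ind.values.sum() == math.ceil(0.95 * k)

    def test_point_mass_single_cell(self, unit_grid):
        v = np.zeros((20, 20))
        v[3, 7] = 1.0
        od = RasterGrid(spec=unit_grid, values=v)
        for level in (0.05, 0.5, 0.95, 1.0):
            ind = od_contour_indicator(od, level)
            assert ind.values.sum() == 1 and ind.values[3, 7] == 1

    def test_binary_output_and_level_validation(self, unit_grid):
        ind = od_contour_indicator(self._uniform_od(unit_grid, 11), 0.6)
        assert set(np.unique(ind.values)) <= {0.0, 1.0}
        with pytest.raises(ValueError):
            od_contour_indicator(self._uniform_od(unit_grid, 11), 0.0)

    def test_matches_bruteforce_cumulative_sort(self, unit_grid):
        rng = np.random.default_rng(8)
        v = rng.random((20, 20))
        od = RasterGrid(spec=unit_grid, values=v / v.sum())
        level = 0.95
        ind = od_contour_indicator(od, level)
        flat = od.values.ravel()
        order = sorted(range(flat.size), key=lambda i: (-flat[i], i))
        acc, chosen = 0.0, set()
        for i in order:
            chosen.add(i)
            acc += flat[i]
            if acc >= level:
                break
        assert set(np.flatnonzero(ind.values.ravel())) == chosen


class TestStratifiedODs:
    def test_short_equals_long_when_windows_coincide(self, unit_grid):
        tr = _track([(50 + i, 50) for i in range(6)], dt=0.25)  # 1.25 days total
        got = stratified_ods(tr, t_now=1.5, spec=unit_grid, bandwidth=10.0, short_window=3.0)
        assert np.allclose(got["long_all"].values, got["short_all"].values, atol=1e-12)

    def test_daytime_step_uses_daytime_history(self, unit_grid):
        # history: one fix at hour 2 (night, at x=30), one at hour 10 (day, x=170)
        tr = Track(id="d", locations=[Location(2 / 24, 35.0, 105.0), Location(10 / 24, 165.0, 105.0)])
        got = stratified_ods(tr, t_now=0.5, spec=unit_grid, bandwidth=2.0)  # hour 12: day
        diel = got["long_diel"]
        full = got["long_all"]
        r, c_day = unit_grid.cell_of(165.0, 105.0)
        _, c_night = unit_grid.cell_of(35.0, 105.0)
        assert diel.values[r, c_day] > 0.99
        assert diel.values[r, c_night] < 1e-6
        assert full.values[r, c_night] > 0.4

    def test_missing_diel_history_flagged_unavailable(self, unit_grid):
        tr = Track(id="d", locations=[Location(12 / 24, 100.0, 100.0)])  # daytime only
        got = stratified_ods(tr, t_now=1.0, spec=unit_grid, bandwidth=5.0)  # t_now hour 0: night
        assert got["long_diel"] is None and got["short_diel"] is None
        assert got["long_all"] is not None and got["short_all"] is not None


class TestTSLV:
    def test_visit_then_query(self, unit_grid):
        st_ = TSLVState(spec=unit_grid)
        tslv_advance(st_, Location(10.0, 55.0, 55.0))
        (v,) = tslv_lookup(st_, [Location(12.0, 57.0, 51.0)], t_query=12.0)
        assert v == 2.0

    def test_revisit_resets(self, unit_grid):
        st_ = TSLVState(spec=unit_grid)
        tslv_advance(st_, Location(10.0, 55.0, 55.0))
        tslv_advance(st_, Location(12.0, 51.0, 59.0))  # same cell
        (v,) = tslv_lookup(st_, [Location(12.0, 55.0, 55.0)], t_query=12.0)
        assert v == 0.0

    def test_never_visited_default(self, unit_grid):
        st_ = TSLVState(spec=unit_grid, default_tslv=365.0)
        for tq in (0.0, 5.0, 1000.0):
            (v,) = tslv_lookup(st_, np.array([[150.0, 150.0]]), t_query=tq)
            assert v == 365.0

    def test_two_points_same_cell_share_value(self, unit_grid):
        st_ = TSLVState(spec=unit_grid)
        tslv_advance(st_, Location(3.0, 105.0, 105.0))
        got = tslv_lookup(st_, np.array([[101.0, 101.0], [109.0, 109.0]]), t_query=7.0)
        assert got[0] == got[1] == 4.0

    def test_sequence_of_visits_hand_enumeration(self, unit_grid):
        st_ = TSLVState(spec=unit_grid)
        pts = [(5.0, 5.0), (25.0, 5.0), (45.0, 5.0), (65.0, 5.0), (85.0, 5.0)]
        for t, (x, y) in enumerate(pts):
            tslv_advance(st_, Location(float(t), x, y))
        got = tslv_lookup(st_, np.array(pts), t_query=10.0)
        assert got.tolist() == [10.0, 9.0, 8.0, 7.0, 6.0]

    def test_time_regression_and_outside_grid_errors(self, unit_grid):
        st_ = TSLVState(spec=unit_grid)
        tslv_advance(st_, Location(5.0, 50.0, 50.0))
        with pytest.raises(ValueError, match="regression"):
            tslv_advance(st_, Location(4.0, 50.0, 50.0))
        with pytest.raises(ValueError, match="outside"):
            tslv_advance(st_, Location(6.0, 500.0, 50.0))
        with pytest.raises(ValueError, match="outside"):
            tslv_lookup(st_, np.array([[500.0, 50.0]]), t_query=6.0)

    def test_trace_matches_event_log_oracle(self, unit_grid):
        """Cell TSLV grows with slope 1 between visits and resets at visits,
        checked against an independent dict-based event log."""
        rng = np.random.default_rng(12)
        st_ = TSLVState(spec=unit_grid, default_tslv=365.0)
        log: dict[tuple[int, int], float] = {}
        query_pts = np.array([[15.0, 15.0], [95.0, 95.0], [185.0, 185.0]])
        for t in range(60):
            x, y = rng.uniform(0, 200, size=2)
            loc = Location(float(t), float(x), float(y))
            tslv_advance(st_, loc)
            log[(int(y // 10), int(x // 10))] = float(t)
            expected = [
                float(t) - log[(int(py // 10), int(px // 10))]
                if (int(py // 10), int(px // 10)) in log
                else 365.0
                for px, py in query_pts
            ]
            got = tslv_lookup(st_, query_pts, t_query=float(t))
            assert got.tolist() == expected


class TestBurnIn:
    def _two_year_track(self):
        n = 200
        return Track(
            id="b",
            locations=[Location(i * 3.65, 50.0 + (i % 7) * 10, 50.0) for i in range(n)],
        )

    def test_zero_burn_in(self, unit_grid):
        tr = self._two_year_track()
        state, rest = burn_in_initialize(tr, 0.0, unit_grid)
        assert np.all(np.isnan(state.last_visit))
        assert len(rest) == len(tr)

    def test_one_year_burn_in_on_two_year_track(self, unit_grid):
        tr = self._two_year_track()  # ~730 days
        state, rest = burn_in_initialize(tr, 365.0, unit_grid)
        assert rest.duration == pytest.approx(365.0, abs=4.0)
        assert rest.locations[0].t >= 365.0
        assert state.clock < 365.0

    def test_single_cell_burn_in(self, unit_grid):
        tr = Track(id="s", locations=[Location(float(i), 55.0, 55.0) for i in range(10)])
        state, rest = burn_in_initialize(tr, 5.0, unit_grid)
        assert np.sum(~np.isnan(state.last_visit)) == 1
        assert state.last_visit[5, 5] == 4.0

    def test_burn_in_longer_than_track_is_error(self, unit_grid):
        tr = Track(id="s", locations=[Location(float(i), 55.0, 55.0) for i in range(10)])
        with pytest.raises(ValueError, match="duration"):
            burn_in_initialize(tr, 20.0, unit_grid)


class TestMinDistanceToPath:
    def test_point_on_segment(self):
        d = min_distance_to_path(np.array([[1.0, 0.0]]), np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert d[0] == 0.0

    def test_perpendicular_foot(self):
        d = min_distance_to_path(np.array([[0.0, 1.0]]), np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert d[0] == pytest.approx(1.0)

    def test_single_vertex_path(self):
        d = min_distance_to_path(np.array([[3.0, 4.0]]), np.array([[0.0, 0.0]]))
        assert d[0] == pytest.approx(5.0)

    def test_empty_path_error(self):
        with pytest.raises(ValueError):
            min_distance_to_path(np.array([[0.0, 0.0]]), np.empty((0, 2)))

    def test_matches_bruteforce_segment_oracle(self):
        rng = np.random.default_rng(21)
        path = rng.uniform(0, 1000, size=(50, 2))
        pts = rng.uniform(-200, 1200, size=(200, 2))
        got = min_distance_to_path(pts, path)

        def seg_dist(p, a, b):
            ab = b - a
            tt = np.dot(p - a, ab) / np.dot(ab, ab)
            tt = min(1.0, max(0.0, tt))
            c = a + tt * ab
            return math.hypot(p[0] - c[0], p[1] - c[1])

        for i, p in enumerate(pts):
            brute = min(seg_dist(p, path[j], path[j + 1]) for j in range(len(path) - 1))
            assert got[i] == pytest.approx(brute, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        theta=st.floats(-math.pi, math.pi),
        dx=st.floats(-1e4, 1e4),
        dy=st.floats(-1e4, 1e4),
    )
    def test_rigid_motion_invariance(self, theta, dx, dy):
        rng = np.random.default_rng(3)
        path = rng.uniform(0, 500, size=(12, 2))
        pts = rng.uniform(0, 500, size=(20, 2))
        c, s = math.cos(theta), math.sin(theta)
        R = np.array([[c, -s], [s, c]])
        base = min_distance_to_path(pts, path)
        moved = min_distance_to_path(pts @ R.T + [dx, dy], path @ R.T + [dx, dy])
        assert np.allclose(base, moved, atol=1e-7)


class TestDirectionalBias:
    def test_aligned_antialigned_perpendicular_exact(self):
        start, target = (0.0, 0.0), (10.0, 0.0)
        assert directional_bias(start, (4.0, 0.0), target) == 1.0
        assert directional_bias(start, (-3.0, 0.0), target) == -1.0
        assert directional_bias(start, (0.0, 7.0), target) == 0.0

    def test_magnitude_invariance(self):
        start, target = (1.0, 2.0), (8.0, -3.0)
        a = directional_bias(start, (4.0, 5.0), target)
        # same direction, 100x the length
        far = (1.0 + 100 * 3.0, 2.0 + 100 * 3.0)
        assert directional_bias(start, far, target) == pytest.approx(a, abs=1e-12)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(17)
        ends = rng.normal(size=(30, 2)) * 50
        start, target = (3.0, -2.0), (40.0, 10.0)
        vec = directional_bias(start, ends, target)
        for e, v in zip(ends, vec):
            assert directional_bias(start, (float(e[0]), float(e[1])), target) == pytest.approx(v)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="centroid"):
            directional_bias((0.0, 0.0), (1.0, 0.0), (0.0, 0.0))
        with pytest.raises(ValueError, match="zero-length"):
            directional_bias((0.0, 0.0), (0.0, 0.0), (1.0, 0.0))

    def test_centroid_is_arithmetic_mean(self):
        pts = [(0.0, 0.0), (2.0, 0.0), (2.0, 4.0), (0.0, 4.0)]
        assert centroid(pts) == (1.0, 2.0)
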