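"""Track loading, owa classification, step geometry and motility statistics."""

import io

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from conftest import make_track
from woundtrack import trajectories as traj
from woundtrack.errors import DataError


class TestLoadTracks:
    def _csv(self, rows):
        return pd.DataFrame(rows, columns=["track_id", "t_s", "x_um", "y_um"])

    def test_duration_filter_boundary(self):
        rows = [(1, 0, 0, 0), (1, 30, 1, 0),                 # 2 points: drop
                (2, 0, 0, 0), (2, 30, 1, 0), (2, 60, 2, 0)]  # 3 points: keep
        tracks = traj.load_tracks(self._csv(rows))
        assert [t.track_id for t in tracks] == [2]
        assert len(tracks[0]) == 3

    def test_fin_clipping_before_duration_filter(self):
        fin = Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])
        rows = [(1, t, x, 50) for t, x in
                [(0, 5), (30, 10), (60, 15), (90, 150), (120, 160)]]
        tracks = traj.load_tracks(self._csv(rows), fin_polygon=fin)
        assert len(tracks) == 1 and len(tracks[0]) == 3

    def test_nonmonotone_time_rejected(self):
        rows = [(1, 0, 0, 0), (1, 30, 1, 0), (1, 30, 2, 0)]
        with pytest.raises(DataError):
            traj.load_tracks(self._csv(rows))

    def test_malformed_rows_reported(self):
        csv = io.StringIO("track_id,t_s,x_um,y_um\n1,0,1.0,2.0\n1,30,oops,2.0\n")
        with pytest.raises(DataError, match="line"):
            traj.load_tracks(csv)


class TestClassifyTrack:
    def test_enters_and_stays(self, square_owa):
        pts = [(20, 5), (17, 5), (14, 5), (12, 5), (11, 5), (5, 5), (4, 5)]
        c = traj.classify_track(make_track(pts), square_owa)
        assert c.category == traj.FORWARD_INTERSECTING
        assert c.forward_segment == (0, 4)
        assert c.reverse_segment is None

    def test_enters_and_leaves_yields_both_segments(self, square_owa):
        outside = [(20 - i, 5) for i in range(5)]          # 0..4 outside
        inside = [(5, 5)] * 5                              # 5..9 inside
        after = [(11 + i, 5) for i in range(6)]            # 10..15 outside
        c = traj.classify_track(make_track(outside + inside + after), square_owa)
        assert c.category == traj.REVERSE
        assert c.forward_segment == (0, 4)
        assert c.reverse_segment == (9, 15)

    def test_nonintersecting_toward_and_away(self, square_owa):
        toward = make_track([(90, 5), (60, 5), (40, 5)])
        away = make_track([(40, 5), (60, 5), (90, 5)])
        assert traj.classify_track(toward, square_owa).category == \
            traj.FORWARD_NONINTERSECTING
        assert traj.classify_track(away, square_owa).category == \
            traj.AWAY_NONINTERSECTING

    def test_entirely_inside_is_reported_separately(self, square_owa):
        c = traj.classify_track(make_track([(5, 5), (6, 5), (5, 6)]), square_owa)
        assert c.category == traj.UNCLASSIFIED_INSIDE

    def test_boundary_point_counts_as_inside(self, square_owa):
        c = traj.classify_track(make_track([(20, 5), (15, 5), (10, 5)]),
                                square_owa)
        assert c.intersected

    def test_starts_inside_then_exits_gives_reverse_only(self, square_owa):
        c = traj.classify_track(make_track([(5, 5), (12, 5), (15, 5)]),
                                square_owa)
        assert c.category == traj.REVERSE
        assert c.forward_segment is None
        assert c.reverse_segment == (0, 2)


class TestStepRecords:
    def test_speed_arithmetic(self, square_owa):
        steps = traj.step_records(make_track([(20, 5), (25, 5)]), square_owa)
        assert steps["v_um_min"].iloc[0] == pytest.approx(10.0)  # 5 µm / 30 s

    def test_square_owa_distance_geometry(self, square_owa):
        steps = traj.step_records(make_track([(15, 5), (5, 5), (6, 5)]),
                                  square_owa)
        assert steps["d_um"].iloc[0] == pytest.approx(5.0)
        assert steps["d_um"].iloc[1] == 0.0
        assert bool(steps["inside_owa"].iloc[1])

    @pytest.mark.parametrize("step_to,expected", [
        ((14, 5), 1.0),    # straight at the nearest perimeter point
        ((16, 5), -1.0),   # directly away
        ((15, 6), 0.0),    # perpendicular
    ])
    def test_cosine_geometry(self, square_owa, step_to, expected):
        steps = traj.step_records(make_track([(15, 5), step_to]), square_owa)
        assert steps["cos_theta"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_cosine_undefined_inside_and_for_zero_step(self, square_owa):
        steps = traj.step_records(make_track([(5, 5), (6, 5), (6, 6)]),
                                  square_owa)
        assert np.isnan(steps["cos_theta"].iloc[0])  # start inside
        steps2 = traj.step_records(make_track([(15, 5), (15, 5), (14, 5)]),
                                   square_owa)
        assert np.isnan(steps2["cos_theta"].iloc[0])  # zero displacement

    def test_distance_continuity_bounded_by_step_length(self, square_owa, rng):
        pts = np.cumsum(rng.normal(0, 3, (50, 2)), axis=0) + [30, 30]
        steps = traj.step_records(make_track(pts), square_owa)
        d = steps["d_um"].to_numpy()
        lengths = np.hypot(*np.diff(pts, axis=0).T)
        assert np.all(np.abs(np.diff(d)) <= lengths[:-1] + 1e-9)


class TestStraightness:
    def test_straight_track_is_one(self, square_owa):
        pts = [(12 + 2 * i, 5) for i in range(10)]
        r = traj.straightness(make_track(pts), square_owa)
        assert r.straightness == pytest.approx(1.0)

    def test_out_and_back_is_zero(self, square_owa):
        pts = [(12, 5), (18, 5), (24, 5), (18, 5), (12, 5)]
        r = traj.straightness(make_track(pts), square_owa)
        assert r.straightness == 0.0

    def test_l_path_is_sqrt2_over_2(self, square_owa):
        pts = [(12, 15), (17, 15), (22, 15), (22, 20), (22, 25)]
        r = traj.straightness(make_track(pts), square_owa)
        assert r.straightness == pytest.approx(np.sqrt(200) / 20, abs=1e-12)

    def test_short_path_excluded_with_reason(self, square_owa):
        pts = [(12, 5), (13, 5), (14, 5)]  # 2 µm total
        r = traj.straightness(make_track(pts), square_owa)
        assert r.straightness is None
        assert "10" in r.excluded_reason

    def test_restricted_to_zone(self, square_owa):
        # only the first three points are within 50 µm of the owa
        pts = [(15, 5), (25, 5), (35, 5), (200, 5), (300, 5)]
        r = traj.straightness(make_track(pts), square_owa)
        assert r.straightness == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self, square_owa, rng):
        for _ in range(20):
            pts = np.cumsum(rng.normal(0, 4, (12, 2)), axis=0) + [20, 20]
            r = traj.straightness(make_track(pts), square_owa)
            if r.straightness is not None:
                assert 0.0 <= r.straightness <= 1.0 + 1e-12


class TestNetReverseTraffic:
    @staticmethod
    def _cls(n_forward_only, n_both, n_nonint=0):
        out = []
        for i in range(n_forward_only):
            out.append(traj.TrackClassification(i, traj.FORWARD_INTERSECTING,
                                                (0, 3), None, True))
        for i in range(n_both):
            out.append(traj.TrackClassification(100 + i, traj.REVERSE,
                                                (0, 3), (6, 9), True))
        for i in range(n_nonint):
            out.append(traj.TrackClassification(200 + i,
                                                traj.AWAY_NONINTERSECTING))
        return out

    def test_half_of_entrants_leave(self):
        assert traj.net_reverse_traffic(self._cls(2, 2)) == 0.5

    def test_all_entrants_stay(self):
        assert traj.net_reverse_traffic(self._cls(4, 0)) == 0.0

    def test_nonintersecting_excluded_from_both_counts(self):
        assert traj.net_reverse_traffic(self._cls(2, 2, n_nonint=7)) == 0.5

    def test_no_entrants_is_missing(self):
        assert traj.net_reverse_traffic(self._cls(0, 0, n_nonint=3)) is None

    def test_invariant_under_relabeling_and_time_shift(self, square_owa, rng):
        pts_sets = []
        for _ in range(12):
            pts = np.cumsum(rng.normal(0, 4, (20, 2)), axis=0) + [15, 15]
            pts_sets.append(pts)
        base = [traj.classify_track(make_track(p, track_id=i), square_owa)
                for i, p in enumerate(pts_sets)]
        shifted = [traj.classify_track(
            traj.Track(99 - i, np.arange(len(p)) * 30.0 + 12345,
                       p[:, 0], p[:, 1]), square_owa)
            for i, p in enumerate(pts_sets)]
        assert traj.net_reverse_traffic(base) == traj.net_reverse_traffic(shifted)


class TestProfiles:
    def _steps(self, rows):
        return pd.DataFrame(rows, columns=["track_id", "t_s", "v_um_min",
                                           "d_um", "cos_theta", "inside_owa",
                                           "phase", "category"])

    def test_flat_speed_gives_flat_profile(self):
        rows = [(1, t * 30, 10.0, d, 0.5, False, "forward",
                 traj.FORWARD_INTERSECTING)
                for t, d in enumerate([5, 10, 30, 40, 60, 70])]
        prof = traj.speed_vs_distance(self._steps(rows),
                                      bin_edges=[0, 25, 50, 75])
        assert np.allclose(prof["mean"], 10.0)
        assert np.allclose(prof["sem"].fillna(0.0), 0.0)

    def test_binned_means(self):
        rows = [(1, 0, 12.0, 10, 0.5, False, "forward", traj.FORWARD_INTERSECTING),
                (1, 30, 6.0, 30, 0.5, False, "forward", traj.FORWARD_INTERSECTING)]
        prof = traj.speed_vs_distance(self._steps(rows), bin_edges=[0, 25, 50])
        assert list(prof["mean"]) == [12.0, 6.0]

    def test_forward_scope_includes_toward_nonintersecting(self):
        rows = [(1, 0, 5.0, 10, 0.5, False, "unclassified",
                 traj.FORWARD_NONINTERSECTING),
                (2, 0, 9.0, 10, 0.5, False, "unclassified",
                 traj.AWAY_NONINTERSECTING)]
        prof = traj.speed_vs_distance(self._steps(rows), bin_edges=[0, 25],
                                      scope="forward_all")
        assert prof.iloc[0]["mean"] == 5.0  # away-moving track excluded

    def test_single_step_cosine_bin(self):
        rows = [(1, 0, 7.0, 10, 1.0, False, "forward",
                 traj.FORWARD_INTERSECTING)]
        prof = traj.speed_vs_cosine(self._steps(rows))
        assert len(prof) == 1
        assert prof.iloc[0]["mean"] == 7.0
        assert prof.iloc[0]["bin_hi"] == 1.0

    def test_cosine_zone_restriction(self):
        rows = [(1, 0, 7.0, 10, 1.0, False, "forward", traj.FORWARD_INTERSECTING),
                (1, 30, 9.0, 80, 1.0, False, "forward", traj.FORWARD_INTERSECTING)]
        prof = traj.speed_vs_cosine(self._steps(rows), zone_um=50.0)
        assert prof["n"].sum() == 1

    def test_speed_coupling_profile_increases(self):
        rows = []
        for i, ct in enumerate(np.linspace(-1, 1, 200)):
            rows.append((i, 0, 10 * (1 + 0.5 * ct), 20, ct, False, "forward",
                         traj.FORWARD_INTERSECTING))
        prof = traj.speed_vs_cosine(self._steps(rows))
        assert (np.diff(prof["mean"]) > 0).all()

    def test_per_cell_equals_per_step_with_one_step_per_bin(self):
        rows = [(1, 0, 4.0, 10, 0.5, False, "forward", traj.FORWARD_INTERSECTING),
                (2, 0, 8.0, 10, 0.5, False, "forward", traj.FORWARD_INTERSECTING),
                (1, 30, 6.0, 30, 0.5, False, "forward", traj.FORWARD_INTERSECTING)]
        a = traj.speed_vs_distance(self._steps(rows), bin_edges=[0, 25, 50],
                                   aggregation="per_step")
        b = traj.speed_vs_distance(self._steps(rows), bin_edges=[0, 25, 50],
                                   aggregation="per_cell")
        pd.testing.assert_frame_equal(a, b)

    def test_speed_within_owa_matches_filter_then_mean(self, rng):
        rows = []
        for i in range(30):
            rows.append((1, i * 30, rng.uniform(2, 12), 0.0,
                         np.nan, bool(i % 2), "unclassified",
                         traj.FORWARD_INTERSECTING))
        df = self._steps(rows)
        mean, sem, n = traj.speed_within_owa(df)
        expected = df[df["inside_owa"]]["v_um_min"]
        assert mean == pytest.approx(expected.mean())
        assert n == len(expected)

    def test_speed_within_owa_missing_when_none_inside(self):
        rows = [(1, 0, 5.0, 10, 0.5, False, "forward",
                 traj.FORWARD_INTERSECTING)]
        assert traj.speed_within_owa(self._steps(rows)) is None
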