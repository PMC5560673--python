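import numpy as np
import pandas as pd
import pytest

from lsfmtrack import (
    VoxelGeometry,
    cohort_summary,
    distance_from_origin,
    export_tracks,
    path_length,
    speeds,
    track_metrics,
)
from lsfmtrack.zrecovery import Point3D, Track3D


def _track(coords, tid=0, statuses=None):
    statuses = statuses or ["detected"] * len(coords)
    return Track3D(
        tid,
        [
            Point3D(t, x, y, z, status=s)
            for (t, x, y, z), s in zip(coords, statuses)
        ],
    )


def _random_track(rng, n=10, tid=0):
    pts = np.cumsum(rng.normal(0, 3, size=(n, 3)), axis=0) + 50
    return _track([(t, *pts[t]) for t in range(n)], tid)


class TestPathLength:
    def test_stationary_track_zero(self, geometry):
        tr = _track([(t, 5.0, 5.0, 5.0) for t in range(21)])
        assert path_length(tr, geometry) == 0.0

    def test_ten_unit_steps_in_x(self, geometry):
        tr = _track([(t, float(t), 0.0, 0.0) for t in range(11)])
        assert path_length(tr, geometry) == pytest.approx(10 * 0.589)

    def test_anisotropic_step(self, geometry):
        tr = _track([(0, 0, 0, 0), (1, 1, 0, 1)])
        assert path_length(tr, geometry) == pytest.approx(
            np.hypot(0.589, 2.0), abs=1e-4
        )

    def test_single_point_zero(self, geometry):
        assert path_length(_track([(0, 1, 2, 3)]), geometry) == 0.0

    def test_gap_filled_points_excluded_by_default(self, geometry):
        # the interpolated middle point lies off the straight line; including
        # it would inflate the path
        tr = _track(
            [(0, 0, 0, 0), (1, 5, 5, 0), (2, 10, 0, 0)],
            statuses=["detected", "gap-filled", "detected"],
        )
        direct = path_length(tr, geometry)
        assert direct == pytest.approx(10 * 0.589)
        assert path_length(tr, geometry, include_gap_filled=True) > direct

    def test_2d_mode_ignores_z(self, geometry):
        tr = _track([(0, 0, 0, 0), (1, 0, 0, 10)])
        assert path_length(tr, geometry, mode="2d") == 0.0
        assert path_length(tr, geometry, mode="3d") == pytest.approx(20.0)


class TestDistanceFromOrigin:
    def test_out_and_back_returns_to_zero(self, geometry):
        out = [(t, float(t), 0.0, 0.0) for t in range(5)]
        back = [(5 + t, float(3 - t), 0.0, 0.0) for t in range(4)]
        tr = _track(out + back)
        d = distance_from_origin(tr, geometry)
        assert d[0] == 0.0
        assert d[-1] == pytest.approx(0.0)
        assert path_length(tr, geometry) > 0

    def test_straight_mover_matches_cumulative_path(self, geometry):
        tr = _track([(t, 2.0 * t, 0.0, 0.0) for t in range(8)])
        d = distance_from_origin(tr, geometry)
        assert np.all(np.diff(d) > 0)
        assert d[-1] == pytest.approx(path_length(tr, geometry))

    def test_single_point(self, geometry):
        np.testing.assert_array_equal(
            distance_from_origin(_track([(0, 1, 1, 1)]), geometry), [0.0]
        )


class TestSpeeds:
    def test_two_pixel_step_per_frame(self, geometry):
        tr = _track([(0, 0, 0, 0), (1, 2, 0, 0)])
        mean, inst = speeds(tr, geometry)
        assert mean == pytest.approx(2 * 0.589 / 30.0)
        assert inst[0] == pytest.approx(2 * 0.589 / 30.0)

    def test_stationary_zero(self, geometry):
        mean, inst = speeds(_track([(t, 1, 1, 1) for t in range(5)]), geometry)
        assert mean == 0.0
        assert np.all(inst == 0.0)

    def test_doubling_dt_halves_speeds(self):
        tr = _track([(t, 3.0 * t, 0.0, 0.0) for t in range(6)])
        g1 = VoxelGeometry(dt=30.0)
        g2 = VoxelGeometry(dt=60.0)
        m1, i1 = speeds(tr, g1)
        m2, i2 = speeds(tr, g2)
        assert m2 == pytest.approx(m1 / 2)
        np.testing.assert_allclose(i2, i1 / 2)

    def test_single_point(self, geometry):
        mean, inst = speeds(_track([(0, 0, 0, 0)]), geometry)
        assert mean == 0.0 and inst.size == 0


class TestInvariants:
    def test_triangle_translation_reversal_on_random_tracks(self, geometry):
        rng = np.random.default_rng(0)
        for k in range(200):
            tr = _random_track(rng, n=int(rng.integers(2, 15)))
            m = track_metrics(tr, geometry)
            cum = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(
                    np.array([[p.x * geometry.dx, p.y * geometry.dy, p.z * geometry.dz] for p in tr.points]),
                    axis=0), axis=1))])
            assert np.all(m.distance_from_origin <= cum + 1e-9)
            assert m.net_displacement <= m.path_length + 1e-9
            # translation invariance
            shifted = _track([(p.time_index, p.x + 7, p.y - 3, p.z + 11) for p in tr.points])
            ms = track_metrics(shifted, geometry)
            assert ms.path_length == pytest.approx(m.path_length)
            assert ms.net_displacement == pytest.approx(m.net_displacement)
            np.testing.assert_allclose(ms.distance_from_origin, m.distance_from_origin)
            # time reversal preserves path length
            rev = _track([(i, p.x, p.y, p.z) for i, p in enumerate(reversed(tr.points))])
            assert path_length(rev, geometry) == pytest.approx(m.path_length)

    def test_straightness_bounds(self, geometry):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = track_metrics(_random_track(rng), geometry)
            assert 0.0 <= m.straightness <= 1.0 + 1e-12


class TestCohort:
    def test_identical_copies_average_equals_member(self, geometry):
        tr = _track([(t, 2.0 * t, t * 1.0, 0.0) for t in range(6)])
        copies = [_track([(p.time_index, p.x, p.y, p.z) for p in tr.points], tid=k) for k in range(4)]
        summary = cohort_summary(copies, geometry)
        dist = summary["distance_from_origin"]
        np.testing.assert_allclose(dist.loc["mean"].values, dist.loc[0].values)

    def test_mirror_movers_symmetric_average(self, geometry):
        a = _track([(t, float(t), 0.0, 0.0) for t in range(6)], tid=0)
        b = _track([(t, float(-t), 0.0, 0.0) for t in range(6)], tid=1)
        summary = cohort_summary([a, b], geometry)
        dist = summary["distance_from_origin"]
        np.testing.assert_allclose(dist.loc["mean"].values, dist.loc[0].values)

    def test_average_uses_only_defined_tracks(self, geometry):
        long = _track([(t, float(t), 0.0, 0.0) for t in range(6)], tid=0)
        short = _track([(t, float(t), 0.0, 0.0) for t in range(3)], tid=1)
        dist = cohort_summary([long, short], geometry)["distance_from_origin"]
        # beyond the short track's end the average equals the long track alone
        assert dist.loc["mean", 150.0] == pytest.approx(dist.loc[0, 150.0])


class TestExport:
    def test_files_written_and_deterministic(self, tmp_path, geometry):
        rng = np.random.default_rng(3)
        tracks = [_random_track(rng, tid=k) for k in range(3)]
        out1 = tmp_path / "a"
        out2 = tmp_path / "b"
        p1 = export_tracks(tracks, geometry, out1)
        p2 = export_tracks(tracks, geometry, out2)
        for key in ("tracks3d", "metrics", "summary"):
            assert p1[key].read_bytes() == p2[key].read_bytes()
        assert p1["xlsx"].exists() and p1["manifest"].exists()
        assert len(pd.read_csv(p1["summary"])) == 3

    def test_zero_tracks_headers_only(self, tmp_path, geometry):
        paths = export_tracks([], geometry, tmp_path)
        df = pd.read_csv(paths["summary"])
        assert len(df) == 0
        assert list(df.columns) == [
            "id", "path_length_um", "net_disp_um", "mean_speed_um_min", "straightness",
        ]
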