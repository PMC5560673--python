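import itertools

import numpy as np
import pandas as pd
import pytest

from lsfmtrack import DetectionParams, detect_cells, import_manual_track, link_tracks, seeded_track
from lsfmtrack.tracking import Detection, GAP_FILLED, tracks_to_dataframe

from conftest import gaussian_spot_image


# --- detection -------------------------------------------------------------

class TestDetectCells:
    def test_single_spot_subpixel_centroid(self):
        img = gaussian_spot_image((128, 128), cx=60.0, cy=40.0, sigma=3.0)
        dets = detect_cells(img, DetectionParams(sigma_px=1.5))
        assert len(dets) == 1
        assert abs(dets[0].x - 60.0) < 0.5
        assert abs(dets[0].y - 40.0) < 0.5

    def test_blank_frame_yields_no_detections(self):
        assert detect_cells(np.zeros((64, 64))) == []
        assert detect_cells(np.full((64, 64), 7.0)) == []

    @pytest.mark.parametrize(
        "sep_sigmas,expected", [(6.0, 2), (5.0, 2), (0.8, 1), (0.5, 1)]
    )
    def test_spot_pair_resolution(self, sep_sigmas, expected):
        # two equal spots merge below ~1 sigma separation, resolve above ~4
        sigma = 3.0
        sep = sep_sigmas * sigma
        img = gaussian_spot_image((128, 128), 64 - sep / 2, 64, sigma)
        img += gaussian_spot_image((128, 128), 64 + sep / 2, 64, sigma, background=0.0)
        dets = detect_cells(img, DetectionParams(sigma_px=1.0))
        assert len(dets) == expected

    def test_deterministic_ordering(self):
        img = gaussian_spot_image((96, 96), 20, 70, 2.5)
        img += gaussian_spot_image((96, 96), 70, 20, 2.5, background=0.0)
        dets = detect_cells(img, DetectionParams(sigma_px=1.0))
        assert [round(d.y) for d in dets] == sorted(round(d.y) for d in dets)

    def test_absolute_threshold_requires_value(self):
        with pytest.raises(ValueError):
            DetectionParams(threshold_mode="absolute")


# --- linking ---------------------------------------------------------------

def _dets(frame_positions):
    return [
        [Detection(t, x, y) for (x, y) in frame]
        for t, frame in enumerate(frame_positions)
    ]


def _oracle_transition_cost(a, b, gate):
    """Minimum of sum(d^2) + gate^2 * (#unmatched) over all gated matchings."""
    gate2 = gate * gate
    best = gate2 * (len(a) + len(b))  # nobody matched
    for k in range(1, min(len(a), len(b)) + 1):
        for rows in itertools.combinations(range(len(a)), k):
            for cols in itertools.permutations(range(len(b)), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d2 = (a[i][0] - b[j][0]) ** 2 + (a[i][1] - b[j][1]) ** 2
                    if d2 > gate2:
                        ok = False
                        break
                    cost += d2
                if ok:
                    cost += gate2 * (len(a) - k + len(b) - k)
                    best = min(best, cost)
    return best


def _implementation_transition_costs(tracks, frame_positions, gate):
    """Recompute the per-transition objective realised by link_tracks."""
    gate2 = gate * gate
    T = len(frame_positions)
    costs = []
    for t in range(T - 1):
        matched = 0
        cost = 0.0
        for tr in tracks:
            pts = {p.time_index: p for p in tr.points}
            if t in pts and t + 1 in pts:
                p, q = pts[t], pts[t + 1]
                cost += (q.x - p.x) ** 2 + (q.y - p.y) ** 2
                matched += 1
        cost += gate2 * (
            len(frame_positions[t]) - matched + len(frame_positions[t + 1]) - matched
        )
        costs.append(cost)
    return costs


class TestLinkTracks:
    def test_stationary_detection_single_track(self):
        dets = _dets([[(10.0, 20.0)]] * 21)
        tracks = link_tracks(dets, gate_px=5.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 21
        assert np.allclose(tracks[0].xy, [10.0, 20.0])

    def test_parallel_movers_keep_identity(self):
        frames = [[(10.0 + 2 * t, 10.0), (10.0 + 2 * t, 60.0)] for t in range(15)]
        tracks = link_tracks(_dets(frames), gate_px=5.0)
        assert len(tracks) == 2
        for tr in tracks:
            ys = {round(p.y) for p in tr.points}
            assert len(ys) == 1  # no identity swap across the 50 px lane gap

    def test_gap_bridging_flags_interpolated_points(self):
        frames = [[(10.0, 10.0)], [], [(14.0, 10.0)]]
        tracks = link_tracks(_dets(frames), gate_px=10.0, max_gap=1)
        assert len(tracks) == 1
        statuses = [p.status for p in tracks[0].points]
        assert statuses == ["detected", GAP_FILLED, "detected"]
        assert tracks[0].points[1].x == pytest.approx(12.0)

    def test_absence_beyond_max_gap_starts_new_track(self):
        frames = [[(10.0, 10.0)], [], [], [(10.0, 10.0)]]
        tracks = link_tracks(_dets(frames), gate_px=10.0, max_gap=1)
        assert len(tracks) == 2
        assert tracks[0].points[-1].time_index == 0
        assert tracks[1].points[0].time_index == 3

    def test_empty_input(self):
        assert link_tracks([], gate_px=5.0) == []
        assert link_tracks([[], []], gate_px=5.0) == []

    def test_matches_exhaustive_oracle_on_random_instances(self):
        # gated optimal assignment must equal brute-force enumeration
        gate = 10.0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            T = int(rng.integers(2, 7))
            frames = [
                [tuple(rng.uniform(0, 40, 2)) for _ in range(rng.integers(0, 6))]
                for _ in range(T)
            ]
            tracks = link_tracks(_dets(frames), gate_px=gate, max_gap=0)
            impl = _implementation_transition_costs(tracks, frames, gate)
            oracle = [
                _oracle_transition_cost(frames[t], frames[t + 1], gate)
                for t in range(T - 1)
            ]
            assert impl == pytest.approx(oracle), f"seed {seed}"

    def test_velocity_prediction_resolves_crossing(self):
        # two movers crossing at right angles: position-only linking swaps
        # or merges; prediction keeps both identities straight
        frames = [
            [(10.0 + 5 * t, 30.0), (30.0, 10.0 + 5 * t)] for t in range(9)
        ]
        tracks = link_tracks(_dets(frames), gate_px=12.0, predict="velocity")
        assert len(tracks) == 2
        for tr in tracks:
            xs = [p.x for p in tr.points]
            ys = [p.y for p in tr.points]
            horizontal = np.ptp(ys) < 1e-9
            vertical = np.ptp(xs) < 1e-9
            assert horizontal or vertical


# --- seeded (semi-automatic) ----------------------------------------------

class TestSeededTrack:
    def _stationary_frames(self, n=8):
        return [gaussian_spot_image((64, 64), 30.0, 25.0, 2.5) for _ in range(n)]

    def test_follows_stationary_spot(self):
        frames = self._stationary_frames()
        (track,) = seeded_track([(0, 30.0, 25.0)], frames, search_radius_px=6)
        assert len(track) == len(frames)
        for p in track.points:
            assert abs(p.x - 30.0) < 0.5 and abs(p.y - 25.0) < 0.5

    def test_seed_on_background_terminates_immediately(self):
        frames = self._stationary_frames(4)
        (track,) = seeded_track(
            [(0, 5.0, 5.0)], frames, search_radius_px=3, min_intensity=500.0
        )
        assert len(track) == 1 and track.terminated

    def test_seed_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            seeded_track([(0, 100.0, 5.0)], self._stationary_frames(2), 5)

    def test_agrees_with_automatic_on_isolated_mover(self):
        frames = [
            gaussian_spot_image((96, 96), 20.0 + 3 * t, 40.0 + 2 * t, 2.5)
            for t in range(10)
        ]
        (seeded,) = seeded_track([(0, 20.0, 40.0)], frames, search_radius_px=10)
        dets = [detect_cells(f, DetectionParams(sigma_px=1.0), t) for t, f in enumerate(frames)]
        (auto,) = link_tracks(dets, gate_px=8.0)
        assert len(seeded) == len(auto)
        for ps, pa in zip(seeded.points, auto.points):
            assert np.hypot(ps.x - pa.x, ps.y - pa.y) < 1.0


# --- manual import ---------------------------------------------------------

class TestManualImport:
    def test_verbatim_conversion(self):
        df = pd.DataFrame(
            {"id": [1] * 3, "time_index": [0, 1, 2], "x": [1.0, 2.0, 3.0], "y": [4.0, 5.0, 6.0]}
        )
        (track,) = import_manual_track(df)
        assert [p.status for p in track.points] == ["manual"] * 3
        np.testing.assert_allclose(track.xy, df[["x", "y"]].values)

    def test_unsorted_rows_sorted_within_id(self):
        df = pd.DataFrame(
            {"id": [1, 1, 1], "time_index": [2, 0, 1], "x": [3.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]}
        )
        (track,) = import_manual_track(df)
        assert [p.time_index for p in track.points] == [0, 1, 2]
        assert [p.x for p in track.points] == [1.0, 2.0, 3.0]

    def test_duplicate_rows_rejected(self):
        df = pd.DataFrame(
            {"id": [1, 1], "time_index": [0, 0], "x": [1.0, 2.0], "y": [0.0, 0.0]}
        )
        with pytest.raises(ValueError):
            import_manual_track(df)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            import_manual_track(pd.DataFrame({"id": [1], "t": [0]}))

    def test_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"id": [0, 0, 1], "time_index": [0, 1, 0], "x": [1.5, 2.5, 9.0], "y": [3.0, 4.0, 8.0]}
        )
        path = tmp_path / "manual.csv"
        df.to_csv(path, index=False)
        tracks = import_manual_track(path)
        assert [tr.id for tr in tracks] == [0, 1]
        out = tracks_to_dataframe(tracks)
        assert len(out) == 3
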