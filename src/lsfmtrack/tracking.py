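"""Detect fluorescent cells on projected frames and link them through time.

Three tracking modes are provided, mirroring common practice for point-like
fluorescent objects:

* **automatic** — per-frame detection (Gaussian smoothing, Otsu or absolute
  threshold, connected components, intensity-weighted centroids) followed by
  gated optimal-assignment linking that minimises total squared displacement
  per frame transition;
* **seeded (semi-automatic)** — the user clicks a cell once; its position is
  followed frame-to-frame as the intensity-weighted centroid inside a search
  disk around the previous position;
* **manual import** — externally clicked coordinates are ingested verbatim
  from CSV.

Linking bridges short detection drop-outs (``max_gap`` frames) with linearly
interpolated, explicitly flagged gap-filled points; longer absences end the
track.  Gap-filled points are excluded from path-length accumulation
downstream by default, so interpolation never fabricates motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "Detection",
    "TrackPoint",
    "Track2D",
    "DetectionParams",
    "detect_cells",
    "link_tracks",
    "seeded_track",
    "import_manual_track",
    "tracks_to_dataframe",
]

# point status labels
DETECTED = "detected"
GAP_FILLED = "gap-filled"
SEEDED = "seeded"
MANUAL = "manual"

_BIG = 1e12  # forbidden-assignment cost; any feasible match beats it


@dataclass(frozen=True)
class Detection:
    """One candidate cell in one 2D frame."""

    time_index: int
    x: float
    y: float
    peak_intensity: float = 0.0
    area: int = 0


@dataclass(frozen=True)
class TrackPoint:
    time_index: int
    x: float
    y: float
    status: str = DETECTED


@dataclass
class Track2D:
    """Per-cell time series of 2D positions with per-point provenance."""

    id: int
    points: List[TrackPoint] = field(default_factory=list)
    terminated: bool = False

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_index for p in self.points])

    @property
    def xy(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float).reshape(-1, 2)


@dataclass
class DetectionParams:
    """Spot-detection parameters.

    ``sigma_px`` — Gaussian pre-smoothing; ``threshold_mode`` — ``"otsu"``
    (data-driven) or ``"absolute"`` (uses ``threshold``); ``min_area``/
    ``max_area`` — connected-component size gate in pixels.
    """

    sigma_px: float = 2.0
    threshold_mode: str = "otsu"
    threshold: Optional[float] = None
    min_area: int = 4
    max_area: int = 10_000

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "absolute"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "absolute" and self.threshold is None:
            raise ValueError("absolute threshold_mode requires a threshold value")
        if not (0 < self.min_area <= self.max_area):
            raise ValueError("require 0 < min_area <= max_area")


def detect_cells(
    frame: np.ndarray,
    params: DetectionParams | None = None,
    time_index: int = 0,
) -> List[Detection]:
    """Detect bright spots on one 2D frame.

    Gaussian smoothing, thresholding, 8-connected component labelling, area
    filtering, and intensity-weighted centroids on the smoothed image.
    Detections are returned ordered by (y, x) so output is deterministic.
    An all-zero (or all-constant) frame yields an empty list.
    """
    params = params or DetectionParams()
    img = np.asarray(frame, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    smoothed = ndimage.gaussian_filter(img, params.sigma_px) if params.sigma_px > 0 else img

    if params.threshold_mode == "absolute":
        thr = float(params.threshold)
    else:
        if np.ptp(smoothed) == 0:
            return []
        thr = float(threshold_otsu(smoothed))
    mask = smoothed > thr
    if not mask.any():
        return []

    labels = cc_label(mask, connectivity=2)  # 8-connectivity
    detections: List[Detection] = []
    for region in regionprops(labels, intensity_image=smoothed):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        cy, cx = region.centroid_weighted
        detections.append(
            Detection(
                time_index=time_index,
                x=float(cx),
                y=float(cy),
                peak_intensity=float(region.intensity_max),
                area=int(region.area),
            )
        )
    detections.sort(key=lambda d: (d.y, d.x))
    return detections


def _interpolated_points(last: TrackPoint, nxt: TrackPoint) -> List[TrackPoint]:
    """Linearly interpolated gap-filled points strictly between two points."""
    out = []
    span = nxt.time_index - last.time_index
    for t in range(last.time_index + 1, nxt.time_index):
        f = (t - last.time_index) / span
        out.append(
            TrackPoint(t, last.x + f * (nxt.x - last.x), last.y + f * (nxt.y - last.y), GAP_FILLED)
        )
    return out


def link_tracks(
    detections: Sequence[Sequence[Detection]],
    gate_px: float,
    max_gap: int = 0,
    predict: str = "none",
) -> List[Track2D]:
    """Link per-frame detections into tracks by gated optimal assignment.

    For each frame transition the track-to-detection assignment minimising
    the total squared centroid displacement is solved exactly (Hungarian
    algorithm on a square matrix padded with non-match entries of cost
    ``gate_px**2``); pairs farther apart than the gate are forbidden.  A
    track unseen for ``g <= max_gap`` frames may still capture a detection
    within ``gate_px * (g + 1)`` (the per-frame gate scaled by the elapsed
    frames); the missing frames are then bridged with flagged, linearly
    interpolated points.  Unmatched detections start new tracks; tracks
    unseen for more than ``max_gap`` frames are closed.

    Parameters
    ----------
    detections : sequence of per-frame detection lists, frames ordered.
    gate_px : float
        Maximum displacement per frame, pixels (> 0).
    max_gap : int
        Maximum bridgeable drop-out, frames (>= 0).
    predict : {"none", "velocity"}
        Reference point for the cost.  ``"none"`` measures displacement
        from the track's last position; ``"velocity"`` from a
        constant-velocity extrapolation of its last step, which strongly
        suppresses identity swaps between persistent movers whose paths
        cross.  The gate is applied around the same reference point.
    """
    if gate_px <= 0:
        raise ValueError("gate_px must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if predict not in ("none", "velocity"):
        raise ValueError(f"unknown predict mode {predict!r}")

    finished: List[Track2D] = []
    active: List[Track2D] = []
    next_id = 0

    for frame_idx, frame_dets in enumerate(detections):
        frame_dets = list(frame_dets)
        # close tracks whose drop-out exceeded max_gap
        still_active = []
        for tr in active:
            if frame_idx - tr.points[-1].time_index - 1 > max_gap:
                finished.append(tr)
            else:
                still_active.append(tr)
        active = still_active

        if not frame_dets:
            continue

        n_tr, n_det = len(active), len(frame_dets)
        if n_tr:
            gate2 = gate_px * gate_px
            size = n_tr + n_det
            cost = np.full((size, size), _BIG)
            cost[n_tr:, n_det:] = 0.0
            for i, tr in enumerate(active):
                last = tr.points[-1]
                gap = frame_idx - last.time_index
                eff_gate2 = (gate_px * gap) ** 2
                rx, ry = last.x, last.y
                if predict == "velocity" and len(tr.points) >= 2:
                    prev = tr.points[-2]
                    span = last.time_index - prev.time_index
                    if span > 0:
                        vx = (last.x - prev.x) / span
                        vy = (last.y - prev.y) / span
                        rx, ry = last.x + vx * gap, last.y + vy * gap
                for j, det in enumerate(frame_dets):
                    d2 = (det.x - rx) ** 2 + (det.y - ry) ** 2
                    if d2 <= eff_gate2:
                        cost[i, j] = d2
                cost[i, n_det + i] = gate2  # track skips this frame
            for j in range(n_det):
                cost[n_tr + j, j] = gate2  # detection starts a new track
            rows, cols = linear_sum_assignment(cost)

            matched_dets = set()
            for i, j in zip(rows, cols):
                if i < n_tr and j < n_det and cost[i, j] < _BIG:
                    tr = active[i]
                    pt = TrackPoint(frame_idx, frame_dets[j].x, frame_dets[j].y, DETECTED)
                    tr.points.extend(_interpolated_points(tr.points[-1], pt))
                    tr.points.append(pt)
                    matched_dets.add(j)
            new_dets = [j for j in range(n_det) if j not in matched_dets]
        else:
            new_dets = list(range(n_det))

        for j in new_dets:
            det = frame_dets[j]
            active.append(
                Track2D(next_id, [TrackPoint(frame_idx, det.x, det.y, DETECTED)])
            )
            next_id += 1

    finished.extend(active)
    finished.sort(key=lambda tr: tr.id)
    return finished


def _disk_mask(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return yy * yy + xx * xx <= radius * radius


def _window(
    img: np.ndarray, cx: float, cy: float, radius: int
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Clip a (2r+1)² window and matching disk mask at (cx, cy)."""
    h, w = img.shape
    ix, iy = int(round(cx)), int(round(cy))
    y0, y1 = max(0, iy - radius), min(h, iy + radius + 1)
    x0, x1 = max(0, ix - radius), min(w, ix + radius + 1)
    mask = _disk_mask(radius)[
        y0 - (iy - radius) : y1 - (iy - radius), x0 - (ix - radius) : x1 - (ix - radius)
    ]
    return img[y0:y1, x0:x1], mask, x0, y0


def seeded_track(
    seeds: Sequence[tuple],
    frames: Sequence[np.ndarray],
    search_radius_px: int = 10,
    min_intensity: Optional[float] = None,
) -> List[Track2D]:
    """Semi-automatic tracking from user-provided seed points.

    Each seed ``(time_index, x, y)`` is followed forward in time: at every
    subsequent frame the new position is the intensity-weighted centroid
    within the search disk around the previous position.  The track stops
    (``terminated=True``) as soon as the local maximum inside the disk falls
    below the detection threshold (``min_intensity``, or per-frame Otsu when
    not given).

    Raises
    ------
    ValueError
        If a seed lies outside the image bounds or the radius is not > 0.
    """
    if search_radius_px <= 0:
        raise ValueError("search_radius_px must be > 0")
    frames = [np.asarray(f, dtype=float) for f in frames]
    h, w = frames[0].shape

    thresholds = []
    for f in frames:
        if min_intensity is not None:
            thresholds.append(float(min_intensity))
        else:
            thresholds.append(float(threshold_otsu(f)) if np.ptp(f) > 0 else np.inf)

    tracks: List[Track2D] = []
    for sid, (t0, sx, sy) in enumerate(seeds):
        t0 = int(t0)
        if not (0 <= t0 < len(frames)):
            raise ValueError(f"seed time_index {t0} outside the time-lapse")
        if not (0 <= sx < w and 0 <= sy < h):
            raise ValueError(f"seed ({sx}, {sy}) outside image bounds {w}x{h}")

        track = Track2D(sid, [], terminated=False)
        x, y = float(sx), float(sy)
        for t in range(t0, len(frames)):
            win, mask, x0, y0 = _window(frames[t], x, y, search_radius_px)
            local_max = float(win[mask].max()) if mask.any() else -np.inf
            if local_max < thresholds[t]:
                if t == t0:
                    track.points.append(TrackPoint(t, x, y, SEEDED))
                track.terminated = True
                break
            weights = np.where(mask, win, 0.0)
            total = weights.sum()
            if total > 0:
                ys, xs = np.indices(win.shape)
                y = y0 + float((ys * weights).sum() / total)
                x = x0 + float((xs * weights).sum() / total)
            track.points.append(TrackPoint(t, x, y, SEEDED))
        tracks.append(track)
    return tracks


def import_manual_track(table: Union[str, Path, pd.DataFrame]) -> List[Track2D]:
    """Ingest manually clicked tracks from CSV columns (id, time_index, x, y).

    Rows are sorted by time within each id; values are preserved verbatim
    and every point is flagged ``manual``.  Duplicate (id, time_index) pairs
    raise a format error.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    required = {"id", "time_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manual track table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["id", "time_index"]).any():
        dup = df[df.duplicated(subset=["id", "time_index"], keep=False)]
        raise ValueError(
            f"duplicate (id, time_index) rows in manual track table:\n{dup}"
        )
    tracks = []
    for tid, group in df.groupby("id", sort=True):
        group = group.sort_values("time_index")
        points = [
            TrackPoint(int(r.time_index), float(r.x), float(r.y), MANUAL)
            for r in group.itertuples()
        ]
        tracks.append(Track2D(int(tid), points))
    return tracks


def tracks_to_dataframe(tracks: Sequence[Track2D]) -> pd.DataFrame:
    """Flatten tracks to a tidy table (id, t, x_px, y_px, status)."""
    rows = [
        {"id": tr.id, "t": p.time_index, "x_px": p.x, "y_px": p.y, "status": p.status}
        for tr in tracks
        for p in tr.points
    ]
    return pd.DataFrame(rows, columns=["id", "t", "x_px", "y_px", "status"])


def tracks_from_dataframe(df: pd.DataFrame) -> List[Track2D]:
    """Inverse of :func:`tracks_to_dataframe`."""
    tracks = []
    for tid, group in df.groupby("id", sort=True):
        group = group.sort_values("t")
        points = [
            TrackPoint(int(r.t), float(r.x_px), float(r.y_px), str(r.status))
            for r in group.itertuples()
        ]
        tracks.append(Track2D(int(tid), points))
    return tracks
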