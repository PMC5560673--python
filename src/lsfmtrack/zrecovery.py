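"""Lift 2D tracks to 3D by per-timepoint axial intensity argmax.

For a point-like fluorophore, the z-plane in which the tracked (x, y)
position is brightest is the plane the cell occupies.  For every track
point the whole stack is scanned: ``score(z)`` is the mean intensity within
a small disk (default radius 3 px) around (x, y) on slice ``z``, and the
estimate is the lowest slice index attaining the maximum score.  Radius 0
recovers the literal single-pixel column argmax.  Optional sub-slice
refinement fits a parabola through the scores at (z−1, z, z+1) when the
peak is interior; refined points are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .geometry import VoxelGeometry, to_physical
from .image_model import TimeLapse
from .tracking import Track2D, TrackPoint

__all__ = ["Point3D", "Track3D", "recover_z"]


@dataclass(frozen=True)
class Point3D:
    """One 3D track point in voxel coordinates, with axial provenance.

    ``z_confidence`` is the ratio of the winning plane's score to the median
    score over all slices of the same (x, y) column — near 1 means the
    column is featureless and the z-estimate uninformative.  ``refined``
    marks sub-slice parabolic refinement; ``valid`` is False when (x, y)
    fell outside the stack at that frame (z undefined).
    """

    time_index: int
    x: float
    y: float
    z: float
    status: str = "detected"
    z_confidence: float = float("nan")
    refined: bool = False
    valid: bool = True


@dataclass
class Track3D:
    """Per-cell time series of (t, x, y, z) voxel coordinates."""

    id: int
    points: List[Point3D] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def physical(self, geometry: VoxelGeometry) -> np.ndarray:
        """(n, 4) array of (t_min, x_um, y_um, z_um) for valid points."""
        return np.array(
            [
                to_physical((p.time_index, p.x, p.y, p.z), geometry)
                for p in self.points
                if p.valid
            ]
        ).reshape(-1, 4)


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    keep = yy * yy + xx * xx <= radius * radius
    return yy[keep], xx[keep]


def _column_scores(vox: np.ndarray, ix: int, iy: int, radius: int) -> np.ndarray:
    """Mean disk intensity around (ix, iy) per slice; clips at the border."""
    nz, h, w = vox.shape
    dy, dx = _disk_offsets(radius)
    ys, xs = iy + dy, ix + dx
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    ys, xs = ys[keep], xs[keep]
    return vox[:, ys, xs].astype(float).mean(axis=1)


def recover_z(
    track: Track2D,
    timelapse: TimeLapse,
    window_radius_px: int = 3,
    refine: bool = False,
    max_dz_per_frame: int | None = None,
) -> Track3D:
    """Estimate z for every point of a 2D track.

    Parameters
    ----------
    track : Track2D
        2D track whose frames all exist in ``timelapse``.
    timelapse : TimeLapse
        The (corrected, aligned) stacks the track was made from.
    window_radius_px : int
        Disk radius for the per-slice score; 0 uses the single pixel at the
        rounded (x, y) — the literal per-column argmax.
    refine : bool
        Parabolic sub-slice refinement of interior peaks (off by default;
        integer slice selection is the plain reading of the method).
    max_dz_per_frame : int, optional
        Temporal continuity constraint: after the first valid point the
        argmax is searched only within this many slices of the previous
        estimate (per elapsed frame).  Guards against hemisphere flips when
        two cells cross in projection — the brightest plane at the shared
        (x, y) can then belong to the other cell.  ``None`` (default) keeps
        the unconstrained per-point argmax.

    Notes
    -----
    Ties at the maximum score break to the lowest slice.  Points whose
    (x, y) lies outside the image are carried over with ``valid=False``.
    """
    if window_radius_px < 0:
        raise ValueError("window_radius_px must be >= 0")
    T = len(timelapse)
    points3d: List[Point3D] = []
    prev_z: float | None = None
    prev_t: int | None = None
    for p in track.points:
        if not (0 <= p.time_index < T):
            raise IndexError(
                f"track point at frame {p.time_index} outside time-lapse of length {T}"
            )
        vox = timelapse[p.time_index].voxels
        nz, h, w = vox.shape
        ix, iy = int(round(p.x)), int(round(p.y))
        if not (0 <= ix < w and 0 <= iy < h):
            points3d.append(
                Point3D(p.time_index, p.x, p.y, float("nan"), p.status, valid=False)
            )
            continue
        scores = _column_scores(vox, ix, iy, window_radius_px)
        if max_dz_per_frame is not None and prev_z is not None:
            reach = max_dz_per_frame * max(1, p.time_index - prev_t)
            lo = max(0, int(round(prev_z)) - reach)
            hi = min(nz, int(round(prev_z)) + reach + 1)
            z = lo + int(np.argmax(scores[lo:hi]))
        else:
            z = int(np.argmax(scores))  # first (lowest) index on ties
        med = float(np.median(scores))
        confidence = float(scores[z] / med) if med > 0 else float("inf")
        z_out, refined = float(z), False
        if refine and 0 < z < nz - 1:
            y0, y1, y2 = scores[z - 1], scores[z], scores[z + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:  # strict interior maximum
                z_out = z + 0.5 * (y0 - y2) / denom
                refined = True
        points3d.append(
            Point3D(
                p.time_index, p.x, p.y, z_out, p.status, confidence, refined, True
            )
        )
        prev_z, prev_t = float(z), p.time_index
    return Track3D(track.id, points3d)


def recover_all(
    tracks: Sequence[Track2D],
    timelapse: TimeLapse,
    window_radius_px: int = 3,
    refine: bool = False,
    max_dz_per_frame: int | None = None,
) -> List[Track3D]:
    """Vector convenience: :func:`recover_z` over a list of tracks."""
    return [
        recover_z(tr, timelapse, window_radius_px, refine, max_dz_per_frame)
        for tr in tracks
    ]
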