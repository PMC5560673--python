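"""Quantitative motility measures per track and per cohort, in μm and μm/min.

Measures follow the standard definitions of the cell-migration literature:

* **path length** — sum of Euclidean step distances along the trajectory;
* **net displacement** — distance between the last and first retained point;
* **distance from origin** — per-timepoint distance from the first point;
* **speed** — instantaneous (step length over step duration) and mean
  (path length over elapsed time);
* **straightness** (confinement ratio) — net displacement / path length,
  in [0, 1]; 1 for perfectly directed motion.

All measures are computed in anisotropic physical units via the voxel
geometry.  By default the axial coordinate contributes (full 3D measures);
a 2D-only mode ignoring z is available for comparison.  Gap-filled points
are excluded by default so interpolation never inflates motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import VoxelGeometry
from .zrecovery import Track3D

__all__ = [
    "TrackMetrics",
    "path_length",
    "distance_from_origin",
    "speeds",
    "track_metrics",
    "cohort_summary",
    "export_tracks",
]


@dataclass
class TrackMetrics:
    """Per-track motility summary (physical units)."""

    id: int
    path_length: float  # μm
    net_displacement: float  # μm
    distance_from_origin: np.ndarray  # μm, per retained time point
    times_min: np.ndarray  # minutes, per retained time point
    mean_speed: float  # μm/min
    instantaneous_speed: np.ndarray  # μm/min, per step
    straightness: float  # dimensionless, [0, 1]


def _retained_coords(
    track: Track3D,
    geometry: VoxelGeometry,
    include_gap_filled: bool,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(times_min, positions_um) of retained points, in physical units."""
    if mode not in ("3d", "2d"):
        raise ValueError(f"mode must be '3d' or '2d', got {mode!r}")
    pts = [
        p
        for p in track.points
        if p.valid and (include_gap_filled or p.status != "gap-filled")
    ]
    times = np.array([p.time_index * geometry.dt for p in pts], dtype=float)
    pos = np.array(
        [
            [
                p.x * geometry.dx,
                p.y * geometry.dy,
                p.z * geometry.dz if mode == "3d" else 0.0,
            ]
            for p in pts
        ],
        dtype=float,
    ).reshape(-1, 3)
    return times, pos


def _steps(pos: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.diff(pos, axis=0), axis=1)


def path_length(
    track: Track3D,
    geometry: VoxelGeometry,
    include_gap_filled: bool = False,
    mode: str = "3d",
) -> float:
    """Total path length in μm (sum of consecutive 3D step distances)."""
    _, pos = _retained_coords(track, geometry, include_gap_filled, mode)
    if len(pos) < 2:
        return 0.0
    return float(_steps(pos).sum())


def distance_from_origin(
    track: Track3D,
    geometry: VoxelGeometry,
    include_gap_filled: bool = False,
    mode: str = "3d",
) -> np.ndarray:
    """Per-timepoint Euclidean distance (μm) from the first retained point."""
    _, pos = _retained_coords(track, geometry, include_gap_filled, mode)
    if len(pos) == 0:
        return np.array([])
    return np.linalg.norm(pos - pos[0], axis=1)


def speeds(
    track: Track3D,
    geometry: VoxelGeometry,
    include_gap_filled: bool = False,
    mode: str = "3d",
) -> tuple[float, np.ndarray]:
    """(mean speed, instantaneous speed series) in μm/min.

    Instantaneous speed divides each step length by its duration; the mean
    speed is the path length over the elapsed time of the retained span.
    A single-point track yields (0, empty).
    """
    times, pos = _retained_coords(track, geometry, include_gap_filled, mode)
    if len(pos) < 2:
        return 0.0, np.array([])
    step = _steps(pos)
    dt = np.diff(times)
    inst = step / dt
    elapsed = times[-1] - times[0]
    return float(step.sum() / elapsed), inst


def track_metrics(
    track: Track3D,
    geometry: VoxelGeometry,
    include_gap_filled: bool = False,
    mode: str = "3d",
) -> TrackMetrics:
    """All per-track measures in one pass."""
    times, pos = _retained_coords(track, geometry, include_gap_filled, mode)
    dist = np.linalg.norm(pos - pos[0], axis=1) if len(pos) else np.array([])
    if len(pos) < 2:
        return TrackMetrics(track.id, 0.0, 0.0, dist, times, 0.0, np.array([]), 1.0)
    step = _steps(pos)
    total = float(step.sum())
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    mean_speed = total / (times[-1] - times[0])
    inst = step / np.diff(times)
    straightness = net / total if total > 0 else 1.0
    return TrackMetrics(track.id, total, net, dist, times, mean_speed, inst, straightness)


def cohort_summary(
    tracks: Sequence[Track3D],
    geometry: VoxelGeometry,
    include_gap_filled: bool = False,
    mode: str = "3d",
) -> Dict[str, pd.DataFrame]:
    """Per-time cohort averages of path length and distance from origin.

    Returns a dict with:

    * ``"distance_from_origin"`` and ``"cumulative_path"`` — (track × time)
      matrices indexed by track id, columns elapsed minutes, with a final
      ``"mean"`` row averaging over the tracks defined at each time (no
      imputation);
    * ``"per_track"`` — one summary row per track (path length, net
      displacement, mean speed, straightness).
    """
    if not tracks:
        raise ValueError("cohort_summary requires at least one track")
    dist_rows, path_rows, summary_rows = {}, {}, []
    for tr in tracks:
        m = track_metrics(tr, geometry, include_gap_filled, mode)
        _, pos = _retained_coords(tr, geometry, include_gap_filled, mode)
        cum = (
            np.concatenate([[0.0], np.cumsum(_steps(pos))]) if len(pos) else np.array([])
        )
        dist_rows[tr.id] = pd.Series(m.distance_from_origin, index=m.times_min)
        path_rows[tr.id] = pd.Series(cum, index=m.times_min)
        summary_rows.append(
            {
                "id": tr.id,
                "path_length_um": m.path_length,
                "net_disp_um": m.net_displacement,
                "mean_speed_um_min": m.mean_speed,
                "straightness": m.straightness,
            }
        )
    dist = pd.DataFrame(dist_rows).T.sort_index(axis=1)
    path = pd.DataFrame(path_rows).T.sort_index(axis=1)
    for df in (dist, path):
        df.loc["mean"] = df.mean(axis=0, skipna=True)
    return {
        "distance_from_origin": dist,
        "cumulative_path": path,
        "per_track": pd.DataFrame(summary_rows),
    }


def load_tracks3d(path: Union[str, Path]) -> List[Track3D]:
    """Read a tracks3d.csv written by :func:`export_tracks` back into tracks."""
    from .zrecovery import Point3D

    df = pd.read_csv(path)
    tracks = []
    for tid, group in df.groupby("id", sort=True):
        group = group.sort_values("t")
        points = [
            Point3D(
                int(r.t),
                float(r.x_px),
                float(r.y_px),
                float(r.z_slice),
                str(r.status),
                float(r.z_confidence),
                valid=np.isfinite(r.z_slice),
            )
            for r in group.itertuples()
        ]
        tracks.append(Track3D(int(tid), points))
    return tracks


def _tracks3d_frame(tracks: Sequence[Track3D], geometry: VoxelGeometry) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for p in tr.points:
            rows.append(
                {
                    "id": tr.id,
                    "t": p.time_index,
                    "x_px": p.x,
                    "y_px": p.y,
                    "z_slice": p.z,
                    "x_um": p.x * geometry.dx,
                    "y_um": p.y * geometry.dy,
                    "z_um": p.z * geometry.dz,
                    "t_min": p.time_index * geometry.dt,
                    "z_confidence": p.z_confidence,
                    "status": p.status,
                }
            )
    cols = [
        "id", "t", "x_px", "y_px", "z_slice", "x_um", "y_um", "z_um",
        "t_min", "z_confidence", "status",
    ]
    return pd.DataFrame(rows, columns=cols)


def _metrics_frame(
    tracks: Sequence[Track3D],
    geometry: VoxelGeometry,
    include_gap_filled: bool,
    mode: str,
) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        m = track_metrics(tr, geometry, include_gap_filled, mode)
        _, pos = _retained_coords(tr, geometry, include_gap_filled, mode)
        cum = np.concatenate([[0.0], np.cumsum(_steps(pos))]) if len(pos) else []
        inst = np.concatenate([[np.nan], m.instantaneous_speed]) if len(pos) else []
        for t, d, c, s in zip(m.times_min, m.distance_from_origin, cum, inst):
            rows.append(
                {
                    "id": tr.id,
                    "t_min": t,
                    "dist_origin_um": d,
                    "cum_path_um": c,
                    "inst_speed_um_min": s,
                }
            )
    cols = ["id", "t_min", "dist_origin_um", "cum_path_um", "inst_speed_um_min"]
    return pd.DataFrame(rows, columns=cols)


def export_tracks(
    tracks: Sequence[Track3D],
    geometry: VoxelGeometry,
    out_dir: Union[str, Path],
    include_gap_filled: bool = False,
    mode: str = "3d",
    manifest_extra: Optional[dict] = None,
) -> Dict[str, Path]:
    """Write tracks and measures to CSV, an XLSX workbook and a JSON manifest.

    Files written: ``tracks3d.csv`` (per-point coordinates in voxels and
    μm), ``metrics.csv`` (per-point measures), ``summary.csv`` (per-track
    measures), ``metrics.xlsx`` (one sheet per metric) and
    ``manifest.json`` (parameters, software version, extras) — the
    structured stand-in for a binary workspace export.  Output is
    deterministic: re-export of the same inputs is byte-identical.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tracks_df = _tracks3d_frame(tracks, geometry)
    metrics_df = _metrics_frame(tracks, geometry, include_gap_filled, mode)
    if tracks:
        summary_df = cohort_summary(tracks, geometry, include_gap_filled, mode)[
            "per_track"
        ]
    else:
        summary_df = pd.DataFrame(
            columns=["id", "path_length_um", "net_disp_um", "mean_speed_um_min", "straightness"]
        )

    paths = {
        "tracks3d": out_dir / "tracks3d.csv",
        "metrics": out_dir / "metrics.csv",
        "summary": out_dir / "summary.csv",
        "xlsx": out_dir / "metrics.xlsx",
        "manifest": out_dir / "manifest.json",
    }
    tracks_df.to_csv(paths["tracks3d"], index=False, float_format="%.6f")
    metrics_df.to_csv(paths["metrics"], index=False, float_format="%.6f")
    summary_df.to_csv(paths["summary"], index=False, float_format="%.6f")

    with pd.ExcelWriter(paths["xlsx"], engine="openpyxl") as writer:
        tracks_df.to_excel(writer, sheet_name="tracks3d", index=False)
        metrics_df.to_excel(writer, sheet_name="metrics", index=False)
        summary_df.to_excel(writer, sheet_name="summary", index=False)

    manifest = {
        "software": "lsfmtrack",
        "version": __version__,
        "geometry": {
            "dx_um": geometry.dx,
            "dy_um": geometry.dy,
            "dz_um": geometry.dz,
            "dt_min": geometry.dt,
        },
        "n_tracks": len(tracks),
        "metrics_mode": mode,
        "include_gap_filled": include_gap_filled,
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
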