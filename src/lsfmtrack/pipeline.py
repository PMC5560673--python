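"""End-to-end workflow: correct → align → project → track → lift → measure.

A run is fully determined by (inputs, config); the config is serialised
verbatim into the run manifest next to the outputs, so any result can be
regenerated.  Stages can be toggled off individually (e.g. skip alignment
for a mechanically stable acquisition).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from . import __version__
from .alignment import align_timelapse, save_transforms
from .geometry import VoxelGeometry
from .illumination import estimate_illumination, correct_illumination, IlluminationModel
from .image_model import TimeLapse, ZStack, read_timelapse
from .metrics import export_tracks
from .projection import ProjectedFrame, max_intensity_projection, extended_depth_of_field
from .tracking import (
    DetectionParams,
    detect_cells,
    link_tracks,
    seeded_track,
    import_manual_track,
)
from .zrecovery import recover_all

logger = logging.getLogger("lsfmtrack")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All knobs of one tracking run.

    ``tracking_mode`` is ``auto`` (detect + link), ``seeded`` (follow
    user-supplied seed points) or ``manual`` (import clicked coordinates
    and only lift + measure them).
    """

    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    illumination: bool = True
    alignment: bool = True
    reference_index: int = 0
    projection: str = "mip"  # mip | edf
    edf_patch: int = 9
    tracking_mode: str = "auto"  # auto | seeded | manual
    detection: DetectionParams = field(default_factory=DetectionParams)
    gate_px: float = 20.0
    max_gap: int = 1
    link_predict: str = "velocity"  # "none" = cost from last position
    min_track_length: int = 3
    seeds: Optional[List[tuple]] = None
    manual_table: Optional[str] = None
    search_radius_px: int = 10
    window_radius_px: int = 3
    refine_z: bool = False
    max_dz_slices: Optional[int] = 10  # per-frame axial continuity bound
    metrics_mode: str = "3d"  # 3d | 2d
    include_gap_filled: bool = False
    seed: int = 0
    keep_intermediate: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = {
            "dx_um": self.geometry.dx,
            "dy_um": self.geometry.dy,
            "dz_um": self.geometry.dz,
            "dt_min": self.geometry.dt,
        }
        d["detection"] = asdict(self.detection)
        return d


def _sample_planes(timelapse: TimeLapse, max_planes: int = 100) -> List[np.ndarray]:
    """Evenly sample z-planes across frames for illumination estimation."""
    T, nz = len(timelapse), timelapse[0].n_slices
    total = T * nz
    stride = max(1, total // max_planes)
    planes = []
    for idx in range(0, total, stride):
        t, z = divmod(idx, nz)
        planes.append(timelapse[t].voxels[z].astype(np.float32))
    return planes


def run_pipeline(
    timelapse: Union[TimeLapse, Sequence[Union[str, Path]]],
    config: PipelineConfig,
    out_dir: Union[str, Path],
    in_place: bool = False,
) -> Dict[str, Path]:
    """Execute the full tracking workflow and write results.

    Parameters
    ----------
    timelapse : TimeLapse or sequence of TIFF paths
    config : PipelineConfig
    out_dir : output directory; receives tracks3d.csv, metrics.csv,
        summary.csv, metrics.xlsx, manifest.json (+ intermediates when
        ``keep_intermediate``).
    in_place : bool
        Let the correction and alignment stages overwrite the input voxel
        data instead of copying it; halves peak memory on large
        acquisitions (the caller's TimeLapse is consumed).

    Raises
    ------
    PipelineError
        On stage failure; a ``FAILED`` marker file is left in ``out_dir``
        next to any partial outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            (out_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: %.3f s", name, timings[name])
        return result

    if not isinstance(timelapse, TimeLapse):
        timelapse = _stage("read", read_timelapse, list(timelapse), config.geometry)

    working = timelapse
    if config.illumination:
        def _correct(tl: TimeLapse) -> TimeLapse:
            model = estimate_illumination(_sample_planes(tl))
            if config.keep_intermediate:
                model.save(out_dir / "illumination.tif")
            info = np.iinfo(tl[0].voxels.dtype)
            stacks = []
            for st in tl.stacks:
                corr = correct_illumination(st.voxels, model)
                corr = np.clip(np.rint(corr), info.min, info.max).astype(st.voxels.dtype)
                if in_place:
                    st.voxels = corr
                    stacks.append(st)
                else:
                    stacks.append(ZStack(corr, st.time_index))
            return tl if in_place else TimeLapse(stacks, tl.geometry, tl.channel_name)

        working = _stage("illumination", _correct, working)

    if config.alignment:
        def _align(tl: TimeLapse):
            aligned, transforms = align_timelapse(
                tl, config.reference_index, in_place=in_place
            )
            save_transforms(transforms, out_dir / "transforms.csv")
            return aligned

        working = _stage("alignment", _align, working)

    def _project(tl: TimeLapse) -> List[ProjectedFrame]:
        frames = []
        for st in tl.stacks:
            if config.projection == "mip":
                frames.append(max_intensity_projection(st))
            elif config.projection == "edf":
                img = extended_depth_of_field(st, config.edf_patch)
                frames.append(ProjectedFrame(img, np.zeros_like(img, dtype=int), st.time_index))
            else:
                raise ValueError(f"unknown projection {config.projection!r}")
        return frames

    frames = _stage("projection", _project, working)
    images = [f.image for f in frames]

    def _track():
        if config.tracking_mode == "auto":
            dets = [
                detect_cells(img, config.detection, time_index=t)
                for t, img in enumerate(images)
            ]
            tracks = link_tracks(
                dets, config.gate_px, config.max_gap, config.link_predict
            )
            return [tr for tr in tracks if len(tr) >= config.min_track_length]
        if config.tracking_mode == "seeded":
            if not config.seeds:
                raise ValueError("seeded mode requires seeds")
            return seeded_track(config.seeds, images, config.search_radius_px)
        if config.tracking_mode == "manual":
            if not config.manual_table:
                raise ValueError("manual mode requires manual_table")
            return import_manual_track(config.manual_table)
        raise ValueError(f"unknown tracking_mode {config.tracking_mode!r}")

    tracks2d = _stage("tracking", _track)

    tracks3d = _stage(
        "z_recovery",
        recover_all,
        tracks2d,
        working,
        config.window_radius_px,
        config.refine_z,
        config.max_dz_slices,
    )

    paths = _stage(
        "metrics",
        export_tracks,
        tracks3d,
        config.geometry,
        out_dir,
        config.include_gap_filled,
        config.metrics_mode,
        {
            "pipeline_config": config.to_dict(),
            "stage_timings_s": timings,
            "seed": config.seed,
            "version": __version__,
        },
    )
    return paths
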