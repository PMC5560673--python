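"""Containers and TIFF I/O for calibrated time-lapse z-stacks.

A :class:`ZStack` is one 3D intensity volume indexed ``(z, y, x)``; a
:class:`TimeLapse` is an ordered sequence of stacks sharing one
:class:`~lsfmtrack.geometry.VoxelGeometry`.  Stacks are read from multi-page
grayscale TIFFs (one file per time point) or from a single 4D ``(t, z, y, x)``
container, and are preserved bit-exactly on round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Union

import numpy as np
import tifffile

from .geometry import VoxelGeometry

__all__ = [
    "ZStack",
    "TimeLapse",
    "read_timelapse",
    "write_timelapse",
    "DimensionError",
    "FormatError",
]

_SUPPORTED_DTYPES = (np.uint8, np.uint16)


class DimensionError(ValueError):
    """Array dimensions inconsistent across slices, stacks or files."""


class FormatError(ValueError):
    """Unsupported pixel format (non-grayscale or bit depth other than 8/16)."""


def _check_voxels(voxels: np.ndarray) -> np.ndarray:
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise DimensionError(f"stack must be 3D (z, y, x), got shape {voxels.shape}")
    if voxels.shape[0] < 1:
        raise DimensionError("stack must contain at least one z-slice")
    if voxels.dtype not in _SUPPORTED_DTYPES:
        raise FormatError(
            f"unsupported dtype {voxels.dtype}; 8- or 16-bit unsigned grayscale required"
        )
    return voxels


@dataclass
class ZStack:
    """One 3D intensity volume at a single time point.

    ``voxels`` is a non-negative integer array indexed ``(z, y, x)``;
    ``time_index`` the ordinal frame number (0-based).
    """

    voxels: np.ndarray
    time_index: int = 0

    def __post_init__(self) -> None:
        self.voxels = _check_voxels(self.voxels)
        if self.time_index < 0:
            raise ValueError(f"time_index must be >= 0, got {self.time_index}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def plane_shape(self) -> tuple:
        return self.voxels.shape[1:]


@dataclass
class TimeLapse:
    """Ordered z-stacks sharing one voxel geometry.

    ``time_index`` values run 0..T−1 with no gaps, and all stacks share
    identical voxel dimensions.
    """

    stacks: List[ZStack]
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    channel_name: str = ""

    def __post_init__(self) -> None:
        if not self.stacks:
            raise ValueError("TimeLapse requires at least one stack")
        shape0 = self.stacks[0].voxels.shape
        for k, stack in enumerate(self.stacks):
            if stack.voxels.shape != shape0:
                raise DimensionError(
                    f"stack {k} has shape {stack.voxels.shape}, expected {shape0}"
                )
            if stack.time_index != k:
                raise ValueError(
                    f"time_index values must be consecutive from 0; "
                    f"stack {k} has time_index {stack.time_index}"
                )

    def __len__(self) -> int:
        return len(self.stacks)

    def __getitem__(self, k: int) -> ZStack:
        return self.stacks[k]

    @property
    def shape(self) -> tuple:
        """(T, z, y, x)."""
        return (len(self.stacks),) + self.stacks[0].voxels.shape


def _load_pages(path: Union[str, Path]) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a (z, y, x) array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected grayscale pages, got array of shape {arr.shape}"
        )
    if arr.dtype not in _SUPPORTED_DTYPES:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype} (8/16-bit required)")
    return arr


def read_timelapse(
    paths: Sequence[Union[str, Path]],
    geometry: VoxelGeometry | None = None,
    channel_name: str = "",
) -> TimeLapse:
    """Read a time-lapse from TIFF files.

    ``paths`` may be one path per time point (each a multi-page z-stack) or a
    single path holding a 4D ``(t, z, y, x)`` container.  Stack order follows
    the input order; intensities are preserved bit-exactly.

    Raises
    ------
    DimensionError
        If files disagree in page dimensions or page counts (the offending
        file is named).
    FormatError
        For non-grayscale data or unsupported bit depth.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("at least one input path is required")
    geometry = geometry or VoxelGeometry()

    if len(paths) == 1:
        arr = tifffile.imread(str(paths[0]))
        if arr.dtype not in _SUPPORTED_DTYPES:
            raise FormatError(f"{paths[0]}: unsupported dtype {arr.dtype}")
        if arr.ndim == 4:  # single 4D container
            stacks = [ZStack(arr[t], time_index=t) for t in range(arr.shape[0])]
            return TimeLapse(stacks, geometry=geometry, channel_name=channel_name)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise FormatError(f"{paths[0]}: unsupported array shape {arr.shape}")
        return TimeLapse([ZStack(arr, 0)], geometry=geometry, channel_name=channel_name)

    volumes = [_load_pages(p) for p in paths]
    shape0 = volumes[0].shape
    for p, v in zip(paths, volumes):
        if v.shape != shape0:
            raise DimensionError(
                f"{p}: shape {v.shape} does not match first file's {shape0}"
            )
    stacks = [ZStack(v, time_index=t) for t, v in enumerate(volumes)]
    return TimeLapse(stacks, geometry=geometry, channel_name=channel_name)


def write_timelapse(timelapse: TimeLapse, out_dir: Union[str, Path], prefix: str = "t") -> List[Path]:
    """Write one multi-page TIFF per time point; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(len(timelapse) - 1)))
    written = []
    for stack in timelapse.stacks:
        path = out_dir / f"{prefix}{stack.time_index:0{width}d}.tif"
        tifffile.imwrite(str(path), stack.voxels, photometric="minisblack")
        written.append(path)
    return written
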