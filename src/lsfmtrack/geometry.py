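"""Physical calibration of voxel and frame indices.

A :class:`VoxelGeometry` ties array indices to the physical world: lateral
pixel size ``dx``/``dy`` and axial slice spacing ``dz`` in μm, and the frame
interval ``dt`` in minutes.  Defaults mirror a typical light-sheet
acquisition of a ~400 μm microcarrier: 0.589 μm lateral sampling, 2 μm
z-interval, one stack every 30 min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

__all__ = ["VoxelGeometry", "physical_extent", "to_physical"]


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel and frame calibration.

    Parameters
    ----------
    dx, dy : float
        Lateral pixel size along x (columns) and y (rows), μm/pixel.
    dz : float
        Axial slice spacing, μm/slice.
    dt : float
        Frame interval, minutes/frame.
    """

    dx: float = 0.589
    dy: float = 0.589
    dz: float = 2.0
    dt: float = 30.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz", "dt"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite, got {v!r}")

    @property
    def voxel_size(self) -> Tuple[float, float, float]:
        """(dz, dy, dx) in μm, matching (z, y, x) array axis order."""
        return (self.dz, self.dy, self.dx)


def physical_extent(
    geometry: VoxelGeometry, n_x: int, n_y: int, n_z: int
) -> Tuple[int, int, int]:
    """Physical field-of-view size in integer μm.

    Each extent is the pixel/slice count times the voxel size along that
    axis, rounded to the nearest integer μm (half away from zero).  E.g.
    1920 pixels at 0.589 μm/px span 1130.88 → 1131 μm, and 500 slices at
    2 μm span 1000 μm.
    """
    counts = {"n_x": n_x, "n_y": n_y, "n_z": n_z}
    for name, n in counts.items():
        if n < 1:
            raise ValueError(f"{name} must be >= 1, got {n}")
    return (
        int(math.floor(n_x * geometry.dx + 0.5)),
        int(math.floor(n_y * geometry.dy + 0.5)),
        int(math.floor(n_z * geometry.dz + 0.5)),
    )


def to_physical(
    point: Sequence[float], geometry: VoxelGeometry
) -> Tuple[float, float, float, float]:
    """Convert a (t, x, y, z) voxel-coordinate point to (min, μm, μm, μm).

    Component-wise scaling by (dt, dx, dy, dz); the identity when all
    calibrations are 1.  Coordinates refer to voxel centres, 0-based.
    """
    t, x, y, z = point
    if not all(math.isfinite(v) for v in (t, x, y, z)):
        raise ValueError(f"coordinates must be finite, got {point!r}")
    if t < 0:
        raise ValueError(f"time index must be >= 0, got {t}")
    return (t * geometry.dt, x * geometry.dx, y * geometry.dy, z * geometry.dz)
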