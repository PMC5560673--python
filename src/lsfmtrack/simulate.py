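"""Synthetic cell-on-microcarrier motility time-lapses with ground truth.

The generator emulates a light-sheet acquisition of point-like fluorescent
cells moving on the surface of a spherical microcarrier (~400 μm diameter):
persistent random walks on the sphere, rendered as anisotropic 3D Gaussian
spots over a constant background, modulated by a radially symmetric
vignetting gain field, degraded by Poisson shot noise and Gaussian read
noise, and quantised to 16 bit.  Acquisition geometry defaults match the
target modality: 0.589 μm lateral pixels, 2 μm z-interval, 21 frames at
30-min intervals.

Motion model (surface mode): each cell carries a unit tangent heading; per
frame the heading is a persistence-weighted mixture of the previous heading
and a uniform random tangent direction, and the cell advances along the
corresponding great circle by a chord of exactly ``step_um_per_frame``.
Persistence 0 gives an undirected wander that turns back on itself;
persistence near 1 gives distinct, nearly linear trajectories — the two
motility regimes observed for freshly seeded versus spread, polarised
cells.  A free-space mode (persistent walk in 3D) is kept for unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import numpy as np

from .geometry import VoxelGeometry
from .image_model import TimeLapse, ZStack
from .zrecovery import Point3D, Track3D

__all__ = ["SimConfig", "GroundTruth", "simulate_tracks", "render_timelapse", "vignetting_field"]


@dataclass
class SimConfig:
    """Study conditions of the synthetic acquisition.

    Defaults reproduce the target acquisition: a 400 μm carrier imaged at
    0.589 × 0.589 × 2.0 μm voxels, 21 frames every 30 min, in a volume just
    large enough to contain the sphere (720 × 720 × 230 voxels ≈ 424 × 424
    × 460 μm).  The motion defaults (15 μm/frame, persistence 0.9) put
    20-frame path lengths at ~300 μm, the order of magnitude reported for
    cells on such carriers.
    """

    sphere_diameter_um: float = 400.0
    n_cells: int = 15
    n_frames: int = 21
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    volume_px: Tuple[int, int, int] = (720, 720, 230)  # (n_x, n_y, n_z)
    step_um_per_frame: float = 15.0
    persistence: float = 0.9
    motion_mode: str = "surface"  # surface | free
    psf_sigma_xy_um: float = 2.0
    psf_sigma_z_um: float = 4.0
    cell_amplitude: float = 2000.0
    background_level: float = 100.0
    shell_amplitude: float = 30.0  # faint carrier shell (static anchor for alignment)
    poisson_noise: bool = True
    read_sigma: float = 5.0
    vignetting_strength: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must lie in [0, 1]")
        if self.motion_mode not in ("surface", "free"):
            raise ValueError(f"unknown motion_mode {self.motion_mode!r}")
        if not (0.0 <= self.vignetting_strength < 1.0):
            raise ValueError("vignetting_strength must lie in [0, 1)")
        if self.motion_mode == "surface" and self.step_um_per_frame > self.radius_um:
            raise ValueError(
                f"step {self.step_um_per_frame} μm exceeds sphere radius "
                f"{self.radius_um} μm"
            )
        n_x, n_y, n_z = self.volume_px
        ex, ey, ez = (
            n_x * self.geometry.dx,
            n_y * self.geometry.dy,
            n_z * self.geometry.dz,
        )
        if self.motion_mode == "surface" and not (
            self.sphere_diameter_um <= ex
            and self.sphere_diameter_um <= ey
            and self.sphere_diameter_um <= ez
        ):
            raise ValueError(
                f"sphere of {self.sphere_diameter_um} μm does not fit inside the "
                f"rendered volume ({ex:.0f} × {ey:.0f} × {ez:.0f} μm)"
            )

    @property
    def radius_um(self) -> float:
        return self.sphere_diameter_um / 2.0

    @property
    def center_um(self) -> np.ndarray:
        """Sphere centre = volume centre, μm (voxel-centre convention)."""
        n_x, n_y, n_z = self.volume_px
        return np.array(
            [
                (n_x - 1) / 2.0 * self.geometry.dx,
                (n_y - 1) / 2.0 * self.geometry.dy,
                (n_z - 1) / 2.0 * self.geometry.dz,
            ]
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = {
            "dx_um": self.geometry.dx,
            "dy_um": self.geometry.dy,
            "dz_um": self.geometry.dz,
            "dt_min": self.geometry.dt,
        }
        d["volume_px"] = list(self.volume_px)
        return d


@dataclass
class GroundTruth:
    """True trajectories (μm and voxel coordinates) plus the config echo."""

    positions_um: np.ndarray  # (n_cells, n_frames, 3) — (x, y, z) μm
    config: SimConfig

    @property
    def tracks(self) -> List[Track3D]:
        """True tracks in voxel coordinates."""
        g = self.config.geometry
        out = []
        for cid in range(self.positions_um.shape[0]):
            pts = [
                Point3D(
                    t,
                    self.positions_um[cid, t, 0] / g.dx,
                    self.positions_um[cid, t, 1] / g.dy,
                    self.positions_um[cid, t, 2] / g.dz,
                    status="truth",
                )
                for t in range(self.positions_um.shape[1])
            ]
            out.append(Track3D(cid, pts))
        return out


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _random_tangent(rng: np.random.Generator, u: np.ndarray) -> np.ndarray:
    """Uniform random unit vector in the tangent plane at radial direction u."""
    while True:
        v = rng.normal(size=3)
        t = v - np.dot(v, u) * u
        norm = np.linalg.norm(t)
        if norm > 1e-12:
            return t / norm


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about the unit axis."""
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * np.dot(axis, v) * (1 - np.cos(angle))
    )


def simulate_tracks(config: SimConfig) -> GroundTruth:
    """Simulate ground-truth cell trajectories.

    Surface mode: cells start uniformly at random on the sphere and take
    per-frame steps of chord length exactly ``step_um_per_frame`` along
    great circles whose direction mixes the previous heading (weight
    ``persistence``) with a uniform random tangent direction.  Every point
    lies on the sphere to machine precision.  Free mode: the analogous
    persistent walk in unconstrained 3D, started inside the volume centre
    region.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_cells, config.n_frames
    pos = np.zeros((n, T, 3))
    if n == 0:
        return GroundTruth(pos, config)

    if config.motion_mode == "surface":
        R, c = config.radius_um, config.center_um
        s = config.step_um_per_frame
        theta = 2.0 * np.arcsin(min(1.0, s / (2.0 * R)))
        for cid in range(n):
            u = _random_unit(rng)[0]  # radial unit vector
            h = _random_tangent(rng, u)  # heading, unit tangent
            pos[cid, 0] = c + R * u
            for t in range(1, T):
                r_t = _random_tangent(rng, u)
                mix = config.persistence * h + (1.0 - config.persistence) * r_t
                nrm = np.linalg.norm(mix)
                h = mix / nrm if nrm > 1e-12 else r_t
                axis = np.cross(u, h)
                axis /= np.linalg.norm(axis)
                u = _rotate(u, axis, theta)
                u /= np.linalg.norm(u)
                h = _rotate(h, axis, theta)
                h -= np.dot(h, u) * u  # re-orthogonalise against drift
                h /= np.linalg.norm(h)
                pos[cid, t] = c + R * u
    else:
        c = config.center_um
        s = config.step_um_per_frame
        for cid in range(n):
            p = c + rng.uniform(-20.0, 20.0, size=3)
            d = _random_unit(rng)[0]
            pos[cid, 0] = p
            for t in range(1, T):
                mix = config.persistence * d + (1.0 - config.persistence) * _random_unit(rng)[0]
                nrm = np.linalg.norm(mix)
                d = mix / nrm if nrm > 1e-12 else _random_unit(rng)[0]
                p = p + s * d
                pos[cid, t] = p
    return GroundTruth(pos, config)


def vignetting_field(
    shape: Tuple[int, int], strength: float, normalize: bool = True
) -> np.ndarray:
    """Radially symmetric gain field ``1 − strength · (r/r_max)²``.

    ``r`` is the distance from the image centre, ``r_max`` the centre-to-
    corner distance; strength 0 gives a uniform field of 1.  With
    ``normalize`` the field is rescaled to unit mean (matching the
    convention of the estimated illumination model).
    """
    if not (0.0 <= strength < 1.0):
        raise ValueError("vignetting strength must lie in [0, 1)")
    h, w = shape
    yy, xx = np.indices((h, w), dtype=float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    gain = 1.0 - strength * r2 / r2.max() if r2.max() > 0 else np.ones((h, w))
    if normalize:
        gain = gain / gain.mean()
    return gain


def render_timelapse(truth: GroundTruth, config: SimConfig | None = None) -> TimeLapse:
    """Render ground-truth trajectories as a 16-bit time-lapse of z-stacks.

    Each cell is an anisotropic 3D Gaussian (σ_xy, σ_z) of amplitude
    ``cell_amplitude`` over ``background_level``; the expected image is
    multiplied per z-plane by the vignetting gain, then Poisson shot noise
    and additive Gaussian read noise are applied and the result quantised
    to uint16.  The same seed reproduces identical voxel data.
    """
    config = config or truth.config
    g = config.geometry
    n_x, n_y, n_z = config.volume_px
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gain = vignetting_field((n_y, n_x), config.vignetting_strength, normalize=False)

    sx = config.psf_sigma_xy_um / g.dx
    sy = config.psf_sigma_xy_um / g.dy
    sz = config.psf_sigma_z_um / g.dz
    rx, ry, rz = (int(np.ceil(4 * s)) for s in (sx, sy, sz))

    shell = None
    if config.shell_amplitude > 0:
        shell = _render_shell(config).astype(np.float32)

    stacks = []
    for t in range(config.n_frames):
        expected = np.full((n_z, n_y, n_x), config.background_level, dtype=np.float32)
        if shell is not None:
            expected += shell
        for cid in range(truth.positions_um.shape[0]):
            x_um, y_um, z_um = truth.positions_um[cid, t]
            cx, cy, cz = x_um / g.dx, y_um / g.dy, z_um / g.dz
            x0, x1 = max(0, int(cx) - rx), min(n_x, int(cx) + rx + 1)
            y0, y1 = max(0, int(cy) - ry), min(n_y, int(cy) + ry + 1)
            z0, z1 = max(0, int(cz) - rz), min(n_z, int(cz) + rz + 1)
            if x0 >= x1 or y0 >= y1 or z0 >= z1:
                continue
            zz = (np.arange(z0, z1) - cz) / sz
            yy = (np.arange(y0, y1) - cy) / sy
            xx = (np.arange(x0, x1) - cx) / sx
            spot = config.cell_amplitude * np.exp(
                -0.5
                * (
                    zz[:, None, None] ** 2
                    + yy[None, :, None] ** 2
                    + xx[None, None, :] ** 2
                )
            )
            expected[z0:z1, y0:y1, x0:x1] += spot
        expected *= gain.astype(np.float32)[np.newaxis, :, :]
        if config.poisson_noise:
            noisy = rng.poisson(expected).astype(np.float32)
        else:
            noisy = expected
        if config.read_sigma > 0:
            noisy += rng.normal(0.0, config.read_sigma, size=noisy.shape).astype(
                np.float32
            )
        voxels = np.clip(np.rint(noisy), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        stacks.append(ZStack(voxels, t))
    return TimeLapse(stacks, geometry=g, channel_name="synthetic-calcein")


def _render_shell(config: SimConfig) -> np.ndarray:
    """Faint spherical shell of the carrier (Gaussian radial profile)."""
    g = config.geometry
    n_x, n_y, n_z = config.volume_px
    c = config.center_um
    zz = np.arange(n_z) * g.dz - c[2]
    yy = np.arange(n_y) * g.dy - c[1]
    xx = np.arange(n_x) * g.dx - c[0]
    r = np.sqrt(
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    width_um = 3.0
    return config.shell_amplitude * np.exp(
        -0.5 * ((r - config.radius_um) / width_um) ** 2
    )
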