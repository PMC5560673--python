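import numpy as np
import pytest

from lsfmtrack import SimConfig, VoxelGeometry, simulate_tracks, render_timelapse


@pytest.fixture(scope="session")
def geometry():
    return VoxelGeometry()


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic acquisition: 5 cells on a 60 μm
    carrier in a 128×128×60 voxel volume, 8 frames."""
    cfg = SimConfig(
        n_cells=5,
        n_frames=8,
        volume_px=(128, 128, 60),
        sphere_diameter_um=60.0,
        step_um_per_frame=5.0,
        persistence=0.9,
        seed=2,
    )
    truth = simulate_tracks(cfg)
    timelapse = render_timelapse(truth, cfg)
    return cfg, truth, timelapse


def gaussian_spot_image(shape, cx, cy, sigma=3.0, amplitude=1000.0, background=10.0):
    yy, xx = np.indices(shape, dtype=float)
    return background + amplitude * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
    )


def gaussian_spot_stack(shape_zyx, cx, cy, cz, sigma_xy=3.0, sigma_z=2.0, amplitude=1000.0, background=10.0):
    nz, ny, nx = shape_zyx
    zz = ((np.arange(nz) - cz) / sigma_z) ** 2
    img = gaussian_spot_image((ny, nx), cx, cy, sigma_xy, 1.0, 0.0)
    vol = background + amplitude * np.exp(-0.5 * zz)[:, None, None] * img[None]
    return vol
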