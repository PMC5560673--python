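"""Reduce z-stacks to 2D images for tracking, keeping depth provenance.

The default projection is the maximum-intensity projection (MIP) along z;
each projected pixel also records the slice index that attained the maximum
(ties break to the lowest slice), so depth information is never discarded.
An extended-depth-of-field (full-focus) reconstruction is available as an
opt-in alternative: per pixel it samples the slice with the highest local
variance (a sharpness proxy), after median-smoothing the slice-label map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import ZStack

__all__ = ["ProjectedFrame", "max_intensity_projection", "extended_depth_of_field"]


@dataclass
class ProjectedFrame:
    """A 2D projection of one z-stack with per-pixel depth provenance.

    ``image[y, x] == stack[argmax_z[y, x], y, x]`` holds exactly for MIPs.
    """

    image: np.ndarray
    argmax_z: np.ndarray
    time_index: int = 0


def max_intensity_projection(stack: ZStack) -> ProjectedFrame:
    """Per-pixel maximum over z, with the argmax slice map.

    The argmax records the smallest slice index attaining the maximum.
    """
    vox = stack.voxels
    image = vox.max(axis=0)
    argmax_z = vox.argmax(axis=0)  # np.argmax returns the first (lowest) index
    return ProjectedFrame(image=image, argmax_z=argmax_z, time_index=stack.time_index)


def extended_depth_of_field(stack: ZStack, patch: int = 9) -> np.ndarray:
    """Full-focus 2D reconstruction by local-variance slice selection.

    Per pixel, the slice maximising the intensity variance within a
    ``patch`` × ``patch`` window is selected; the slice-label map is
    median-filtered with the same window before sampling so that the
    reconstruction does not flicker between slices at noise scale.

    Parameters
    ----------
    stack : ZStack
    patch : int
        Odd window size >= 3.
    """
    if patch < 3 or patch % 2 == 0:
        raise ValueError(f"patch must be odd and >= 3, got {patch}")
    vox = stack.voxels.astype(float)
    nz = vox.shape[0]
    if nz == 1:
        return stack.voxels[0].copy()

    sharpness = np.empty_like(vox)
    for z in range(nz):
        plane = vox[z]
        mean = ndimage.uniform_filter(plane, size=patch)
        mean_sq = ndimage.uniform_filter(plane * plane, size=patch)
        sharpness[z] = mean_sq - mean * mean

    labels = sharpness.argmax(axis=0)
    labels = ndimage.median_filter(labels, size=patch)
    rows, cols = np.indices(labels.shape)
    return stack.voxels[labels, rows, cols]
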