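"""Rigid alignment of z-stacks to a global reference frame.

Sample drift between time points is removed by registering every frame to a
chosen reference frame.  Lateral shift (Δx, Δy) is estimated by phase
correlation between the frame's maximum-intensity projection and the
reference's; axial shift Δz by 1D cross-correlation of the axial
mean-intensity profiles.  An optional user-supplied in-plane rotation is
applied first.  Stacks are resampled with linear interpolation and
out-of-frame voxels filled with 0.

Registration must follow the *static* scene content (carrier, background
structure), not the moving cells, so the MIPs are preprocessed before
correlation: Gaussian smoothing (sigma 2 px) suppresses the noise ceiling of
the projection, and clipping at the 75th percentile flattens the bright,
compact movers while keeping extended structure.  Each estimated shift is
then accepted only if it *improves* the normalised correlation of the
preprocessed projections over applying no shift at all ("do no harm");
otherwise a warning is issued and a zero shift recorded, as for a
low-confidence correlation peak.  Ties in the axial correlation peak break
towards the smallest-magnitude shift.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _rotate2d

from .image_model import TimeLapse, ZStack

__all__ = ["RigidTransform", "align_timelapse", "save_transforms"]

_SMOOTH_SIGMA = 2.0
_CLIP_PERCENTILE = 75.0


@dataclass(frozen=True)
class RigidTransform:
    """Rigid motion of one frame relative to the reference.

    ``shift`` is the (Δx, Δy, Δz) displacement, in voxels, of the frame's
    content relative to the reference; aligning applies the opposite
    translation.  ``rotation_deg`` is an in-plane rotation about the image
    centre, applied before the translation.
    """

    shift: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0

    def inverse(self) -> "RigidTransform":
        dx, dy, dz = self.shift
        return RigidTransform((-dx, -dy, -dz), -self.rotation_deg)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Translation composition (rotations add); exact for pure shifts."""
        return RigidTransform(
            tuple(a + b for a, b in zip(self.shift, other.shift)),
            self.rotation_deg + other.rotation_deg,
        )

    @property
    def is_identity(self) -> bool:
        return (
            max(abs(s) for s in self.shift) < 1e-6 and abs(self.rotation_deg) < 1e-6
        )


def _prep_mip(mip: np.ndarray) -> np.ndarray:
    """Structure-weighted view of a MIP for registration (see module doc).

    Clipped from above (75th percentile) to flatten bright compact movers
    and from below (10th percentile) so dark fill borders left by an
    earlier resampling carry no weight.
    """
    sm = gaussian_filter(np.asarray(mip, dtype=float), _SMOOTH_SIGMA)
    lo, hi = np.percentile(sm, (100.0 - _CLIP_PERCENTILE, _CLIP_PERCENTILE))
    return np.clip(sm, lo, hi)


def _masked_corr(a: np.ndarray, b: np.ndarray, margin: int) -> float:
    """Normalised correlation away from the shift-fill border."""
    if margin > 0:
        a = a[margin:-margin, margin:-margin]
        b = b[margin:-margin, margin:-margin]
    av = a.ravel() - a.mean()
    bv = b.ravel() - b.mean()
    denom = np.linalg.norm(av) * np.linalg.norm(bv)
    if denom == 0:
        return 1.0  # flat images are trivially registered
    return float(np.dot(av, bv) / denom)


def _axial_profile(voxels: np.ndarray) -> np.ndarray:
    """Mean intensity per slice after clipping bright movers.

    Voxels are clipped at median + 10 robust standard deviations (MAD-based)
    so compact bright cells barely perturb the profile while extended static
    structure and the background pass through.
    """
    vox = np.asarray(voxels)
    sample = vox[::4, ::4, ::4].astype(float)  # robust stats need no full copy
    med = np.median(sample)
    mad = np.median(np.abs(sample - med)) * 1.4826
    ceiling = vox.dtype.type(min(med + 10.0 * mad, np.iinfo(vox.dtype).max)) if (
        np.issubdtype(vox.dtype, np.integer)
    ) else med + 10.0 * mad
    prof = np.minimum(vox, ceiling).mean(axis=(1, 2), dtype=float)
    # zero-filled slices from an earlier resampling carry no information
    return np.maximum(prof, np.percentile(prof, 10.0))


def _axial_shift(profile: np.ndarray, reference: np.ndarray, margin: float = 0.01) -> float:
    """Lag of `profile` relative to `reference` maximising the per-lag
    normalised cross-correlation over the overlapping segment.

    Lags are limited to a quarter of the profile length.  The zero lag is
    kept unless some lag beats it by ``margin`` (absolute, on the
    correlation coefficient); remaining ties break towards the
    smallest-magnitude lag.
    """
    n = len(profile)
    if np.ptp(profile) == 0 or np.ptp(reference) == 0:
        return 0.0
    max_lag = max(1, n // 4)

    def ncc(lag: int) -> float:
        # positive lag: profile content sits `lag` slices above reference
        if lag >= 0:
            a, b = profile[lag:], reference[: n - lag]
        else:
            a, b = profile[: n + lag], reference[-lag:]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return float(np.dot(a, b) / denom) if denom > 0 else 0.0

    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.array([ncc(int(k)) for k in lags])
    zero_val = vals[lags == 0][0]
    peak = vals.max()
    if peak <= zero_val + margin:
        return 0.0
    candidates = lags[np.isclose(vals, peak, rtol=0, atol=1e-12)]
    return float(candidates[np.argmin(np.abs(candidates))])


def _apply_transform(voxels: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Resample a stack so the transformed content matches the reference."""
    out = np.asarray(voxels, dtype=float)
    if abs(transform.rotation_deg) > 1e-12:
        out = np.stack(
            [
                _rotate2d(s, -transform.rotation_deg, preserve_range=True, order=1)
                for s in out
            ]
        )
    dx, dy, dz = transform.shift
    if max(abs(dx), abs(dy), abs(dz)) > 1e-12:
        out = ndimage.shift(out, (-dz, -dy, -dx), order=1, mode="constant", cval=0.0)
    return out


def align_timelapse(
    timelapse: TimeLapse,
    reference_index: int = 0,
    rotations_deg: Sequence[float] | None = None,
    upsample_factor: int = 10,
    min_improvement: float = 0.005,
    in_place: bool = False,
) -> Tuple[TimeLapse, List[RigidTransform]]:
    """Register every frame of a time-lapse to a reference frame.

    Parameters
    ----------
    timelapse : TimeLapse
        Input frames (T >= 1).
    reference_index : int
        Frame used as the global reference; its transform is the identity.
    rotations_deg : sequence of float, optional
        User-supplied per-frame in-plane rotations, applied before shift
        estimation (manual override for rotated acquisitions).
    upsample_factor : int
        Sub-pixel refinement factor of the lateral phase correlation.
    min_improvement : float
        A lateral shift is applied only when it raises the normalised
        correlation of the preprocessed MIPs by at least this much over the
        unshifted frame; otherwise a warning is issued and a zero lateral
        shift recorded.
    in_place : bool
        Overwrite the input stacks instead of allocating a second
        time-lapse (halves peak memory for large acquisitions; the input
        object is returned, resampled).

    Returns
    -------
    (aligned, transforms)
        The resampled time-lapse (same dtype as input, linear interpolation,
        zero fill) and one :class:`RigidTransform` per frame.
    """
    T = len(timelapse)
    if not (0 <= reference_index < T):
        raise IndexError(f"reference_index {reference_index} out of range for T={T}")
    if rotations_deg is not None and len(rotations_deg) != T:
        raise ValueError("rotations_deg must give one angle per frame")

    ref_vox = timelapse[reference_index].voxels
    ref_prep = _prep_mip(ref_vox.max(axis=0))
    ref_profile = _axial_profile(ref_vox)

    dtype = timelapse[reference_index].voxels.dtype
    info = np.iinfo(dtype)
    transforms: List[RigidTransform] = []
    aligned_stacks: List[ZStack] = []

    for k in range(T):
        rot = float(rotations_deg[k]) if rotations_deg is not None else 0.0
        if k == reference_index and rot == 0.0:
            transforms.append(RigidTransform())
            aligned_stacks.append(
                timelapse[k] if in_place else ZStack(timelapse[k].voxels.copy(), k)
            )
            continue

        vox = timelapse[k].voxels
        if abs(rot) > 1e-12:
            vox = np.stack(
                [
                    _rotate2d(s, -rot, preserve_range=True, order=1)
                    for s in vox.astype(float)
                ]
            )
        prep = _prep_mip(vox.max(axis=0))
        # (drow, dcol) registers `prep` onto `ref_prep`; the content
        # displacement relative to the reference is its negation
        (drow, dcol), _, _ = phase_cross_correlation(
            ref_prep, prep, upsample_factor=upsample_factor, normalization=None
        )
        dx, dy = -float(dcol), -float(drow)

        margin = int(np.ceil(max(abs(drow), abs(dcol)))) + 1
        if max(abs(dx), abs(dy)) > 1e-9:
            moved = ndimage.shift(prep, (drow, dcol), order=1, mode="constant")
            gain = _masked_corr(moved, ref_prep, margin) - _masked_corr(
                prep, ref_prep, margin
            )
            if gain < min_improvement:
                warnings.warn(
                    f"frame {k}: lateral shift ({dx:.2f}, {dy:.2f}) does not "
                    f"improve registration (gain {gain:+.4f}); using zero shift",
                    stacklevel=2,
                )
                dx = dy = 0.0

        dz = _axial_shift(_axial_profile(vox), ref_profile)
        transform = RigidTransform((dx, dy, dz), rot)
        transforms.append(transform)
        if transform.is_identity:
            aligned_stacks.append(
                timelapse[k] if in_place else ZStack(timelapse[k].voxels.copy(), k)
            )
            continue
        moved_vox = _apply_transform(timelapse[k].voxels, transform)
        moved_vox = np.clip(np.rint(moved_vox), info.min, info.max).astype(dtype)
        if in_place:
            timelapse[k].voxels = moved_vox
            aligned_stacks.append(timelapse[k])
        else:
            aligned_stacks.append(ZStack(moved_vox, k))

    if in_place:
        return timelapse, transforms
    aligned = TimeLapse(
        aligned_stacks, geometry=timelapse.geometry, channel_name=timelapse.channel_name
    )
    return aligned, transforms


def save_transforms(
    transforms: Sequence[RigidTransform], path: Union[str, Path]
) -> None:
    """Export per-frame transforms as CSV (frame, dx, dy, dz, rot_deg)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "dx", "dy", "dz", "rot_deg"])
        for k, tr in enumerate(transforms):
            writer.writerow(
                [
                    k,
                    f"{tr.shift[0]:.6f}",
                    f"{tr.shift[1]:.6f}",
                    f"{tr.shift[2]:.6f}",
                    f"{tr.rotation_deg:.6f}",
                ]
            )
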