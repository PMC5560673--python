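"""Retrospective illumination (vignetting) correction.

Light-sheet images show a smooth multiplicative fall-off of brightness away
from the optical centre ("vignetting") plus a roughly additive dark level.
The model here is retrospective: it is estimated from the image collection
itself, without calibration frames.  Per pixel,

    observed(y, x) = gain(y, x) * signal(y, x) + offset(y, x)

The offset field is the smoothed per-pixel low quantile (q = 0.05) of the
collection — an estimate of the dark/background level — and the gain field
is the smoothed per-pixel robust mean (median) of the offset-subtracted
planes, normalised to unit mean.  Smoothing uses a Gaussian with sigma equal
to 2% of the image diagonal, enforcing the smooth, low-frequency character
of real shading.  Correction inverts the model:

    corrected = (observed - offset) / gain, clipped at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = ["IlluminationModel", "estimate_illumination", "correct_illumination"]

OFFSET_QUANTILE = 0.05
SMOOTH_DIAG_FRACTION = 0.02


class InsufficientDataError(ValueError):
    """Too few planes to estimate an illumination model."""


@dataclass
class IlluminationModel:
    """Per-pixel gain and offset fields describing vignetting.

    ``gain`` is strictly positive with unit mean; ``offset`` is non-negative
    and bounded by the per-pixel minimum of the training collection.
    """

    gain: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.gain.shape != self.offset.shape or self.gain.ndim != 2:
            raise ValueError("gain and offset must be 2D fields of equal shape")
        if not np.all(self.gain > 0):
            raise ValueError("gain must be strictly positive everywhere")
        if not np.all(self.offset >= 0):
            raise ValueError("offset must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.gain.shape

    def save(self, path: Union[str, Path]) -> None:
        """Save as a 2-page TIFF (gain, offset) with a JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(
            str(path),
            np.stack([self.gain, self.offset]).astype(np.float32),
            photometric="minisblack",
        )
        meta = {
            "pages": ["gain", "offset"],
            "shape": list(self.shape),
            "offset_quantile": OFFSET_QUANTILE,
            "smooth_sigma_fraction_of_diagonal": SMOOTH_DIAG_FRACTION,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "IlluminationModel":
        pages = tifffile.imread(str(path))
        return cls(gain=np.asarray(pages[0], float), offset=np.asarray(pages[1], float))


def _smooth_sigma(shape: tuple) -> float:
    return SMOOTH_DIAG_FRACTION * float(np.hypot(*shape))


def estimate_illumination(planes: Sequence[np.ndarray]) -> IlluminationModel:
    """Estimate gain and offset fields from a collection of 2D planes.

    The collection should sample many z-slices and/or time points so that
    true signal decorrelates across planes while the shading stays fixed.

    Per pixel: offset = Gaussian-smoothed 5% quantile across the collection;
    gain = Gaussian-smoothed median of (plane − offset), normalised to unit
    mean.  Smoothing sigma is 2% of the image diagonal.  For a constant
    collection the gain is identically 1 and the offset the constant (the
    quantile of identical values is that value).

    Raises
    ------
    InsufficientDataError
        If fewer than 2 planes are supplied.
    """
    stack = np.stack([np.asarray(p, dtype=float) for p in planes]) if planes else None
    if stack is None or stack.shape[0] < 2:
        raise InsufficientDataError(
            f"need at least 2 planes to estimate illumination, got "
            f"{0 if stack is None else stack.shape[0]}"
        )
    if stack.ndim != 3:
        raise ValueError("all planes must be 2D and share one shape")

    sigma = _smooth_sigma(stack.shape[1:])
    pix_min = stack.min(axis=0)
    offset = gaussian_filter(np.quantile(stack, OFFSET_QUANTILE, axis=0), sigma)
    # smoothing may lift the offset above the raw per-pixel minimum; clamp
    offset = np.clip(offset, 0.0, pix_min)

    residual = np.median(stack - offset, axis=0)
    gain = gaussian_filter(residual, sigma)
    mean_gain = gain.mean()
    if mean_gain <= 0 or not np.all(gain > 0):
        # degenerate (e.g. constant collection: residual ≈ 0): flat field
        gain = np.ones_like(gain)
    else:
        gain = gain / mean_gain
    return IlluminationModel(gain=gain, offset=offset)


def correct_illumination(
    image: np.ndarray, model: IlluminationModel
) -> np.ndarray:
    """Invert the shading model: ``(image − offset) / gain``, clipped at 0.

    Accepts a 2D plane or a 3D stack (applied per z-slice).  Output is
    real-valued.

    Raises
    ------
    ValueError
        If the plane shape does not match the model shape.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim not in (2, 3):
        raise ValueError(f"expected 2D or 3D input, got ndim={image.ndim}")
    if image.shape[-2:] != model.shape:
        raise ValueError(
            f"plane shape {image.shape[-2:]} does not match model shape {model.shape}"
        )
    corrected = (image - model.offset) / model.gain
    return np.clip(corrected, 0.0, None)
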