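"""Front end of the pipeline: green channel, vesselness, binarization.

Color fundus images are reduced to their green channel (the channel with
the best vessel/background contrast), passed through a multiscale Hessian
vesselness filter, rescaled to 8 bits, and thresholded at gray level 100
(strictly greater-than). The vesselness stage is prior art and is
delegated to an established implementation; any callable honoring the same
contract can be plugged in instead. The min–max rescaling from the
filter's native real range to [0, 255] is the main source of drift between
vesselness implementations, which is why the threshold level stays
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
from skimage import filters as _skfilters

from .core import require_gray_image

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrangiParams:
    """Multiscale vesselness parameters.

    ``scale_min``/``scale_max``/``scale_step`` define the Gaussian scale
    sweep in pixels; ``beta`` penalizes blob-like structures; ``gamma``
    controls sensitivity to overall structure contrast. ``invert=True``
    targets dark vessels on a bright background (fundus imagery); X-ray
    angiograms use ``invert=False``. The per-dataset parameter sets used in
    published benchmarks are not part of this package; these defaults are a
    reasonable multimodal starting point and are config-overridable.
    """

    scale_min: float = 1.0
    scale_max: float = 8.0
    scale_step: float = 1.0
    beta: float = 0.5
    gamma: float = 15.0
    invert: bool = True

    def __post_init__(self) -> None:
        if self.scale_min <= 0 or self.scale_max < self.scale_min or self.scale_step <= 0:
            raise ValueError("scale range must be non-empty with positive step")
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")

    @property
    def sigmas(self) -> np.ndarray:
        return np.arange(self.scale_min, self.scale_max + self.scale_step / 2, self.scale_step)


@dataclass(frozen=True)
class ThresholdSpec:
    """Gray-level threshold; ``strict=True`` keeps values strictly greater."""

    level: int = 100
    strict: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.level <= 255):
            raise ValueError("threshold level must lie in [0, 255]")


def extract_green_channel(image) -> np.ndarray:
    """Green channel of an RGB(A) image; gray input passes through unchanged.

    Images with 2 channels or more than 4 are rejected as ambiguous.
    """
    a = np.asarray(image)
    if a.ndim == 2:
        return require_gray_image(a)
    if a.ndim == 3 and a.shape[2] in (3, 4):
        return require_gray_image(a[:, :, 1])
    raise ValueError(
        f"expected a gray or 3/4-channel image, got shape {a.shape} (ambiguous layout)"
    )


def compute_vesselness(
    gray,
    params: FrangiParams = FrangiParams(),
    vesselness_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Multiscale Hessian vesselness response, rescaled to [0, 255].

    The response is computed by ``skimage.filters.frangi`` (or by
    ``vesselness_fn`` when supplied: a callable mapping a float image to a
    real-valued response) and linearly rescaled min->0, max->255. A
    constant input has no ridges and maps to all zeros.
    """
    g = require_gray_image(gray).astype(np.float64) / 255.0
    if vesselness_fn is not None:
        resp = np.asarray(vesselness_fn(g), dtype=np.float64)
        if resp.shape != g.shape:
            raise ValueError(
                f"vesselness_fn returned shape {resp.shape}, expected {g.shape}"
            )
    else:
        resp = _skfilters.frangi(
            g,
            sigmas=params.sigmas,
            beta=params.beta,
            gamma=params.gamma,
            black_ridges=params.invert,
        )
    lo, hi = float(resp.min()), float(resp.max())
    if hi <= lo:
        return np.zeros_like(resp, dtype=np.uint8)
    scaled = (resp - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def binarize(image, t: ThresholdSpec = ThresholdSpec()) -> np.ndarray:
    """Threshold a gray image into a binary vessel mask (white = vessel)."""
    g = require_gray_image(image)
    return g > t.level if t.strict else g >= t.level


def load_image(path) -> np.ndarray:
    """Read an 8-bit image from PNG/TIFF/JPEG; 16-bit input is right-shifted."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.dtype == np.uint16:
        logger.warning("%s is 16-bit; right-shifting to 8-bit", path)
        arr = (arr >> 8).astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        raise ValueError(f"unsupported image dtype {arr.dtype} in {path}")
    return arr
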