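"""Two-filter image enhancement: mean smoothing minus a Laplacian edge response.

The enhancement stage smooths pixel-to-pixel noise with a 6x6 average filter
(each pixel replaced by the mean of its 35 neighbors, the center excluded) and
sharpens cell boundaries by subtracting a discrete Laplacian response, then
clips the difference back to the [0, 255] intensity scale.  Both filters are
applied independently to the *input* image; clipping happens only after the
subtraction so negative Laplacian lobes survive into the difference.

An even window has no central cell: the 6x6 window covering pixel ``(r, c)``
spans rows ``[r-2, r+3]`` and columns ``[c-2, c+3]`` (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import as_image

__all__ = ["EnhancementConfig", "average_filter", "laplacian_filter", "enhance"]

_BORDER_TO_SCIPY = {"reflect": "reflect", "replicate": "nearest", "zero": "constant"}

LAPLACIAN_KERNELS = {
    4: np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]),
    8: np.array([[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]]),
}


@dataclass(frozen=True)
class EnhancementConfig:
    """Knobs of the enhancement stage.

    window_size
        Edge length of the average-filter window (default 6: 36 cells,
        35 neighbors with the center excluded).
    exclude_center
        Whether the window mean omits the pixel itself (default True).
    laplacian_connectivity
        4 for the [[0,1,0],[1,-4,1],[0,1,0]] kernel, 8 for the all-ones ring.
    border_mode
        One of ``reflect`` (edge-inclusive mirror), ``replicate`` (edge pixel
        repeated), ``zero``.
    """

    window_size: int = 6
    exclude_center: bool = True
    laplacian_connectivity: int = 4
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.window_size < 3:
            raise ValueError(f"window_size must be >= 3, got {self.window_size}")
        if self.laplacian_connectivity not in (4, 8):
            raise ValueError("laplacian_connectivity must be 4 or 8")
        if self.border_mode not in _BORDER_TO_SCIPY:
            raise ValueError(
                f"border_mode must be one of {sorted(_BORDER_TO_SCIPY)}, got {self.border_mode!r}"
            )


def _per_channel(image: np.ndarray, fn) -> np.ndarray:
    if image.ndim == 2:
        return fn(image)
    return np.dstack([fn(image[:, :, c]) for c in range(image.shape[2])])


def average_filter(image, config: EnhancementConfig = EnhancementConfig()) -> np.ndarray:
    """Windowed mean of each pixel's neighborhood, applied per channel.

    With the default 6x6 window and ``exclude_center`` every pixel becomes the
    mean of exactly 35 adjacent pixels.
    """
    arr = as_image(image)
    w = config.window_size
    if w > arr.shape[0] and w > arr.shape[1]:
        raise ValueError(
            f"window_size {w} exceeds both image dimensions {arr.shape[:2]}"
        )
    mode = _BORDER_TO_SCIPY[config.border_mode]
    # For even w, scipy's origin-0 window spans [r - w/2, r + w/2 - 1]; shift
    # by one to realize the documented [r - (w/2 - 1), r + w/2] anchor.
    origin = -1 if w % 2 == 0 else 0

    def _one(ch: np.ndarray) -> np.ndarray:
        window_sum = ndimage.uniform_filter(ch, size=w, mode=mode, origin=origin, cval=0.0) * (w * w)
        if config.exclude_center:
            return (window_sum - ch) / (w * w - 1)
        return window_sum / (w * w)

    return _per_channel(arr, _one)


def laplacian_filter(image, config: EnhancementConfig = EnhancementConfig()) -> np.ndarray:
    """Discrete Laplacian response, per channel; output is *not* clipped."""
    arr = as_image(image)
    kernel = LAPLACIAN_KERNELS[config.laplacian_connectivity]
    mode = _BORDER_TO_SCIPY[config.border_mode]
    return _per_channel(arr, lambda ch: ndimage.convolve(ch, kernel, mode=mode, cval=0.0))


def enhance(image, config: EnhancementConfig = EnhancementConfig()) -> np.ndarray:
    """Average-filtered image minus its Laplacian response, clipped to [0, 255]."""
    diff = average_filter(image, config) - laplacian_filter(image, config)
    return np.clip(diff, 0.0, 255.0)
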