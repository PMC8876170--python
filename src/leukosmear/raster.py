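"""Image representation, color handling and file I/O shared by every stage.

Images are plain :class:`numpy.ndarray` objects in ``float64``:

* grayscale — shape ``(H, W)``
* color — shape ``(H, W, 3)``, RGB channel order

Pixel coordinates are 0-based, row-major, origin at the top-left corner.
Intensities live on the ``[0, 255]`` scale but are *real valued* inside the
pipeline; quantization to 8-bit integers happens only on export.  This matters
because the enhancement stage produces negative and fractional mid-pipeline
values that must not be clipped prematurely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ImageRecord",
    "read_image",
    "write_image",
    "to_grayscale",
    "normalize_channels",
    "as_image",
    "read_manifest",
    "write_manifest",
]

_SUPPORTED_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}

#: ITU-R BT.601 luminance weights.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

LABELS = ("leukemia", "normal", "unlabeled")


@dataclass
class ImageRecord:
    """One dataset entry: an image, its class label and a unique identifier."""

    image: np.ndarray
    label: str
    source_id: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def as_image(values, channels: int | None = None) -> np.ndarray:
    """Validate and coerce ``values`` into a float64 raster image.

    Raises ``ValueError`` when the array is not a (H, W) or (H, W, 3) grid of
    finite values.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 2:
        got_channels = 1
    elif arr.ndim == 3 and arr.shape[2] == 3:
        got_channels = 3
    else:
        raise ValueError(f"expected (H, W) or (H, W, 3) array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"image must be at least 1x1, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image intensities must be finite")
    if channels is not None and got_channels != channels:
        raise ValueError(f"expected {channels}-channel image, got {got_channels}")
    return arr


def read_image(path: str | Path) -> np.ndarray:
    """Read PNG/JPG/TIFF/BMP from ``path``.

    Returns a 3-channel float image for color files and a single-channel image
    for grayscale files, intensities on [0, 255].
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported image format {path.suffix!r} for {path}; "
            f"supported: {sorted(_SUPPORTED_SUFFIXES)}"
        )
    if not path.exists():
        raise IOError(f"image file does not exist: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise IOError(f"could not read image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 257.0
    return as_image(arr.astype(np.float64))


def write_image(image, path: str | Path) -> None:
    """Quantize ``image`` to 8-bit and write it; format from the suffix."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported image format {path.suffix!r} for {path}")
    arr = as_image(image)
    quantized = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    kwargs = {}
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        kwargs["quality"] = 95
    iio.imwrite(path, quantized, **kwargs)


def to_grayscale(image) -> np.ndarray:
    """Luminance conversion 0.299 R + 0.587 G + 0.114 B; grayscale passes through."""
    arr = as_image(image)
    if arr.ndim == 2:
        return arr
    return arr @ LUMA_WEIGHTS


def normalize_channels(image) -> np.ndarray:
    """Gray-world color balancing of a 3-channel image.

    Each channel is scaled by (mean of the three channel means) / (that
    channel's mean) and the result clipped to [0, 255].  A channel whose mean
    is zero is left unscaled.
    """
    arr = as_image(image, channels=3)
    channel_means = arr.reshape(-1, 3).mean(axis=0)
    target = channel_means.mean()
    scale = np.where(channel_means > 0, target / np.where(channel_means > 0, channel_means, 1.0), 1.0)
    return np.clip(arr * scale, 0.0, 255.0)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV with columns source_id, path, label."""
    df = pd.read_csv(path, dtype=str)
    missing = {"source_id", "path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if df["source_id"].duplicated().any():
        dupes = df.loc[df["source_id"].duplicated(), "source_id"].tolist()
        raise ValueError(f"manifest {path} has duplicate source_ids: {dupes[:5]}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
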