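"""Dataset splitting and class-balanced geometric augmentation.

Splitting is stratified per class: the test partition takes
``round_half_up(test_fraction * class_size)`` records, then the remaining
pool is split again with ``round_half_up(validation_fraction_of_pool *
pool_size)`` for validation.  Round-half-up yields the partition
sizes 31/8/10 for a 49-record class and 38/9/12 for a 59-record class,
matching the ALL-IDB1-style benchmark layout.

Augmentation multiplies each *training* record into exactly ``factor``
images — the original plus ``factor - 1`` transformed copies sampled from
rotation (90/180/270 and +-15/+-30 degrees), horizontal/vertical flips,
crop-and-resize (keeping at least 80% per dimension) and shifts of up to 10%
with reflect padding.  Per-class factors are independent so unbalanced
classes can be equalized (e.g. x20 leukemia and x17 normal).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .raster import ImageRecord

__all__ = ["SplitSpec", "AugmentationSpec", "split", "augment", "round_half_up"]

ROTATION_ANGLES = (90.0, 180.0, 270.0, 15.0, -15.0, 30.0, -30.0)
OPERATIONS = ("rotation", "horizontal_flip", "vertical_flip", "crop_resize", "shift")


@dataclass(frozen=True)
class SplitSpec:
    """Stratified 3-way split: test fraction of the class, then validation
    fraction of the remaining pool."""

    test_fraction: float = 0.2
    validation_fraction_of_pool: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("test_fraction", "validation_fraction_of_pool"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class AugmentationSpec:
    """Per-class multiplication factors and the operation families to sample."""

    factors: dict = field(default_factory=lambda: {"leukemia": 20, "normal": 17})
    operations: tuple = OPERATIONS
    seed: int = 0
    include_original: bool = True

    def __post_init__(self) -> None:
        for label, f in self.factors.items():
            if int(f) < 1:
                raise ValueError(f"factor for class {label!r} must be >= 1")
        unknown = set(self.operations) - set(OPERATIONS)
        if unknown:
            raise ValueError(f"unknown operations {sorted(unknown)}")


def round_half_up(x: float) -> int:
    """Round to nearest with halves away from zero (for positive sizes)."""
    return int(np.floor(x + 0.5))


def split(records: list, spec: SplitSpec = SplitSpec()) -> list[str]:
    """Partition assignment (``train``/``validation``/``test``) per record.

    Deterministic under ``spec.seed``; partitions are disjoint, exhaustive
    and stratified by class.
    """
    labels = np.asarray([r.label for r in records])
    assignment = np.empty(len(records), dtype=object)
    rng = np.random.default_rng(spec.seed)
    classes = sorted(set(labels)) if spec.stratified else ["all"]
    for cls in classes:
        idx = np.flatnonzero(labels == cls) if spec.stratified else np.arange(len(records))
        n = idx.size
        n_test = round_half_up(spec.test_fraction * n)
        pool = n - n_test
        n_val = round_half_up(spec.validation_fraction_of_pool * pool)
        n_train = pool - n_val
        if min(n_train, n_val, n_test) < 1:
            raise ValueError(
                f"class {cls!r} with {n} records cannot populate all partitions")
        perm = rng.permutation(n)
        assignment[idx[perm[:n_train]]] = "train"
        assignment[idx[perm[n_train: n_train + n_val]]] = "validation"
        assignment[idx[perm[n_train + n_val:]]] = "test"
    return list(assignment)


def _record_rng(spec_seed: int, source_id: str) -> np.random.Generator:
    # Stable per-record stream: crc32 of the id mixed with the global seed.
    return np.random.default_rng((spec_seed, zlib.crc32(source_id.encode())))


def _apply_operation(image: np.ndarray, op: str, rng: np.random.Generator) -> np.ndarray:
    if op == "rotation":
        angle = ROTATION_ANGLES[rng.integers(len(ROTATION_ANGLES))]
        return sktransform.rotate(image, angle, resize=False, mode="reflect",
                                  preserve_range=True)
    if op == "horizontal_flip":
        return image[:, ::-1].copy()
    if op == "vertical_flip":
        return image[::-1, :].copy()
    if op == "crop_resize":
        h, w = image.shape[:2]
        fh, fw = rng.uniform(0.8, 1.0, 2)
        ch, cw = max(1, int(h * fh)), max(1, int(w * fw))
        r0 = rng.integers(0, h - ch + 1)
        c0 = rng.integers(0, w - cw + 1)
        crop = image[r0: r0 + ch, c0: c0 + cw]
        return sktransform.resize(crop, image.shape, preserve_range=True,
                                  anti_aliasing=True)
    if op == "shift":
        h, w = image.shape[:2]
        dy = rng.uniform(-0.1, 0.1) * h
        dx = rng.uniform(-0.1, 0.1) * w
        shift_vec = (dy, dx) if image.ndim == 2 else (dy, dx, 0.0)
        return ndimage.shift(image, shift_vec, mode="reflect", order=1)
    raise ValueError(f"unknown operation {op!r}")


def augment(records: list, spec: AugmentationSpec = AugmentationSpec()) -> list:
    """Expand each record into exactly ``factor`` images (original included).

    Output is deterministic under ``spec.seed``: each derived image is drawn
    from a per-record random stream, so the result does not depend on the
    order or number of other records.
    """
    out: list[ImageRecord] = []
    for record in records:
        factor = int(spec.factors.get(record.label, 1))
        rng = _record_rng(spec.seed, record.source_id)
        n_new = factor - 1 if spec.include_original else factor
        if spec.include_original:
            out.append(record)
        for j in range(n_new):
            op = spec.operations[rng.integers(len(spec.operations))]
            image = np.clip(_apply_operation(record.image, op, rng), 0.0, 255.0)
            out.append(ImageRecord(image=image, label=record.label,
                                   source_id=f"{record.source_id}_aug{j:03d}"))
    return out
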