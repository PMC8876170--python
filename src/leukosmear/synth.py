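"""Deterministic synthetic blood-smear generator with ground-truth masks.

Emulates stained peripheral-blood micrographs of the kind used for acute
lymphoblastic leukemia screening: a pale plasma background, red-cell discs
with central pallor, and one or more stained lymphocyte nuclei in the
blue-purple band.  The class signal is carried by nucleus *morphology*, the
clinically meaningful cue:

* ``normal`` — a single round, smooth nucleus (small radius);
* ``leukemia`` — a blast-like nucleus: larger radius, strongly perturbed
  (irregular) boundary, and often an extra overlapping lobe.

Both classes draw nucleus **color** from the same distribution, so a
classifier cannot shortcut through the color histogram alone and must exploit
texture / boundary-sensitive features.

Every sample is a pure function of ``(params, seed)``: identical inputs yield
bit-identical images and masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import write_image

__all__ = ["SmearSynthParams", "SmearSample", "generate_smear", "generate_records", "generate_dataset"]


@dataclass(frozen=True)
class SmearSynthParams:
    """Study conditions of the generator; defaults are the package's standard scene.

    Radii are in pixels at the default 512x512 canvas and scale linearly with
    ``size``.  ``blast_radius_mean`` deliberately exceeds ``normal_radius_mean``
    (enlarged blast nuclei); ``blast_irregularity`` drives the perturbed-polygon
    boundary; ``blast_lobe_prob`` adds a second overlapping nuclear lobe.
    """

    size: int = 512
    rbc_count_mean: float = 40.0
    background_rgb: tuple = (232.0, 210.0, 216.0)
    noise_sigma: float = 4.0
    rbc_rgb: tuple = (198.0, 122.0, 128.0)
    rbc_rgb_jitter: float = 10.0
    rbc_radius_mean: float = 18.0
    rbc_radius_sd: float = 3.0
    nucleus_rgb: tuple = (112.0, 72.0, 158.0)
    nucleus_rgb_jitter: float = 10.0
    wbc_count: int = 1
    normal_radius_mean: float = 20.0
    normal_radius_sd: float = 2.0
    normal_irregularity: float = 0.04
    normal_chromatin_amp: float = 3.0
    blast_radius_mean: float = 33.0
    blast_radius_sd: float = 4.0
    blast_irregularity: float = 0.22
    blast_lobe_prob: float = 0.5
    blast_chromatin_amp: float = 16.0
    chromatin_scale: float = 3.0
    edge_softness: float = 2.0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("canvas size must be at least 32 pixels")
        if self.wbc_count < 0:
            raise ValueError("wbc_count must be >= 0")
        if self.blast_radius_mean <= self.normal_radius_mean:
            raise ValueError("blast radius mean must exceed normal radius mean")
        max_shape = self.blast_radius_mean * (1 + self.blast_irregularity) * 2.2 * self.scale
        if max_shape > self.size:
            raise ValueError("nucleus shapes would exceed the image bounds at this size")

    @property
    def scale(self) -> float:
        return self.size / 512.0

    def digest(self) -> str:
        return sha256(repr(sorted(asdict(self).items())).encode()).hexdigest()[:16]


@dataclass
class SmearSample:
    """A generated smear image plus its ground truth."""

    image: np.ndarray          # (H, W, 3) float64, [0, 255]
    nucleus_mask: np.ndarray   # (H, W) bool — exactly the composited nucleus pixels
    label: str                 # "leukemia" | "normal"
    provenance: dict = field(default_factory=dict)


def _irregular_radius(theta: np.ndarray, base: float, irregularity: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Radius of a perturbed polygon: base radius modulated by low-order harmonics."""
    r = np.full_like(theta, base)
    for harmonic in range(2, 7):
        amp = irregularity * base * rng.uniform(0.2, 1.0) / (harmonic - 1)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(harmonic * theta + phase)
    return np.maximum(r, base * 0.3)


def _stamp_shape(canvas: np.ndarray, center: tuple, base_radius: float,
                 irregularity: float, color: np.ndarray, softness: float,
                 rng: np.random.Generator, mask: np.ndarray | None = None,
                 pallor: float = 0.0, chromatin_amp: float = 0.0,
                 chromatin_scale: float = 3.0) -> None:
    """Composite one soft-edged (optionally irregular) disc onto the canvas.

    ``chromatin_amp`` adds a spatially correlated luminance mottle inside the
    shape (the chromatin texture of a stained nucleus): a smoothed Gaussian
    field with the given amplitude, identical across color channels so the
    mean color is untouched.
    """
    size = canvas.shape[0]
    cy, cx = center
    reach = int(np.ceil(base_radius * (1 + irregularity * 2) + softness + 2))
    y0, y1 = max(0, int(cy) - reach), min(size, int(cy) + reach + 1)
    x0, x1 = max(0, int(cx) - reach), min(size, int(cx) + reach + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    radius = _irregular_radius(theta, base_radius, irregularity, rng)
    alpha = np.clip((radius - dist) / max(softness, 1e-6) + 0.5, 0.0, 1.0)
    if pallor > 0:  # lighter disc center (red-cell central pallor)
        inner = np.clip(1.0 - dist / (0.45 * base_radius), 0.0, 1.0)
        alpha = alpha * (1.0 - pallor * inner)
    shade = color[None, None, :]
    if chromatin_amp > 0:
        field = ndimage.gaussian_filter(
            rng.normal(size=alpha.shape), sigma=max(chromatin_scale, 0.5))
        sd = field.std()
        if sd > 0:
            field = field / sd * chromatin_amp
        shade = np.clip(shade + field[..., None], 0.0, 255.0)
    region = canvas[y0:y1, x0:x1]
    region[:] = region * (1.0 - alpha[..., None]) + shade * alpha[..., None]
    if mask is not None:
        mask[y0:y1, x0:x1] |= alpha >= 0.5


def generate_smear(params: SmearSynthParams, seed: int, label: str = "normal") -> SmearSample:
    """Generate one smear image with its nucleus ground-truth mask."""
    if label not in ("leukemia", "normal"):
        raise ValueError(f"label must be 'leukemia' or 'normal', got {label!r}")
    rng = np.random.default_rng(seed)
    size, scale = params.size, params.scale
    canvas = np.ones((size, size, 3)) * np.asarray(params.background_rgb)
    nucleus_mask = np.zeros((size, size), dtype=bool)

    n_rbc = rng.poisson(params.rbc_count_mean)
    for _ in range(n_rbc):
        center = (rng.uniform(0, size), rng.uniform(0, size))
        radius = max(4.0, rng.normal(params.rbc_radius_mean, params.rbc_radius_sd)) * scale
        color = np.asarray(params.rbc_rgb) + rng.normal(0, params.rbc_rgb_jitter, 3)
        _stamp_shape(canvas, center, radius, 0.03, color, params.edge_softness,
                     rng, pallor=0.45)

    margin = (params.blast_radius_mean * 1.8 + 8) * scale
    for _ in range(params.wbc_count):
        center = (rng.uniform(margin, size - margin), rng.uniform(margin, size - margin))
        color = np.asarray(params.nucleus_rgb) + rng.normal(0, params.nucleus_rgb_jitter, 3)
        chrom_scale = max(params.chromatin_scale * scale, 0.8)
        if label == "leukemia":
            radius = max(6.0, rng.normal(params.blast_radius_mean, params.blast_radius_sd)) * scale
            irregularity = params.blast_irregularity
            _stamp_shape(canvas, center, radius, irregularity, color,
                         params.edge_softness, rng, mask=nucleus_mask,
                         chromatin_amp=params.blast_chromatin_amp,
                         chromatin_scale=chrom_scale)
            if rng.uniform() < params.blast_lobe_prob:
                angle = rng.uniform(0, 2 * np.pi)
                offset = 0.8 * radius
                lobe_center = (center[0] + offset * np.sin(angle),
                               center[1] + offset * np.cos(angle))
                _stamp_shape(canvas, lobe_center, 0.55 * radius, irregularity, color,
                             params.edge_softness, rng, mask=nucleus_mask,
                             chromatin_amp=params.blast_chromatin_amp,
                             chromatin_scale=chrom_scale)
        else:
            radius = max(6.0, rng.normal(params.normal_radius_mean, params.normal_radius_sd)) * scale
            _stamp_shape(canvas, center, radius, params.normal_irregularity, color,
                         params.edge_softness, rng, mask=nucleus_mask,
                         chromatin_amp=params.normal_chromatin_amp,
                         chromatin_scale=chrom_scale)

    canvas += rng.normal(0, params.noise_sigma, canvas.shape)
    np.clip(canvas, 0.0, 255.0, out=canvas)
    provenance = {"seed": int(seed), "params_digest": params.digest(), "label": label}
    return SmearSample(image=canvas, nucleus_mask=nucleus_mask, label=label,
                       provenance=provenance)


def generate_records(n_per_class: int, params: SmearSynthParams, seed: int) -> list[SmearSample]:
    """A balanced in-memory dataset: ``n_per_class`` samples of each class.

    Sample ``i`` of class ``c`` is generated with the derived seed
    ``seed * 100000 + index`` so individual samples can be regenerated alone.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    samples = []
    idx = 0
    for label in ("leukemia", "normal"):
        for _ in range(n_per_class):
            samples.append(generate_smear(params, seed * 100000 + idx, label=label))
            idx += 1
    return samples


def generate_dataset(n_per_class: int, params: SmearSynthParams, seed: int,
                     out_dir: str | Path) -> pd.DataFrame:
    """Write images/, masks/ and manifest.csv for a balanced synthetic dataset."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    mask_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sample in enumerate(generate_records(n_per_class, params, seed)):
        source_id = f"synth_{sample.label}_{i:04d}"
        img_path = img_dir / f"{source_id}.png"
        write_image(sample.image, img_path)
        write_image(sample.nucleus_mask.astype(float) * 255.0, mask_dir / f"{source_id}.png")
        rows.append({"source_id": source_id, "path": str(img_path), "label": sample.label})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
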