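"""Handcrafted ROI descriptors: LBP, GLCM (Haralick) and fuzzy color histogram.

Three texture/color descriptors are computed over the refined nucleus ROI and
fused by concatenation into one 232-entry vector:

======== ======= ============================================================
segment  length  content
======== ======= ============================================================
LBP      203     histogram of 24-neighbor local binary pattern codes
GLCM     13      Haralick statistics of the gray co-occurrence matrix,
                 averaged over four offsets
FCH      16      (fuzzy) color histogram over coarse RGB bins
======== ======= ============================================================

The LBP neighborhood is the 24-pixel ring of the 5x5 square window.  No
standard histogram of a 24-bit code space has 203 bins (uniform
rotation-invariant coding gives 26, full uniform coding 555); the fixed
203-entry dimensionality is realized by fixed-width binning of the code range:
``bin = floor(code * n_bins / 2**P)``.  Pixels outside the ROI mask never
contribute to any descriptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .raster import as_image

__all__ = [
    "LBPParams",
    "GLCMParams",
    "FCHParams",
    "FeatureVector",
    "lbp_histogram",
    "glcm_features",
    "fch_features",
    "fuse_features",
    "LBP_LENGTH",
    "GLCM_LENGTH",
    "FCH_LENGTH",
    "FUSED_LENGTH",
    "SEGMENT_OFFSETS",
    "GLCM_STAT_NAMES",
    "feature_names",
]

logger = logging.getLogger(__name__)

LBP_LENGTH = 203
GLCM_LENGTH = 13
FCH_LENGTH = 16
FUSED_LENGTH = LBP_LENGTH + GLCM_LENGTH + FCH_LENGTH
#: start index of each segment in the fused vector
SEGMENT_OFFSETS = (0, LBP_LENGTH, LBP_LENGTH + GLCM_LENGTH)


@dataclass(frozen=True)
class LBPParams:
    """Local-binary-pattern knobs: 5x5 square ring (radius 2, 24 neighbors)."""

    radius: int = 2
    neighbor_count: int = 24
    n_bins: int = LBP_LENGTH
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        window = (2 * self.radius + 1) ** 2 - 1
        if self.neighbor_count != window:
            raise ValueError(
                f"neighbor_count must equal the window neighbor count {window} "
                f"for radius {self.radius}"
            )
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass(frozen=True)
class GLCMParams:
    """Co-occurrence knobs: distance-1 axial and sqrt(2) diagonal offsets.

    Displacements per angle: 0 deg -> (0, 1); 45 deg -> (-1, 1);
    90 deg -> (-1, 0); 135 deg -> (-1, -1).
    """

    gray_levels: int = 16
    offsets: tuple = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if not self.offsets:
            raise ValueError("offsets must be nonempty")


@dataclass(frozen=True)
class FCHParams:
    """Color-histogram knobs: 16 coarse RGB bins (4 x 2 x 2 over R x G x B)."""

    n_bins: int = FCH_LENGTH
    membership: str = "crisp"
    fuzzy_width: float = 0.5

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.membership not in ("crisp", "fuzzy"):
            raise ValueError("membership must be 'crisp' or 'fuzzy'")
        if not (0.0 < self.fuzzy_width <= 1.0):
            raise ValueError("fuzzy_width must be in (0, 1]")


@dataclass
class FeatureVector:
    """The fused 232-entry descriptor with a fixed segment layout."""

    values: np.ndarray
    names: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (FUSED_LENGTH,):
            raise ValueError(f"fused vector must have length {FUSED_LENGTH}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fused vector must be finite")

    @property
    def lbp(self) -> np.ndarray:
        return self.values[: SEGMENT_OFFSETS[1]]

    @property
    def glcm(self) -> np.ndarray:
        return self.values[SEGMENT_OFFSETS[1]: SEGMENT_OFFSETS[2]]

    @property
    def fch(self) -> np.ndarray:
        return self.values[SEGMENT_OFFSETS[2]:]


def feature_names() -> tuple:
    return tuple(
        [f"lbp_{i:03d}" for i in range(LBP_LENGTH)]
        + [f"glcm_{i:02d}" for i in range(GLCM_LENGTH)]
        + [f"fch_{i:02d}" for i in range(FCH_LENGTH)]
    )


def ring_offsets(radius: int) -> list[tuple[int, int]]:
    """Neighbor offsets of the (2R+1)x(2R+1) window, center excluded.

    The 24 neighbors of the default 5x5 window form two concentric square
    rings; each ring is enumerated clockwise starting at its top-left corner,
    outermost ring first.  Bit ``p`` of the LBP code corresponds to the
    ``p``-th offset of this list.
    """
    offsets: list[tuple[int, int]] = []
    for r in range(radius, 0, -1):
        top = [(-r, c) for c in range(-r, r + 1)]
        right = [(dr, r) for dr in range(-r + 1, r + 1)]
        bottom = [(r, c) for c in range(r - 1, -r - 1, -1)]
        left = [(dr, -r) for dr in range(r - 1, -r, -1)]
        offsets.extend(top + right + bottom + left)
    return offsets


def lbp_histogram(gray, roi, params: LBPParams = LBPParams()) -> np.ndarray:
    """Histogram of LBP codes over ROI pixels with a full 5x5 window in-bounds.

    The code of a center ``g_c`` is ``sum_p s(g_p - g_c) 2**p`` with
    ``s(c) = 1`` iff ``c >= 0``; codes are binned by
    ``floor(code * n_bins / 2**P)`` and the histogram normalized to sum 1
    (for a nonempty ROI, when ``normalize``).
    """
    arr = as_image(gray)
    if arr.ndim != 2:
        raise ValueError("lbp_histogram expects a single-channel image")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != arr.shape:
        raise ValueError("roi shape must match the image")
    r = params.radius
    valid = np.zeros_like(roi)
    if arr.shape[0] > 2 * r and arr.shape[1] > 2 * r:
        valid[r:-r, r:-r] = roi[r:-r, r:-r]
    if not valid.any():
        logger.warning("lbp_histogram: empty ROI, returning a zero histogram")
        return np.zeros(params.n_bins)

    center = arr[r:-r, r:-r]
    codes = np.zeros(center.shape, dtype=np.int64)
    for p, (dr, dc) in enumerate(ring_offsets(r)):
        neighbor = arr[r + dr: arr.shape[0] - r + dr or None,
                       r + dc: arr.shape[1] - r + dc or None]
        codes += ((neighbor - center) >= 0).astype(np.int64) << p
    codes = codes[valid[r:-r, r:-r]]
    bins = (codes * params.n_bins) >> params.neighbor_count
    hist = np.bincount(bins, minlength=params.n_bins).astype(np.float64)
    if params.normalize:
        hist /= hist.sum()
    return hist


def _quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of [0, 255] intensities into ``levels`` levels."""
    return np.minimum((gray * levels / 256.0).astype(np.int64), levels - 1)


def cooccurrence_matrix(gray, roi, offset: tuple[int, int],
                        params: GLCMParams = GLCMParams()) -> np.ndarray:
    """Normalized (and optionally symmetrized) co-occurrence matrix for one offset.

    Only pixel pairs with both members inside the ROI are counted.  Returns a
    ``gray_levels x gray_levels`` matrix summing to 1, or all zeros when no
    pair co-occurs.
    """
    arr = as_image(gray)
    roi = np.asarray(roi, dtype=bool)
    lv = _quantize(arr, params.gray_levels)
    dr, dc = offset
    H, W = arr.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr: r1 + dr, c0 + dc: c1 + dc]
    both = roi[r0:r1, c0:c1] & roi[r0 + dr: r1 + dr, c0 + dc: c1 + dc]
    n = params.gray_levels
    if not both.any():
        return np.zeros((n, n))
    counts = np.bincount((a[both] * n + b[both]), minlength=n * n).reshape(n, n).astype(np.float64)
    if params.symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def haralick_statistics(P: np.ndarray) -> np.ndarray:
    """The 13 canonical Haralick statistics of a normalized co-occurrence matrix.

    Order: angular second moment, contrast, correlation, sum of squares
    variance, inverse difference moment, sum average, sum variance, sum
    entropy, entropy, difference variance, difference entropy, and the two
    information measures of correlation.  Entropies use natural logarithms;
    0 log 0 is taken as 0; correlation-type statistics with a zero
    denominator are reported as 0.
    """
    n = P.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    def _ent(p):
        p = p[p > 0]
        return -(p * np.log(p)).sum()

    # p_{x+y}(k), k = i + j, and p_{x-y}(k), k = |i - j|
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), P.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())
    ks = np.arange(2 * n - 1, dtype=np.float64)
    kd = np.arange(n, dtype=np.float64)

    asm = (P**2).sum()
    contrast = (kd**2 * p_diff).sum()
    if sd_x > 0 and sd_y > 0:
        correlation = ((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 0.0
    variance = ((ii - mu_x) ** 2 * P).sum()
    idm = (P / (1.0 + (ii - jj) ** 2)).sum()
    sum_avg = (ks * p_sum).sum()
    sum_var = ((ks - sum_avg) ** 2 * p_sum).sum()
    sum_ent = _ent(p_sum)
    entropy = _ent(P.ravel())
    diff_avg = (kd * p_diff).sum()
    diff_var = ((kd - diff_avg) ** 2 * p_diff).sum()
    diff_ent = _ent(p_diff)
    # information measures of correlation
    pxy = np.outer(px, py)
    mask = (P > 0) & (pxy > 0)
    hxy = entropy
    hxy1 = -(P[mask] * np.log(pxy[mask])).sum()
    m2 = pxy > 0
    hxy2 = -(pxy[m2] * np.log(pxy[m2])).sum()
    hx, hy = _ent(px), _ent(py)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    return np.array([asm, contrast, correlation, variance, idm, sum_avg,
                     sum_var, sum_ent, entropy, diff_var, diff_ent, imc1, imc2])


GLCM_STAT_NAMES = (
    "angular_second_moment", "contrast", "correlation", "sum_of_squares_variance",
    "inverse_difference_moment", "sum_average", "sum_variance", "sum_entropy",
    "entropy", "difference_variance", "difference_entropy",
    "information_correlation_1", "information_correlation_2",
)


def glcm_features(gray, roi, params: GLCMParams = GLCMParams()) -> np.ndarray:
    """13 Haralick statistics averaged over the four co-occurrence offsets."""
    arr = as_image(gray)
    if arr.ndim != 2:
        raise ValueError("glcm_features expects a single-channel image")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != arr.shape:
        raise ValueError("roi shape must match the image")
    stats = []
    for offset in params.offsets:
        P = cooccurrence_matrix(arr, roi, offset, params)
        if P.sum() > 0:
            stats.append(haralick_statistics(P))
    if not stats:
        logger.warning("glcm_features: no co-occurring ROI pair for any offset")
        return np.zeros(GLCM_LENGTH)
    return np.mean(stats, axis=0)


def _fch_bin_edges(n_bins: int) -> tuple[int, int, int]:
    """Factor n_bins into (R, G, B) bin counts, R taking the largest factor."""
    if n_bins == FCH_LENGTH:
        return 4, 2, 2
    return n_bins, 1, 1  # generic fallback: bin the red channel only


def fch_features(image, roi, params: FCHParams = FCHParams()) -> np.ndarray:
    """Color histogram over coarse RGB bins, restricted to the ROI.

    Crisp mode is the literal indicator rule (a pixel belongs entirely to the
    bin containing it); fuzzy mode splits each channel's membership between
    the pixel's bin and the nearest neighboring bin with a triangular weight
    (``fuzzy_width`` scaling the share handed over), memberships multiplying
    across channels and summing to 1 per pixel.  The histogram of a nonempty
    ROI sums to 1.
    """
    arr = as_image(image, channels=3)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != arr.shape[:2]:
        raise ValueError("roi shape must match the image")
    if not roi.any():
        logger.warning("fch_features: empty ROI, returning a zero histogram")
        return np.zeros(params.n_bins)
    shape = _fch_bin_edges(params.n_bins)
    pixels = arr[roi]  # (n, 3)
    n_px = pixels.shape[0]
    hist = np.zeros(shape)
    if params.membership == "crisp":
        idx = tuple(
            np.minimum((pixels[:, c] * shape[c] / 256.0).astype(np.int64), shape[c] - 1)
            for c in range(3)
        )
        np.add.at(hist, idx, 1.0)
    else:
        per_channel = []  # [(own_bin, neigh_bin, own_w, neigh_w), ...]
        for c in range(3):
            nb = shape[c]
            width = 256.0 / nb
            pos = pixels[:, c] / width
            own = np.minimum(pos.astype(np.int64), nb - 1)
            frac = pos - own - 0.5  # signed distance from bin center, in bins
            neigh = np.clip(own + np.sign(frac).astype(np.int64), 0, nb - 1)
            share = params.fuzzy_width * np.abs(frac)
            share[neigh == own] = 0.0
            per_channel.append((own, neigh, 1.0 - share, share))
        for b0 in range(2):
            o0, n0, w0, s0 = per_channel[0]
            i0, v0 = (o0, w0) if b0 == 0 else (n0, s0)
            for b1 in range(2):
                o1, n1, w1, s1 = per_channel[1]
                i1, v1 = (o1, w1) if b1 == 0 else (n1, s1)
                for b2 in range(2):
                    o2, n2, w2, s2 = per_channel[2]
                    i2, v2 = (o2, w2) if b2 == 0 else (n2, s2)
                    np.add.at(hist, (i0, i1, i2), v0 * v1 * v2)
    return hist.ravel() / n_px


def fuse_features(lbp: np.ndarray, glcm: np.ndarray, fch: np.ndarray) -> FeatureVector:
    """Concatenate the three descriptor segments into the fused 232-entry vector."""
    lbp = np.asarray(lbp, dtype=np.float64)
    glcm = np.asarray(glcm, dtype=np.float64)
    fch = np.asarray(fch, dtype=np.float64)
    for name, seg, expected in (("lbp", lbp, LBP_LENGTH), ("glcm", glcm, GLCM_LENGTH),
                                ("fch", fch, FCH_LENGTH)):
        if seg.shape != (expected,):
            raise ValueError(f"{name} segment must have length {expected}, got shape {seg.shape}")
    return FeatureVector(values=np.concatenate([lbp, glcm, fch]), names=feature_names())


def extract_fused(image, gray, roi,
                  lbp_params: LBPParams = LBPParams(),
                  glcm_params: GLCMParams = GLCMParams(),
                  fch_params: FCHParams = FCHParams()) -> FeatureVector:
    """Convenience: all three descriptors of one ROI, fused."""
    return fuse_features(
        lbp_histogram(gray, roi, lbp_params),
        glcm_features(gray, roi, glcm_params),
        fch_features(image, roi, fch_params),
    )
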