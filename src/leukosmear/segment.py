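"""Adaptive region growing, lymphocyte-ROI selection and morphological refinement.

The segmentation contract is the classical four-condition one: the label map
must partition the image (exhaustive), every region must be 8-connected, the
homogeneity predicate ``P`` must hold within every region, and ``P`` must fail
on the union of any two remaining adjacent regions.

``P`` is an adaptive intensity band: region ``X`` satisfies ``P`` when every
pixel of ``X`` lies within ``k * max(std(X), 1)`` of ``mean(X)``.  Growth
admits an adjacent pixel against the *running* region statistics; because a
large noisy region always contains a few pixels beyond any ``k``-sigma band,
growth is followed by an ejection-repair loop (pixels outside the final band
are split off into new connected regions) and a merge pass that fuses every
adjacent pair whose union still satisfies ``P`` — with the union band scaled
by the pooled *within-region* std (see ``_pooled_std``).  The fixed point of
those two passes satisfies all four conditions by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .raster import as_image

__all__ = [
    "SegmentationParams",
    "StructuringElement",
    "RegionLabelMap",
    "region_grow",
    "select_roi",
    "morphological_refine",
    "verify_region_conditions",
]

logger = logging.getLogger(__name__)

_STD_FLOOR = 1.0


@dataclass(frozen=True)
class SegmentationParams:
    """Region-growing knobs.

    similarity_k
        Multiplier of the adaptive band: a pixel is admissible when its
        intensity is within ``similarity_k * max(std, 1)`` of the region mean.
    seed_spacing
        Regular grid spacing (pixels) of the initial seeds.
    min_region_area
        Smallest region (pixels) eligible as a nucleus ROI.
    connectivity
        4 or 8 neighborhood for growth and adjacency.
    """

    similarity_k: float = 2.5
    seed_spacing: int = 16
    min_region_area: int = 64
    connectivity: int = 8
    roi_saturation_min: float = 0.2
    roi_hue_range: tuple = (200.0, 320.0)

    def __post_init__(self) -> None:
        if self.similarity_k < 0:
            raise ValueError("similarity_k must be >= 0")
        if self.seed_spacing < 1:
            raise ValueError("seed_spacing must be >= 1")
        if self.min_region_area < 1:
            raise ValueError("min_region_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class StructuringElement:
    """Boolean morphology footprint; default the standard 5x5 square."""

    footprint: np.ndarray = field(default_factory=lambda: np.ones((5, 5), dtype=bool))

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.ndim != 2 or fp.shape[0] % 2 == 0 or fp.shape[1] % 2 == 0:
            raise ValueError("structuring element must be 2-D with odd edge lengths")
        if not fp.any():
            raise ValueError("structuring element must contain at least one true cell")
        object.__setattr__(self, "footprint", fp)


@dataclass
class RegionLabelMap:
    """Disjoint, exhaustive pixel labeling: 0 is never used, labels run 1..region_count."""

    labels: np.ndarray
    region_count: int


def _offsets(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return np.array([(-1, 0), (1, 0), (0, -1), (0, 1)])
    return np.array([(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)])


def _band(count: np.ndarray, total: np.ndarray, total_sq: np.ndarray, k: float):
    mean = total / count
    var = np.maximum(total_sq / count - mean**2, 0.0)
    return mean, k * np.maximum(np.sqrt(var), _STD_FLOOR)


def _pooled_std(c1, t1, tsq1, c2, t2, tsq2):
    """Pooled within-region standard deviation of two regions.

    The union homogeneity test scales its band by the regions' *internal*
    noise rather than the union's own spread: a balanced mix of two far-apart
    intensity modes has a spread proportional to the mode separation, so a
    band built from the union std would accept any such mix and adjacent
    regions would chain-merge regardless of contrast.
    """
    v1 = np.maximum(tsq1 / c1 - (t1 / c1) ** 2, 0.0)
    v2 = np.maximum(tsq2 / c2 - (t2 / c2) ** 2, 0.0)
    return np.sqrt((c1 * v1 + c2 * v2) / (c1 + c2))


def _grow_competitively(flat: np.ndarray, labels_flat: np.ndarray,
                        seeds: np.ndarray, first_label: int, shape: tuple,
                        offs: np.ndarray, k: float) -> int:
    """Synchronous breadth-first growth of many seed regions at once.

    All regions advance one wave per round; a pixel admissible to several
    regions in the same round goes to the one with the lowest label (pixels
    are processed in row-major order within a round).  Each pixel is judged
    once per region, when the wave first reaches it: re-testing rejected
    pixels after the statistics inflate would feed back (every admission
    widens the band, which admits more of an intensity ramp, without bound),
    so growth stops when every frontier is exhausted and unclaimed pixels
    seed later regions instead.

    Returns the number of regions created.
    """
    height, width = shape
    n_seeds = seeds.size
    labels_flat[seeds] = first_label + np.arange(n_seeds)
    # Region statistics indexed by (label - first_label).
    count = np.ones(n_seeds)
    total = flat[seeds].copy()
    total_sq = flat[seeds] ** 2

    frontier_pix = seeds.copy()
    frontier_reg = np.arange(n_seeds)
    while frontier_pix.size:
        rows, cols = np.divmod(frontier_pix, width)
        nr = rows[:, None] + offs[:, 0]
        nc = cols[:, None] + offs[:, 1]
        ok = (nr >= 0) & (nr < height) & (nc >= 0) & (nc < width)
        cand_pix = (nr * width + nc)[ok]
        cand_reg = np.broadcast_to(frontier_reg[:, None], nr.shape)[ok]
        keep = labels_flat[cand_pix] == 0
        cand_pix, cand_reg = cand_pix[keep], cand_reg[keep]
        if cand_pix.size == 0:
            break
        # Deduplicate (pixel, region) pairs, sorted row-major then by label.
        order = np.lexsort((cand_reg, cand_pix))
        cand_pix, cand_reg = cand_pix[order], cand_reg[order]
        first = np.ones(cand_pix.size, dtype=bool)
        first[1:] = (cand_pix[1:] != cand_pix[:-1]) | (cand_reg[1:] != cand_reg[:-1])
        cand_pix, cand_reg = cand_pix[first], cand_reg[first]

        mean = total / count
        band = k * np.maximum(np.sqrt(np.maximum(total_sq / count - mean**2, 0.0)), _STD_FLOOR)
        admit = np.abs(flat[cand_pix] - mean[cand_reg]) <= band[cand_reg]
        win_pix, win_reg = cand_pix[admit], cand_reg[admit]
        # Conflict resolution: lowest region label wins each pixel (input is
        # sorted by pixel then region already).
        first = np.ones(win_pix.size, dtype=bool)
        first[1:] = win_pix[1:] != win_pix[:-1]
        win_pix, win_reg = win_pix[first], win_reg[first]
        labels_flat[win_pix] = first_label + win_reg
        np.add.at(count, win_reg, 1.0)
        np.add.at(total, win_reg, flat[win_pix])
        np.add.at(total_sq, win_reg, flat[win_pix] ** 2)
        frontier_pix, frontier_reg = win_pix, win_reg
    return n_seeds


def _eject_outliers(labels: np.ndarray, flat_img: np.ndarray, k: float,
                    connectivity: int, max_rounds: int = 200) -> np.ndarray:
    """Split off pixels outside their region's final band until P holds everywhere.

    Terminates: a violating region strictly loses pixels each round and
    singleton regions always satisfy P (std floored at 1, deviation 0).
    """
    skimage_conn = 1 if connectivity == 4 else 2
    for _ in range(max_rounds):
        n_regions = labels.max()
        idx = labels.ravel()
        count = np.bincount(idx, minlength=n_regions + 1).astype(float)
        total = np.bincount(idx, weights=flat_img, minlength=n_regions + 1)
        total_sq = np.bincount(idx, weights=flat_img**2, minlength=n_regions + 1)
        count[0] = 1.0  # avoid 0/0 for the unused background id
        mean, band = _band(count, total, total_sq, k)
        viol = np.abs(flat_img - mean[idx]) > band[idx]
        if not viol.any():
            return labels
        viol2d = viol.reshape(labels.shape)
        kept = np.where(viol2d, 0, labels)
        relabeled = measure.label(kept, background=0, connectivity=skimage_conn)
        ejected = measure.label(viol2d, background=0, connectivity=skimage_conn)
        offset = relabeled.max()
        labels = np.where(viol2d, ejected + offset, relabeled)
    logger.warning("ejection repair did not converge in %d rounds", max_rounds)
    return labels


def _adjacent_pairs(labels: np.ndarray, connectivity: int) -> np.ndarray:
    pairs = []
    shifts = [(0, 1), (1, 0)] + ([(1, 1), (1, -1)] if connectivity == 8 else [])
    for dr, dc in shifts:
        a = labels[max(0, -dr): labels.shape[0] - max(0, dr),
                   max(0, -dc): labels.shape[1] - max(0, dc)]
        b = labels[max(0, dr):, max(0, dc):] if dc >= 0 else labels[max(0, dr):, :dc]
        p = np.stack([a.ravel(), b.ravel()], axis=1)
        p = p[p[:, 0] != p[:, 1]]
        pairs.append(p)
    allp = np.concatenate(pairs)
    allp.sort(axis=1)
    return np.unique(allp, axis=0)


def _merge_regions(labels: np.ndarray, flat_img: np.ndarray, k: float,
                   connectivity: int) -> np.ndarray:
    """Fuse adjacent regions whose union satisfies P, to a fixed point."""
    n = labels.max()
    idx = labels.ravel()
    count = np.bincount(idx, minlength=n + 1).astype(float)
    total = np.bincount(idx, weights=flat_img, minlength=n + 1)
    total_sq = np.bincount(idx, weights=flat_img**2, minlength=n + 1)
    vmin = np.full(n + 1, np.inf)
    vmax = np.full(n + 1, -np.inf)
    np.minimum.at(vmin, idx, flat_img)
    np.maximum.at(vmax, idx, flat_img)

    parent = np.arange(n + 1)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    pairs = _adjacent_pairs(labels, connectivity)
    while True:
        roots = _resolve_roots(parent)
        ra, rb = roots[pairs[:, 0]], roots[pairs[:, 1]]
        live = ra != rb
        if not live.any():
            break
        # Vectorized screen for mergeable pairs; merges are applied one at a
        # time below (each merge changes the statistics of its root).
        c = count[ra] + count[rb]
        t = total[ra] + total[rb]
        tsq = total_sq[ra] + total_sq[rb]
        mean = t / c
        band = k * np.maximum(_pooled_std(count[ra], total[ra], total_sq[ra],
                                          count[rb], total[rb], total_sq[rb]), _STD_FLOOR)
        hi = np.maximum(vmax[ra], vmax[rb])
        lo = np.minimum(vmin[ra], vmin[rb])
        passes = live & (hi - mean <= band) & (mean - lo <= band)
        if not passes.any():
            break
        merged_any = False
        for a, b in pairs[passes]:
            pa, pb = find(a), find(b)
            if pa == pb:
                continue
            cc = count[pa] + count[pb]
            tt = total[pa] + total[pb]
            ttsq = total_sq[pa] + total_sq[pb]
            m = tt / cc
            bd = k * max(_pooled_std(count[pa], total[pa], total_sq[pa],
                                     count[pb], total[pb], total_sq[pb]), _STD_FLOOR)
            hh = max(vmax[pa], vmax[pb])
            ll = min(vmin[pa], vmin[pb])
            if hh - m <= bd and m - ll <= bd:
                parent[pb] = pa
                count[pa], total[pa], total_sq[pa] = cc, tt, ttsq
                vmin[pa], vmax[pa] = ll, hh
                merged_any = True
        if not merged_any:
            break
    roots = _resolve_roots(parent)
    remap = np.zeros(n + 1, dtype=np.int32)
    final_ids = np.unique(roots[1:])
    remap[final_ids] = np.arange(1, final_ids.size + 1)
    return remap[roots[labels]]


def _resolve_roots(parent: np.ndarray) -> np.ndarray:
    roots = parent.copy()
    while True:
        nxt = roots[roots]
        if np.array_equal(nxt, roots):
            return roots
        roots = nxt


def region_grow(image, params: SegmentationParams = SegmentationParams()) -> RegionLabelMap:
    """Adaptive seeded region growing over a single-channel image.

    Seeds are placed on a regular grid (spacing ``seed_spacing``, row-major
    order); any pixel left unlabeled afterwards becomes a new seed, which
    guarantees an exhaustive partition.  See the module docstring for the
    repair and merge passes that enforce the homogeneity conditions.
    """
    arr = as_image(image)
    if arr.ndim != 2:
        raise ValueError("region_grow expects a single-channel image")
    height, width = arr.shape
    flat = arr.ravel()
    labels_flat = np.zeros(flat.size, dtype=np.int32)
    offs = _offsets(params.connectivity)
    k = params.similarity_k

    half = params.seed_spacing // 2
    seeds = np.array([r * width + c
                      for r in range(half, height, params.seed_spacing)
                      for c in range(half, width, params.seed_spacing)],
                     dtype=np.intp)
    next_label = 1
    next_label += _grow_competitively(flat, labels_flat, seeds, next_label,
                                      (height, width), offs, k)
    # Pixels no grown region would admit become new seeds (row-major label
    # order) and grow competitively among themselves until all are labeled.
    while True:
        remaining = np.flatnonzero(labels_flat == 0)
        if remaining.size == 0:
            break
        next_label += _grow_competitively(flat, labels_flat, remaining.astype(np.intp),
                                          next_label, (height, width), offs, k)

    labels = labels_flat.reshape(height, width)
    labels = _eject_outliers(labels, flat, k, params.connectivity)
    labels = _merge_regions(labels, flat, k, params.connectivity)
    return RegionLabelMap(labels=labels, region_count=int(labels.max()))


def verify_region_conditions(label_map: RegionLabelMap, image,
                             params: SegmentationParams = SegmentationParams()) -> dict:
    """Check the four segmentation conditions directly on a label map.

    Returns a dict of booleans: ``exhaustive``, ``connected``,
    ``predicate_within`` (P true on every region) and ``predicate_across``
    (P false on every adjacent pair).
    """
    arr = as_image(image)
    labels = label_map.labels
    flat = arr.ravel()
    idx = labels.ravel()
    n = label_map.region_count
    k = params.similarity_k
    skimage_conn = 1 if params.connectivity == 4 else 2

    exhaustive = bool((labels >= 1).all() and labels.max() == n)

    # Splitting each constant-value region into its connected components must
    # leave the component count unchanged iff every region is connected.
    connected = bool(measure.label(labels, background=0, connectivity=skimage_conn).max() == n)

    count = np.bincount(idx, minlength=n + 1).astype(float)
    total = np.bincount(idx, weights=flat, minlength=n + 1)
    total_sq = np.bincount(idx, weights=flat**2, minlength=n + 1)
    vmin = np.full(n + 1, np.inf)
    vmax = np.full(n + 1, -np.inf)
    np.minimum.at(vmin, idx, flat)
    np.maximum.at(vmax, idx, flat)
    count[0] = 1.0
    mean, band = _band(count, total, total_sq, k)
    within = (vmax[1:] - mean[1:] <= band[1:] + 1e-9) & (mean[1:] - vmin[1:] <= band[1:] + 1e-9)
    predicate_within = bool(within.all())

    pairs = _adjacent_pairs(labels, params.connectivity)
    if pairs.size:
        pa, pb = pairs[:, 0], pairs[:, 1]
        c = count[pa] + count[pb]
        t = total[pa] + total[pb]
        tsq = total_sq[pa] + total_sq[pb]
        m = t / c
        bd = k * np.maximum(_pooled_std(count[pa], total[pa], total_sq[pa],
                                        count[pb], total[pb], total_sq[pb]), _STD_FLOOR)
        mergeable = (np.maximum(vmax[pa], vmax[pb]) - m <= bd - 1e-9) & \
                    (m - np.minimum(vmin[pa], vmin[pb]) <= bd - 1e-9)
        predicate_across = bool(~mergeable.any())
    else:
        predicate_across = True

    return {
        "exhaustive": exhaustive,
        "connected": connected,
        "predicate_within": predicate_within,
        "predicate_across": predicate_across,
    }


def _rgb_to_hue_sat(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hue (degrees, [0, 360)) and saturation of rows of RGB values on [0, 255]."""
    rgb = rgb / 255.0
    cmax = rgb.max(axis=1)
    cmin = rgb.min(axis=1)
    delta = cmax - cmin
    sat = np.where(cmax > 0, delta / np.where(cmax > 0, cmax, 1.0), 0.0)
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    hue = np.zeros(rgb.shape[0])
    safe = np.where(delta > 0, delta, 1.0)
    is_r = (cmax == r) & (delta > 0)
    is_g = (cmax == g) & (delta > 0) & ~is_r
    is_b = (delta > 0) & ~is_r & ~is_g
    hue[is_r] = 60.0 * (((g[is_r] - b[is_r]) / safe[is_r]) % 6)
    hue[is_g] = 60.0 * ((b[is_g] - r[is_g]) / safe[is_g] + 2.0)
    hue[is_b] = 60.0 * ((r[is_b] - g[is_b]) / safe[is_b] + 4.0)
    return hue, sat


def select_roi(label_map: RegionLabelMap, image,
               params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Union of nucleus-like regions: saturated, blue-dominant mean color, big enough.

    Returns a boolean mask.  When no region qualifies the mask is empty and a
    warning is logged (grayscale inputs always land here: saturation is 0).
    """
    arr = as_image(image, channels=3)
    labels = label_map.labels
    if labels.shape != arr.shape[:2]:
        raise ValueError("label map and image shapes differ")
    n = label_map.region_count
    idx = labels.ravel()
    count = np.bincount(idx, minlength=n + 1).astype(float)
    means = np.stack([
        np.bincount(idx, weights=arr[:, :, c].ravel(), minlength=n + 1)
        for c in range(3)
    ], axis=1) / np.maximum(count, 1.0)[:, None]
    hue, sat = _rgb_to_hue_sat(means)
    lo, hi = params.roi_hue_range
    qualifies = (
        (sat >= params.roi_saturation_min)
        & (hue >= lo) & (hue <= hi)
        & (count >= params.min_region_area)
    )
    qualifies[0] = False
    if not qualifies.any():
        logger.warning("select_roi: no region qualifies as a nucleus ROI")
        return np.zeros(labels.shape, dtype=bool)
    return qualifies[labels]


def morphological_refine(mask, se: StructuringElement = StructuringElement()) -> np.ndarray:
    """Closing, interior hole filling, then opening with the structuring element.

    Holes are background components with no pixel on the image border;
    border-connected background is never filled.  The composite is idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    fp = se.footprint
    # Border convention: dilation pads with False, erosion with True, so a
    # mask touching the image border is not eroded away from outside.
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(mask, structure=fp, border_value=0),
        structure=fp, border_value=1)
    filled = ndimage.binary_fill_holes(closed)
    opened = ndimage.binary_dilation(
        ndimage.binary_erosion(filled, structure=fp, border_value=1),
        structure=fp, border_value=0)
    return opened
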