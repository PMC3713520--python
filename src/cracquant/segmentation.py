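"""Localized Otsu thresholding and connected-component labeling of puncta.

The segmentation recipe: the image is uniformly scaled to [0, 1] by
percentile stretch, partitioned into tiles, each tile receives its own Otsu
threshold, per-tile thresholds are bilinearly interpolated from tile centers
to every pixel (avoiding blocking seams), and the binary mask is
``scaled > threshold``. Tiles without enough dynamic range to support a
meaningful split receive a threshold above their own content, so flat or
empty regions contribute no foreground. Connected components below a
minimum area are discarded.

A tile covering the whole image reduces the procedure exactly to global
Otsu thresholding; this limit is used both as an invariant and to build the
global-Otsu comparison masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import maximum as ndi_max
from skimage import measure

from .types import Image2D, YFP

__all__ = [
    "NO_FOREGROUND",
    "SegmentationParams",
    "LabeledClusters",
    "scale_uniform",
    "otsu_threshold",
    "localized_threshold_map",
    "make_cluster_mask",
    "label_clusters",
    "filter_by_prominence",
    "segment_image",
    "global_otsu_mask",
]


class _NoForeground:
    """Sentinel: the value histogram supports no foreground/background split."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_FOREGROUND"


NO_FOREGROUND = _NoForeground()


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the localized-Otsu segmentation.

    tile_px
        Edge length of the square thresholding tiles. Tiles should span a
        few spot diameters: a single diffraction-limited spot must occupy a
        non-negligible fraction of its tile's histogram for Otsu to split
        it from the background rather than splitting the background itself.
    low_contrast_floor
        Minimum tile dynamic range, as a fraction of the global dynamic
        range, below which a tile is considered structure-free and given a
        threshold above its own maximum (no local foreground).
    min_prominence
        Minimum height of a component's brightest pixel above its local
        threshold, as a fraction of the scaled dynamic range. A genuine
        punctum towers above the threshold that detected it; a component
        that barely clears the threshold is a noise artifact of a tile
        whose histogram offered Otsu no real second class. 0 disables.
    """

    p_lo: float = 0.0
    p_hi: float = 100.0
    tile_px: int = 32
    low_contrast_floor: float = 0.15
    connectivity: int = 8
    min_area_px: int = 4
    min_prominence: float = 0.08
    mask_channel: str = YFP
    n_bins: int = 256

    def __post_init__(self) -> None:
        if not (0 <= self.p_lo < self.p_hi <= 100):
            raise ValueError("percentiles must satisfy 0 <= p_lo < p_hi <= 100")
        if self.tile_px < 8:
            raise ValueError("tile_px must be >= 8")
        if not (0 <= self.low_contrast_floor < 1):
            raise ValueError("low_contrast_floor must be in [0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if not (0 <= self.min_prominence < 1):
            raise ValueError("min_prominence must be in [0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class LabeledClusters:
    """Connected-component labels of detected puncta.

    ``labels`` is an integer grid with 0 = background and 1..n_clusters =
    clusters, numbered in raster order of each component's first pixel.
    """

    labels: np.ndarray
    n_clusters: int
    params: SegmentationParams

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size != self.n_clusters or (
            present.size and (present[0] != 1 or present[-1] != self.n_clusters)
        ):
            raise ValueError("labels must be consecutive 1..n_clusters")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def scale_uniform(
    image: Image2D | np.ndarray, p_lo: float = 0.0, p_hi: float = 100.0
) -> np.ndarray:
    """Uniformly scale an image into [0, 1] by percentile stretch.

    ``v -> clip((v - P_lo) / (P_hi - P_lo), 0, 1)`` where P_lo/P_hi are the
    p_lo-th/p_hi-th intensity percentiles. A constant image (P_hi == P_lo)
    maps to all zeros by convention.
    """
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    lo = np.percentile(px, p_lo)
    hi = np.percentile(px, p_hi)
    if hi <= lo:
        return np.zeros_like(px, dtype=float)
    return np.clip((px - lo) / (hi - lo), 0.0, 1.0)


def otsu_threshold(values: np.ndarray, n_bins: int = 256):
    """Otsu's threshold over an n_bins histogram of values in [0, 1].

    Returns the bin-edge threshold maximizing the between-class variance
    sigma_B^2(t) = w0(t) w1(t) (mu0(t) - mu1(t))^2, with classes
    ``v <= t`` and ``v > t``. Ties break toward the lower threshold. If no
    split yields positive between-class variance (e.g. constant input),
    :data:`NO_FOREGROUND` is returned.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("otsu_threshold requires at least one value")
    counts, edges = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    counts = counts.astype(float)
    total = counts.sum()
    if total == 0:
        return NO_FOREGROUND
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    sum0 = np.cumsum(counts * centers)[:-1]
    mu_total = float(np.sum(counts * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, sum0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (mu_total - sum0) / w1, 0.0)
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, 0.0)
    if not np.any(sigma_b > 0):
        return NO_FOREGROUND
    best = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    return float(edges[best + 1])


def _tile_edges(n: int, tile_px: int) -> list[tuple[int, int]]:
    """Non-overlapping [start, stop) tile spans; the last tile may be smaller."""
    starts = list(range(0, n, tile_px))
    return [(s, min(s + tile_px, n)) for s in starts]


def localized_threshold_map(scaled: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Per-pixel threshold grid from tile-wise Otsu thresholds.

    The scaled image is partitioned into ``tile_px`` x ``tile_px`` tiles
    (edge tiles may be smaller; a tile larger than the image degenerates to
    a single tile). Each tile gets its own Otsu threshold. Tiles whose
    dynamic range falls below ``low_contrast_floor`` times the global
    dynamic range — or whose histogram admits no split — are assigned a
    threshold equal to their own maximum value, so that under the strict
    ``>`` mask comparison they contribute no foreground of their own.
    Thresholds are bilinearly interpolated from tile centers to every pixel
    (clamped beyond the outermost centers) to avoid blocking seams.
    """
    scaled = np.asarray(scaled, dtype=float)
    h, w = scaled.shape
    global_range = float(scaled.max() - scaled.min())

    row_tiles = _tile_edges(h, params.tile_px)
    col_tiles = _tile_edges(w, params.tile_px)

    thr = np.empty((len(row_tiles), len(col_tiles)), dtype=float)
    r_centers = np.empty(len(row_tiles))
    c_centers = np.empty(len(col_tiles))
    for i, (r0, r1) in enumerate(row_tiles):
        r_centers[i] = 0.5 * (r0 + r1 - 1)
        for j, (c0, c1) in enumerate(col_tiles):
            c_centers[j] = 0.5 * (c0 + c1 - 1)
            tile = scaled[r0:r1, c0:c1]
            t_range = float(tile.max() - tile.min())
            t = otsu_threshold(tile, params.n_bins)
            low_contrast = t_range < params.low_contrast_floor * global_range
            if low_contrast or t is NO_FOREGROUND:
                thr[i, j] = float(tile.max())
            else:
                thr[i, j] = t

    if thr.size == 1:
        # single-tile degenerate case: constant map equal to the tile's own
        # threshold, which by construction is the global Otsu threshold
        return np.full((h, w), thr[0, 0])

    # bilinear interpolation from tile centers, clamped at the borders
    rr = np.clip(np.arange(h, dtype=float), r_centers[0], r_centers[-1])
    cc = np.clip(np.arange(w, dtype=float), c_centers[0], c_centers[-1])
    if len(r_centers) == 1:
        interp_rows = np.tile(thr[0, :], (1, 1))
        col_interp = np.interp(cc, c_centers, thr[0, :])
        return np.tile(col_interp, (h, 1))
    if len(c_centers) == 1:
        row_interp = np.interp(rr, r_centers, thr[:, 0])
        return np.tile(row_interp[:, None], (1, w))
    interp = RegularGridInterpolator(
        (r_centers, c_centers), thr, method="linear", bounds_error=False, fill_value=None
    )
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    return interp(np.stack([grid_r.ravel(), grid_c.ravel()], axis=1)).reshape(h, w)


def make_cluster_mask(
    image: Image2D | np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Binary cluster mask: scale, localized threshold map, strict compare.

    Definitionally equal to composing :func:`scale_uniform`,
    :func:`localized_threshold_map` and ``scaled > threshold_map``.
    """
    if params is None:
        params = SegmentationParams()
    scaled = scale_uniform(image, params.p_lo, params.p_hi)
    tmap = localized_threshold_map(scaled, params)
    return scaled > tmap


def label_clusters(
    mask: np.ndarray, connectivity: int = 8, min_area_px: int = 4,
    params: SegmentationParams | None = None,
) -> LabeledClusters:
    """Label connected components and drop those below the minimum area.

    Components are connected under 4- or 8-connectivity; surviving labels
    are renumbered 1..n in raster order of each component's first pixel.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    skim_conn = 1 if connectivity == 4 else 2
    raw = measure.label(mask, connectivity=skim_conn)
    n_raw = int(raw.max())
    if n_raw == 0:
        labels = np.zeros_like(raw)
        n = 0
    else:
        areas = np.bincount(raw.ravel(), minlength=n_raw + 1)
        keep = areas >= min_area_px
        keep[0] = False
        # skimage assigns labels in raster order of first pixel, so a rank
        # remap of the kept labels preserves that ordering
        remap = np.zeros(n_raw + 1, dtype=raw.dtype)
        remap[keep] = np.arange(1, int(keep.sum()) + 1)
        labels = remap[raw]
        n = int(keep.sum())
    if params is None:
        params = SegmentationParams(connectivity=connectivity, min_area_px=min_area_px)
    return LabeledClusters(labels=labels, n_clusters=n, params=params)


def filter_by_prominence(
    labeled: LabeledClusters,
    scaled: np.ndarray,
    threshold_map: np.ndarray,
    min_prominence: float,
) -> LabeledClusters:
    """Drop components whose peak barely clears their local threshold.

    A component is kept iff ``max(scaled - threshold_map)`` over its pixels
    is at least ``min_prominence`` times the scaled dynamic range. Labels
    are renumbered consecutively, preserving raster order.
    """
    if min_prominence <= 0 or labeled.n_clusters == 0:
        return labeled
    lab = labeled.labels
    rng = float(scaled.max() - scaled.min())
    if rng == 0:
        return labeled
    excess = scaled - threshold_map
    peaks = ndi_max(excess, lab, index=np.arange(1, labeled.n_clusters + 1))
    keep = np.concatenate([[False], np.asarray(peaks) >= min_prominence * rng])
    remap = np.zeros(labeled.n_clusters + 1, dtype=lab.dtype)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return LabeledClusters(remap[lab], int(keep.sum()), labeled.params)


def segment_image(
    image: Image2D | np.ndarray, params: SegmentationParams | None = None
) -> LabeledClusters:
    """Full segmentation of one image: mask, labels, component filters."""
    if params is None:
        params = SegmentationParams()
    scaled = scale_uniform(image, params.p_lo, params.p_hi)
    tmap = localized_threshold_map(scaled, params)
    mask = scaled > tmap
    labeled = label_clusters(mask, params.connectivity, params.min_area_px, params=params)
    return filter_by_prominence(labeled, scaled, tmap, params.min_prominence)


def global_otsu_mask(
    image: Image2D | np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Mask from a single global Otsu threshold (the single-tile limit)."""
    if params is None:
        params = SegmentationParams()
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=float)
    h, w = px.shape
    from dataclasses import replace

    single = replace(params, tile_px=max(h, w, 8))
    return make_cluster_mask(px, single)
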