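"""Marker-controlled watershed segmentation.

The binary cell mask is converted into a topological surface by negating
its Euclidean distance transform, so each cell interior becomes a
catchment basin that is deepest where the cell is thickest.  Markers are
the extended minima of that surface (regional minima deeper than ``h``),
imposed as the only minima before flooding.  Flooding is a deterministic
Meyer-style priority flood: pixels are processed in ascending height,
first-in-first-out within a height level; a pixel reached by two
distinct basins becomes a ridge pixel (label 0).

Surfaces are quantized to 0.1 px of distance before marker detection and
flooding so that the ordering of near-equal floats is reproducible.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima, reconstruction

from . import imgproc
from .config import PipelineConfig

__all__ = [
    "euclidean_distance_transform",
    "basin_surface",
    "quantize_surface",
    "regional_minima",
    "extended_minima",
    "impose_minima",
    "watershed_transform",
    "remove_small_labels",
    "segment_cells",
    "SegmentationResult",
]

_QUANT_STEP = 0.1


def _footprint(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    raise ValueError("connectivity must be 4 or 8")


# neighbor scan order is part of the deterministic flooding contract:
# raster order of the 8-neighborhood (4-neighbors are the subset)
_OFFSETS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
_OFFSETS4 = ((-1, 0), (0, -1), (0, 1), (1, 0))


def euclidean_distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance from each pixel to the nearest False pixel."""
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError(
            "mask has no background pixel; distances are undefined"
        )
    return ndi.distance_transform_edt(mask)


def basin_surface(mask: np.ndarray) -> np.ndarray:
    """Negated distance transform: cell interiors become catchment basins.

    Each foreground object turns into a depression whose floor lies at
    its thickest point; the background is a flat plateau at height 0.
    An empty mask therefore yields a flat surface.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=float)
    return -euclidean_distance_transform(mask)


def quantize_surface(surface: np.ndarray, step: float = _QUANT_STEP) -> np.ndarray:
    """Snap surface heights to multiples of ``step`` (default 0.1 px)."""
    return np.round(np.asarray(surface, dtype=float) / step) * step


def regional_minima(surface: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Boolean mask of regional minima (plateaus with all neighbors higher)."""
    surface = np.asarray(surface, dtype=float)
    if surface.size and np.ptp(surface) == 0:
        # a constant surface is one big minimum plateau
        return np.ones(surface.shape, dtype=bool)
    return local_minima(surface, connectivity=2 if connectivity == 8 else 1)


def extended_minima(surface: np.ndarray, h: float = 3.0, connectivity: int = 8) -> np.ndarray:
    """Markers: regional minima of the h-minima transform.

    The h-minima transform (grayscale reconstruction-by-erosion of
    ``surface + h`` under ``surface``) suppresses every minimum shallower
    than ``h``; the surviving minima are the marker components.
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    surface = np.asarray(surface, dtype=float)
    filled = reconstruction(
        surface + h, surface, method="erosion", footprint=_footprint(connectivity)
    )
    minima = regional_minima(filled, connectivity=connectivity)
    if minima.all():
        # suppression flattened the surface: no minimum is deeper than h
        return np.zeros_like(minima)
    return minima


def impose_minima(surface: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Force the regional minima of ``surface`` to be exactly ``markers``.

    Marker pixels are sunk to a sentinel below the global minimum and the
    surface is rebuilt by grayscale reconstruction-by-erosion, raising
    every non-marker minimum until it drains into a marker.
    """
    surface = np.asarray(surface, dtype=float)
    markers = np.asarray(markers, dtype=bool)
    if markers.shape != surface.shape:
        raise ValueError("marker mask shape must match the surface")
    if not markers.any():
        raise ValueError("marker mask is empty")
    lo = float(surface.min())
    hi = float(surface.max())
    delta = max((hi - lo) * 1e-3, 1e-6)
    sentinel = lo - (hi - lo) - 1.0
    seed = np.where(markers, sentinel, hi + delta)
    target = np.minimum(surface + delta, seed)
    return reconstruction(seed, target, method="erosion", footprint=_footprint(8))


def watershed_transform(
    surface: np.ndarray,
    connectivity: int = 8,
    markers: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Flood the surface; return one positive label per catchment basin.

    Seeds are the connected components of ``markers`` (or of the surface's
    regional minima when ``markers`` is None), labelled in raster order.
    Flooding proceeds in ascending quantized height with FIFO order inside
    each level; a pixel whose already-labelled neighbors carry two or more
    distinct labels becomes a ridge pixel and keeps label 0.  When
    ``mask`` is given, flooding is confined to it and everything outside
    stays background (label 0).
    """
    surface = quantize_surface(surface)
    h, w = surface.shape
    if mask is None:
        domain = np.ones((h, w), dtype=bool)
    else:
        domain = np.asarray(mask, dtype=bool)
        if domain.shape != surface.shape:
            raise ValueError("mask shape must match the surface")
    if markers is None:
        seeds = regional_minima(surface, connectivity=connectivity) & domain
    else:
        seeds = np.asarray(markers, dtype=bool) & domain
    seed_labels, n_seeds = ndi.label(seeds, structure=_footprint(connectivity))
    labels = np.zeros((h, w), dtype=np.int32)
    if n_seeds == 0:
        return labels

    offsets = _OFFSETS8 if connectivity == 8 else _OFFSETS4
    RIDGE = -1
    heap: list[tuple[float, int, int, int]] = []
    seq = 0

    labels[seeds] = seed_labels[seeds]
    # queue the unlabelled in-domain neighbors of every seed pixel,
    # scanning seed pixels in raster order
    for r, c in zip(*np.nonzero(seeds)):
        r, c = int(r), int(c)
        for dr, dc in offsets:
            q, s = r + dr, c + dc
            if 0 <= q < h and 0 <= s < w and domain[q, s] and labels[q, s] == 0:
                heapq.heappush(heap, (surface[q, s], seq, q, s))
                seq += 1

    while heap:
        _, _, r, c = heapq.heappop(heap)
        if labels[r, c] != 0:
            continue
        found = 0
        multiple = False
        for dr, dc in offsets:
            q, s = r + dr, c + dc
            if 0 <= q < h and 0 <= s < w:
                lab = labels[q, s]
                if lab > 0:
                    if found == 0:
                        found = lab
                    elif lab != found:
                        multiple = True
                        break
        if multiple:
            labels[r, c] = RIDGE
            continue
        if found == 0:
            # neighbor that enqueued this pixel later became a ridge;
            # requeue is unnecessary — another basin will reach it
            continue
        labels[r, c] = found
        for dr, dc in offsets:
            q, s = r + dr, c + dc
            if 0 <= q < h and 0 <= s < w and domain[q, s] and labels[q, s] == 0:
                heapq.heappush(heap, (surface[q, s], seq, q, s))
                seq += 1

    labels[labels == RIDGE] = 0
    return labels


def remove_small_labels(labels: np.ndarray, min_area: int = 500) -> np.ndarray:
    """Drop labelled regions smaller than ``min_area`` px; relabel 1..n.

    Survivors are renumbered consecutively in raster order of their first
    pixel, so label identity is reproducible across runs.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    labels = np.asarray(labels)
    flat = labels.ravel()
    counts = np.bincount(flat[flat > 0], minlength=int(flat.max(initial=0)) + 1)
    old, first_idx = np.unique(flat, return_index=True)
    keep = [(idx, lab) for lab, idx in zip(old, first_idx) if lab > 0 and counts[lab] >= min_area]
    keep.sort()  # raster order of first occurrence
    mapping = np.zeros(counts.size, dtype=np.int32)
    for new, (_, lab) in enumerate(keep, start=1):
        mapping[lab] = new
    return mapping[labels]


@dataclass
class SegmentationResult:
    """Output bundle of the full pipeline.

    ``labels`` is the final cell label map, ``mask`` the cleaned binary
    mask the surface was built from, ``gray`` the green channel of the
    resized frame (intensity statistics downstream are computed on it),
    and ``enhanced`` the contrast-equalized grayscale for inspection.
    """

    labels: np.ndarray
    mask: np.ndarray
    gray: np.ndarray
    enhanced: np.ndarray


def segment_cells(img: np.ndarray, config: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full darkfield segmentation pipeline on an RGB frame.

    Steps: standardizing resize -> green channel -> median filter ->
    CLAHE -> Otsu threshold -> opening and closing with a disk of radius
    ``disk_radius`` -> area opening (``noise_area``) -> hole filling
    (``hole_area``) -> negated distance transform -> extended-minima
    markers (depth ``minima_depth``) -> minima imposition -> priority
    flood -> removal of regions below ``min_cell_area``.

    Degenerate frames (constant intensity, or nothing above threshold)
    yield an empty label map with a warning rather than an error.
    """
    cfg = config or PipelineConfig()
    rgb = imgproc.resize_to_standard(img, cfg.max_side)
    gray = imgproc.extract_green(rgb)
    smooth = imgproc.median_filter(gray, cfg.median_window)
    enhanced = imgproc.clahe(smooth, cfg.clahe_clip, cfg.clahe_tiles)
    work = enhanced if cfg.clahe_feeds_threshold else smooth

    empty = SegmentationResult(
        labels=np.zeros(gray.shape, dtype=np.int32),
        mask=np.zeros(gray.shape, dtype=bool),
        gray=gray,
        enhanced=enhanced,
    )
    try:
        k = imgproc.otsu_threshold(work)
    except ValueError:
        warnings.warn("constant frame: no threshold, returning empty labels")
        return empty
    mask = imgproc.binarize(work, k)
    se = imgproc.disk_se(cfg.disk_radius)
    mask = imgproc.binary_open(mask, se)
    mask = imgproc.binary_close(mask, se)
    mask = imgproc.area_open(mask, cfg.noise_area, cfg.connectivity)
    mask = imgproc.fill_small_holes(mask, cfg.hole_area)
    if not mask.any():
        warnings.warn("nothing above threshold survived filtering; 0 cells")
        return empty
    if mask.all():
        warnings.warn("threshold kept the whole frame; treating as degenerate")
        return empty

    surface = quantize_surface(basin_surface(mask))
    markers = extended_minima(surface, cfg.minima_depth, cfg.connectivity) & mask
    if not markers.any():
        warnings.warn("no minima deeper than h; 0 cells")
        return empty
    imposed = impose_minima(surface, markers)
    labels = watershed_transform(
        imposed, connectivity=cfg.connectivity, markers=markers, mask=mask
    )
    labels = remove_small_labels(labels, cfg.min_cell_area)
    return SegmentationResult(labels=labels, mask=mask, gray=gray, enhanced=enhanced)
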