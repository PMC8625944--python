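"""Pre-processing primitives for darkfield fluorescence micrographs.

All rasters are plain numpy arrays with fixed conventions:

* ``RgbImage``   — ``(H, W, 3)`` uint8, channel order R, G, B.
* ``GrayImage``  — ``(H, W)`` uint8 intensities.
* ``BinaryMask`` — ``(H, W)`` bool, ``True`` = candidate cell pixel.

Structuring elements are odd-sized boolean stencils centred on their
origin (see :func:`disk_se`).  Out-of-bounds pixels are treated as
background throughout, which matches darkfield frames whose borders are
dominated by the near-black backdrop.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph
from skimage.transform import resize as _sk_resize

__all__ = [
    "extract_green",
    "resize_to_standard",
    "median_filter",
    "clahe",
    "equalize_global",
    "otsu_statistics",
    "otsu_threshold",
    "binarize",
    "disk_se",
    "reflect_se",
    "dilate",
    "erode",
    "binary_open",
    "binary_close",
    "area_open",
    "fill_small_holes",
]


# ---------------------------------------------------------------------------
# raster validation helpers


def _as_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB raster, got shape {img.shape}"
        )
    return img


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected an (H, W) gray raster, got shape {img.shape}")
    return img


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected an (H, W) mask, got shape {mask.shape}")
    return mask.astype(bool, copy=False)


# ---------------------------------------------------------------------------
# channel extraction / geometry


def extract_green(img: np.ndarray) -> np.ndarray:
    """Return the green channel of an RGB raster as a GrayImage.

    Fluorescence is captured in the green band, so downstream processing
    runs on this single channel.
    """
    return _as_rgb(img)[:, :, 1].copy()


def resize_to_standard(img: np.ndarray, max_side: int = 1024) -> np.ndarray:
    """Rescale an RGB raster so its longer side equals ``max_side``.

    Aspect ratio is preserved to the nearest pixel; interpolation is
    bilinear and the result is rounded back to uint8.
    """
    img = _as_rgb(img)
    if max_side < 16:
        raise ValueError("max_side must be >= 16")
    h, w = img.shape[:2]
    scale = max_side / max(h, w)
    if scale == 1.0:
        return img.copy()
    new_h = max(1, round(h * scale))
    new_w = max(1, round(w * scale))
    out = _sk_resize(
        img.astype(float),
        (new_h, new_w, 3),
        order=1,
        preserve_range=True,
        anti_aliasing=scale < 1.0,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def median_filter(img: np.ndarray, window: int = 3) -> np.ndarray:
    """Median smoothing with edge-replicated padding.

    ``window`` must be odd and >= 3.  Salt noise narrower than the window
    is removed while edges are preserved, which is why it runs before the
    contrast adjustment.
    """
    img = _as_gray(img)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    return ndi.median_filter(img, size=window, mode="nearest")


# ---------------------------------------------------------------------------
# contrast


def _equalize_map(hist: np.ndarray) -> np.ndarray:
    """Intensity mapping 0..255 from a (possibly clipped) 256-bin histogram."""
    total = hist.sum()
    if total == 0:
        return np.arange(256, dtype=np.float64)
    cdf = np.cumsum(hist) / total
    return np.rint(255.0 * cdf)


def equalize_global(img: np.ndarray) -> np.ndarray:
    """Plain global histogram equalization (map each level to 255*CDF)."""
    img = _as_gray(img)
    hist = np.bincount(img.ravel(), minlength=256)
    return _equalize_map(hist)[img].astype(np.uint8)


def clahe(
    img: np.ndarray,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The raster is divided into a ``tiles`` grid; each tile's histogram is
    clipped at ``clip_limit`` times the tile pixel count (never below one
    count), the excess is redistributed uniformly over all 256 bins, and
    each tile contributes the mapping ``round(255 * CDF)``.  Pixels are
    transformed by bilinear blending of the four surrounding tile
    mappings, so tile seams are invisible.  A low clip limit keeps the
    near-black darkfield background from being amplified into foreground.

    With a single tile and ``clip_limit=1`` this reduces exactly to
    :func:`equalize_global`.
    """
    img = _as_gray(img)
    if not 0.0 <= clip_limit <= 1.0:
        raise ValueError("clip_limit must lie in [0, 1]")
    ty, tx = int(tiles[0]), int(tiles[1])
    if ty < 1 or tx < 1:
        raise ValueError("tile grid dims must be >= 1")
    h, w = img.shape
    ty = min(ty, h)
    tx = min(tx, w)

    # tile edges (tiles as equal as integer division allows)
    ye = np.linspace(0, h, ty + 1).astype(int)
    xe = np.linspace(0, w, tx + 1).astype(int)
    centers_y = (ye[:-1] + ye[1:] - 1) / 2.0
    centers_x = (xe[:-1] + xe[1:] - 1) / 2.0

    maps = np.empty((ty, tx, 256), dtype=np.float64)
    for i in range(ty):
        for j in range(tx):
            tile = img[ye[i]: ye[i + 1], xe[j]: xe[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            clip = max(clip_limit * tile.size, 1.0)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip)
            hist += excess / 256.0
            maps[i, j] = _equalize_map(hist)

    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    # fractional tile coordinates for bilinear blending between tile centers
    fi = np.interp(rows, centers_y, np.arange(ty)) if ty > 1 else np.zeros(h)
    fj = np.interp(cols, centers_x, np.arange(tx)) if tx > 1 else np.zeros(w)
    i0 = np.floor(fi).astype(int)
    j0 = np.floor(fj).astype(int)
    i1 = np.minimum(i0 + 1, ty - 1)
    j1 = np.minimum(j0 + 1, tx - 1)
    wy = (fi - i0)[:, None]
    wx = (fj - j0)[None, :]

    ii0, ii1 = i0[:, None], i1[:, None]
    jj0, jj1 = j0[None, :], j1[None, :]
    m00 = maps[ii0, jj0, img]
    m01 = maps[ii0, jj1, img]
    m10 = maps[ii1, jj0, img]
    m11 = maps[ii1, jj1, img]
    out = (
        (1 - wy) * ((1 - wx) * m00 + wx * m01)
        + wy * ((1 - wx) * m10 + wx * m11)
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Otsu thresholding


def otsu_statistics(img: np.ndarray):
    """Cumulative histogram statistics behind the between-class variance.

    Returns ``(P1, m, mG, sigmaB2)`` where for each candidate level ``k``:
    ``P1[k]`` is the probability mass at levels <= k, ``m[k]`` the
    cumulative mean up to k, ``mG`` the global mean, and

        sigmaB2[k] = (mG * P1[k] - m[k])**2 / (P1[k] * (1 - P1[k]))

    the between-class variance; ``sigmaB2`` is NaN where a class is empty.
    """
    img = _as_gray(img)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    P1 = np.cumsum(p)
    m = np.cumsum(p * levels)
    mG = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigmaB2 = (mG * P1 - m) ** 2 / (P1 * (1.0 - P1))
    sigmaB2[(P1 <= 0.0) | (P1 >= 1.0)] = np.nan
    return P1, m, mG, sigmaB2


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold: the level maximizing the between-class variance.

    Only levels with both classes non-empty are candidates.  When several
    levels tie at the maximum, the mean of the tied set is taken, rounded
    down — a deterministic, symmetric tie rule.
    """
    _, _, _, sigmaB2 = otsu_statistics(img)
    valid = ~np.isnan(sigmaB2)
    if not valid.any():
        raise ValueError("image is constant; Otsu threshold undefined")
    best = np.nanmax(sigmaB2)
    ties = np.flatnonzero(valid & (sigmaB2 >= best))
    return int(ties.mean())  # int() floors for non-negative means


def binarize(img: np.ndarray, k: int) -> np.ndarray:
    """Threshold at level ``k``: ``True`` where intensity is strictly > k."""
    img = _as_gray(img)
    if not 0 <= k <= 255:
        raise ValueError("threshold level must lie in [0, 255]")
    return img > k


# ---------------------------------------------------------------------------
# binary morphology


def disk_se(radius: int) -> np.ndarray:
    """Disk structuring element: lattice points at distance <= radius.

    The stencil is ``(2r+1, 2r+1)`` and symmetric, so it equals its own
    reflection.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    y, x = np.mgrid[-r: r + 1, -r: r + 1]
    return (y * y + x * x) <= r * r


def reflect_se(se: np.ndarray) -> np.ndarray:
    """Reflection of a structuring element through its origin."""
    return np.asarray(se, dtype=bool)[::-1, ::-1]


def dilate(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary dilation: translations where the reflected element hits A."""
    return ndi.binary_dilation(_as_mask(mask), structure=np.asarray(se, bool))


def erode(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary erosion: translations where the element fits inside A.

    Out-of-bounds pixels count as background, so foreground touching the
    border erodes away.
    """
    return ndi.binary_erosion(
        _as_mask(mask), structure=np.asarray(se, bool), border_value=0
    )


def binary_open(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Opening (erode then dilate): removes protrusions and small specks."""
    return dilate(erode(mask, se), se)


def binary_close(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Closing (dilate then erode): fills gulfs and joins broken margins.

    Computed on a frame padded by the element radius, so the result is
    the infinite-background-plane closing restricted to the frame; this
    keeps closing extensive (``A`` is a subset of ``close(A)``) at the
    image border.
    """
    se = np.asarray(se, dtype=bool)
    py, px = se.shape[0] // 2, se.shape[1] // 2
    padded = np.pad(_as_mask(mask), ((py, py), (px, px)), constant_values=False)
    closed = erode(dilate(padded, se), se)
    return closed[py: closed.shape[0] - py, px: closed.shape[1] - px]


def area_open(mask: np.ndarray, min_area: int = 50, connectivity: int = 8) -> np.ndarray:
    """Remove connected foreground components smaller than ``min_area``.

    Components with exactly ``min_area`` pixels are kept.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = _as_mask(mask)
    return skmorph.remove_small_objects(
        mask, max_size=min_area - 1, connectivity=2 if connectivity == 8 else 1
    )


def fill_small_holes(mask: np.ndarray, min_area: int = 50) -> np.ndarray:
    """Fill background components smaller than ``min_area``.

    Implemented as complement -> area_open (4-connected background) ->
    complement, so a hole of exactly ``min_area`` pixels survives.  The
    surrounding background is always large enough to survive, hence only
    enclosed patches are filled.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = _as_mask(mask)
    background = ~mask
    kept = skmorph.remove_small_objects(background, max_size=min_area - 1, connectivity=1)
    return ~kept
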