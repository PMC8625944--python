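"""Per-cell shape descriptors and per-image dose-stage quantification.

Conventions that matter because the dimensionless descriptors are
sensitive to them:

* Perimeter is the 8-connected boundary chain length, diagonal steps
  weighted ``sqrt(2)``.  For regions with interior holes the chains of
  the hole boundaries are added.
* Convex hull area is measured on the pixel-corner polygon (each pixel
  a unit square), so ``Area <= ConvexArea`` always holds for the
  pixel-count area; the convex hull perimeter is measured on the
  pixel-center hull, which the boundary chain encloses, so
  ``Convexity <= 1`` always holds.
* Feret diameters (max/min caliper extent) are measured on pixel
  centers, so a 10x10 square has a max Feret of ``9*sqrt(2)``.

The descriptor formulas themselves are exposed as scalar functions so
they can be evaluated on closed-form geometry as well as on measured
regions; a disk scores 1 on form factor, roundness, aspect ratio,
solidity, compactness and convexity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops

__all__ = [
    "RegionFeatures",
    "StageResult",
    "STAGE_DOSES",
    "form_factor",
    "roundness",
    "aspect_ratio",
    "solidity",
    "extent",
    "compactness",
    "convexity",
    "chain_perimeter",
    "region_census",
    "shape_descriptors",
    "percent_cell_area",
    "white_point_fraction",
    "intensity_histogram",
    "stage_report",
]

#: Treatment stages and their doses in micrograms per millilitre.
STAGE_DOSES = {"A": 0.0, "B": 12.5, "C": 25.0, "D": 50.0}


# ---------------------------------------------------------------------------
# dimensionless descriptors (closed-form evaluable)


def form_factor(area: float, perimeter: float) -> float:
    """``4*pi*Area / Perimeter**2`` — 1 for a disk, ``pi/4`` for a square."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def roundness(area: float, max_diameter: float) -> float:
    """``4*Area / (pi*MaxDiameter**2)`` — 1 for a disk."""
    if max_diameter <= 0:
        raise ValueError("max_diameter must be positive")
    return 4.0 * area / (math.pi * max_diameter**2)


def aspect_ratio(max_diameter: float, min_diameter: float) -> float:
    """``MaxDiameter / MinDiameter`` — 1 for a disk."""
    if min_diameter <= 0:
        raise ValueError("min_diameter must be positive")
    return max_diameter / min_diameter


def solidity(area: float, convex_area: float) -> float:
    """``Area / ConvexArea`` — 1 for any convex region."""
    if convex_area <= 0:
        raise ValueError("convex_area must be positive")
    return area / convex_area


def extent(area: float, bounding_rectangle_area: float) -> float:
    """``Area / BoundingRectangleArea`` — 1 for an axis-aligned square."""
    if bounding_rectangle_area <= 0:
        raise ValueError("bounding_rectangle_area must be positive")
    return area / bounding_rectangle_area


def compactness(area: float, max_diameter: float) -> float:
    """``sqrt(4*Area/pi) / MaxDiameter`` — 1 for a disk.

    This is the dimensionally consistent reading of the descriptor (the
    diameter of the equal-area disk over the max Feret diameter).
    """
    if max_diameter <= 0:
        raise ValueError("max_diameter must be positive")
    return math.sqrt(4.0 * area / math.pi) / max_diameter


def convexity(convex_perimeter: float, perimeter: float) -> float:
    """``ConvexPerimeter / Perimeter`` — 1 for a convex region."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return convex_perimeter / perimeter


# ---------------------------------------------------------------------------
# geometric measurement


@dataclass
class RegionFeatures:
    """Geometric record of one labelled cell.

    Raw measurements are filled by :func:`region_census`; the
    dimensionless descriptors by :func:`shape_descriptors` (``None``
    marks a descriptor undefined for a degenerate region, e.g. a single
    pixel with zero chain perimeter).
    """

    label: int
    area: float
    filled_area: float
    perimeter: float
    convex_area: float
    convex_perimeter: float
    max_diameter: float
    min_diameter: float
    bounding_rectangle_area: float
    centroid: tuple[float, float]
    extrema: np.ndarray = field(repr=False)
    eccentricity: float = 0.0
    form_factor: float | None = None
    roundness: float | None = None
    aspect_ratio: float | None = None
    solidity: float | None = None
    extent: float | None = None
    compactness: float | None = None
    convexity: float | None = None


_MOORE = ((0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1))
# counter-clockwise scan order (dr, dc), starting east, in image coordinates


def _trace_chain(mask: np.ndarray) -> float:
    """Length of the Moore-boundary chain of a single 8-connected blob.

    ``mask`` must contain exactly one 8-connected foreground component.
    Returns 0.0 for a single pixel.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return 0.0
    if rows.size == 1:
        return 0.0
    # start: first foreground pixel in raster order; backtrack: its west
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    h, w = mask.shape

    def next_on_boundary(p, back):
        # scan Moore neighborhood counter-clockwise starting after `back`;
        # return the first foreground neighbor and the background pixel
        # scanned just before it (the new backtrack)
        k = _MOORE.index((back[0] - p[0], back[1] - p[1]))
        prev_bg = back
        for i in range(1, 9):
            dr, dc = _MOORE[(k + i) % 8]
            q = (p[0] + dr, p[1] + dc)
            if 0 <= q[0] < h and 0 <= q[1] < w and mask[q]:
                return q, prev_bg
            prev_bg = q
        raise AssertionError("isolated pixel in multi-pixel blob")

    length = 0.0
    p = start
    back = (start[0], start[1] - 1)  # west of start is background by raster order
    first_move = None
    while True:
        nxt, back = next_on_boundary(p, back)
        move = (p, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break  # Jacob's stopping criterion: same entry repeated
        length += math.hypot(nxt[0] - p[0], nxt[1] - p[1])
        p = nxt
    return length


def chain_perimeter(mask: np.ndarray) -> float:
    """Boundary chain length of a blob, hole boundaries included."""
    from scipy import ndimage as ndi

    mask = np.asarray(mask, dtype=bool)
    total = _trace_chain(mask)
    # interior holes: enclosed background components (4-connected)
    filled = ndi.binary_fill_holes(mask)
    holes = filled & ~mask
    if holes.any():
        hole_labels, n = ndi.label(holes, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))
        for i in range(1, n + 1):
            total += _trace_chain(hole_labels == i)
    return total


def _corner_points(mask: np.ndarray) -> np.ndarray:
    """Pixel-corner cloud of a blob (corners of its boundary pixels)."""
    rows, cols = np.nonzero(mask)
    pts = np.concatenate(
        [
            np.stack([rows - 0.5, cols - 0.5], axis=1),
            np.stack([rows - 0.5, cols + 0.5], axis=1),
            np.stack([rows + 0.5, cols - 0.5], axis=1),
            np.stack([rows + 0.5, cols + 0.5], axis=1),
        ]
    )
    return np.unique(pts, axis=0)


def _hull(points: np.ndarray):
    """Convex hull vertices (closed order), or None when degenerate."""
    if len(points) < 3:
        return None
    try:
        hull = ConvexHull(points)
    except QhullError:
        return None
    return points[hull.vertices]


def _feret_diameters(centers: np.ndarray) -> tuple[float, float]:
    """Max/min caliper extent of a point cloud (pixel centers)."""
    pts = np.unique(centers, axis=0)
    if len(pts) == 1:
        return 0.0, 0.0
    verts = _hull(pts)
    if verts is None:  # collinear cloud
        d = np.linalg.norm(pts - pts[0], axis=1)
        return float(d.max()), 0.0
    # max Feret: diameter of the hull vertex set
    diff = verts[:, None, :] - verts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    max_f = float(dist.max())
    # min Feret: smallest width over supporting directions of hull edges
    min_f = math.inf
    k = len(verts)
    for i in range(k):
        a, b = verts[i], verts[(i + 1) % k]
        e = b - a
        n = np.array([-e[1], e[0]])
        norm = np.linalg.norm(n)
        if norm == 0:
            continue
        widths = np.abs((verts - a) @ n) / norm
        min_f = min(min_f, float(widths.max()))
    return max_f, min_f


def _extrema_points(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Eight boundary extrema (row, col), clockwise from top-left."""
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    top = cols[rows == rmin]
    bottom = cols[rows == rmax]
    left = rows[cols == cmin]
    right = rows[cols == cmax]
    return np.array(
        [
            (rmin, top.min()),     # top-left
            (rmin, top.max()),     # top-right
            (right.min(), cmax),   # right-top
            (right.max(), cmax),   # right-bottom
            (rmax, bottom.max()),  # bottom-right
            (rmax, bottom.min()),  # bottom-left
            (left.max(), cmin),    # left-bottom
            (left.min(), cmin),    # left-top
        ],
        dtype=float,
    )


def region_census(labels: np.ndarray) -> list[RegionFeatures]:
    """Measure raw geometry for every positive label.

    Moment-based quantities (centroid, eccentricity, filled area) come
    from scikit-image region properties; perimeter, hulls and Feret
    diameters follow the package conventions documented above.
    """
    labels = np.asarray(labels)
    out: list[RegionFeatures] = []
    for rp in regionprops(labels.astype(np.int64)):
        sub = rp.image  # bbox-cropped blob
        rows, cols = np.nonzero(sub)
        r0, c0, _, _ = rp.bbox
        perim = chain_perimeter(sub)
        # convex area on the pixel-corner polygon (so Area <= ConvexArea)
        corner_verts = _hull(_corner_points(sub))
        if corner_verts is None:  # cannot happen for >=1 pixel, kept defensive
            convex_a = float(rp.area)
        else:
            closed = np.vstack([corner_verts, corner_verts[:1]])
            x, y = closed[:, 0], closed[:, 1]
            convex_a = float(abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])) / 2.0)
        centers = np.stack([rows.astype(float), cols.astype(float)], axis=1)
        # convex perimeter on the pixel-center hull: the boundary chain also
        # runs through pixel centers and encloses them, so ConvexPerimeter
        # <= Perimeter (Convexity <= 1) is guaranteed
        center_verts = _hull(np.unique(centers, axis=0))
        if center_verts is None:
            d = np.sqrt(((centers[:, None] - centers[None, :]) ** 2).sum(-1))
            convex_p = float(d.max()) * 2.0  # degenerate (collinear) region
        else:
            closed = np.vstack([center_verts, center_verts[:1]])
            seg = np.diff(closed, axis=0)
            convex_p = float(np.sqrt((seg**2).sum(-1)).sum())
        max_f, min_f = _feret_diameters(centers)
        bbox_area = float(sub.shape[0] * sub.shape[1])
        extrema = _extrema_points(rows, cols) + np.array([r0, c0], dtype=float)
        out.append(
            RegionFeatures(
                label=int(rp.label),
                area=float(rp.area),
                filled_area=float(rp.area_filled),
                perimeter=perim,
                convex_area=convex_a,
                convex_perimeter=convex_p,
                max_diameter=max_f,
                min_diameter=min_f,
                bounding_rectangle_area=bbox_area,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                extrema=extrema,
                eccentricity=float(rp.eccentricity),
            )
        )
    return out


def shape_descriptors(rf: RegionFeatures) -> RegionFeatures:
    """Fill the dimensionless descriptors of a measured region.

    Descriptors whose denominator is degenerate (zero perimeter or zero
    min Feret) are flagged ``None`` rather than propagating NaNs.
    """
    def safe(fn, *args):
        try:
            return fn(*args)
        except ValueError:
            return None

    return dataclasses.replace(
        rf,
        form_factor=safe(form_factor, rf.area, rf.perimeter),
        roundness=safe(roundness, rf.area, rf.max_diameter),
        aspect_ratio=safe(aspect_ratio, rf.max_diameter, rf.min_diameter),
        solidity=safe(solidity, rf.area, rf.convex_area),
        extent=safe(extent, rf.area, rf.bounding_rectangle_area),
        compactness=safe(compactness, rf.area, rf.max_diameter),
        convexity=safe(convexity, rf.convex_perimeter, rf.perimeter),
    )


# ---------------------------------------------------------------------------
# per-image quantification


def percent_cell_area(labels: np.ndarray) -> float:
    """Percentage of image pixels covered by labelled cells."""
    labels = np.asarray(labels)
    return 100.0 * float(np.count_nonzero(labels > 0)) / labels.size


def white_point_fraction(img: np.ndarray, threshold: int = 200) -> float:
    """Percentage of pixels strictly above the white-point threshold."""
    img = np.asarray(img)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return 100.0 * float(np.count_nonzero(img > threshold)) / img.size


def intensity_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram; counts sum to the pixel count."""
    img = np.asarray(img)
    return np.bincount(img.ravel().astype(np.int64), minlength=256)[:256]


@dataclass
class StageResult:
    """Quantification of one treatment-stage frame.

    ``stage`` is one of A (control), B (12.5), C (25), D (50 ug/mL);
    ``percent_area`` the cell coverage, ``percent_white_points`` the
    bright-pixel fraction of the grayscale frame, ``histogram`` its
    256-bin intensity tally, and ``regions`` the fully described cells.
    """

    stage: str
    percent_area: float
    cell_count: int
    percent_white_points: float
    histogram: np.ndarray = field(repr=False)
    regions: list[RegionFeatures] = field(repr=False, default_factory=list)

    @property
    def dose(self) -> float:
        return STAGE_DOSES[self.stage]


def stage_report(
    img: np.ndarray,
    labels: np.ndarray,
    stage: str,
    white_threshold: int = 200,
) -> StageResult:
    """Assemble the per-image quantification record."""
    if stage not in STAGE_DOSES:
        raise ValueError(f"stage must be one of {sorted(STAGE_DOSES)}, got {stage!r}")
    img = np.asarray(img)
    labels = np.asarray(labels)
    if img.shape != labels.shape:
        raise ValueError("image and label map shapes differ")
    regions = [shape_descriptors(rf) for rf in region_census(labels)]
    return StageResult(
        stage=stage,
        percent_area=percent_cell_area(labels),
        cell_count=int(len(regions)),
        percent_white_points=white_point_fraction(img, white_threshold),
        histogram=intensity_histogram(img),
        regions=regions,
    )
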