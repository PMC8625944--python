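# Methods

This note documents the model behind `cellshed`, the parameter choices,
the numerical conventions, and what the synthetic benchmark does and
does not show.

## Segmentation model

A darkfield fluorescence frame is modeled as bright, roughly elliptical
objects on a near-black background, observed in the green channel. The
pipeline is a fixed composition:

    resize -> green channel -> median(3x3) -> CLAHE -> Otsu -> open(disk 3)
    -> close(disk 3) -> area_open(50) -> fill_holes(50) -> S = -EDT(mask)
    -> extended minima (h = 3, 8-conn) -> impose minima -> priority flood
    -> drop regions < 500 px

The binarized mask is treated as a topological surface via the negated
Euclidean distance transform: each object interior becomes a catchment
basin whose floor sits at the object's thickest point, so two touching
cells with distinct thickness maxima produce two basins separated by a
saddle at the neck. The extended-minima transform (regional minima of
the reconstruction-by-erosion of S + h under S) keeps only basins deeper
than h, which suppresses spurious minima from boundary roughness; minima
imposition then guarantees the flood grows exactly one region per
marker. Flooding assigns a pixel reached by two distinct basins to
neither: it becomes a ridge pixel with label 0, the segmentation
boundary.

### Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `max_side` | 1024 | px | standardized longer image side (bilinear) |
| `median_window` | 3 | px | smallest edge-preserving denoise window |
| `clahe_clip` | 0.01 | fraction | low clip limit: enhances detail without amplifying background noise |
| `clahe_tiles` | 8×8 | — | local-equalization grid |
| `disk_radius` | 3 | px | opening/closing element (edge smoothing) |
| `noise_area` | 50 | px | bright specks below this are noise |
| `hole_area` | 50 | px | dark holes below this are filled |
| `minima_depth` | 3 | px of distance | minimum basin depth for a marker |
| `connectivity` | 8 | — | components and flooding neighborhood |
| `min_cell_area` | 500 | px | smallest region accepted as a complete cell |
| `white_threshold` | 200 | intensity | "white point" cutoff for the stage metric |
| `iou_threshold` | 0.5 | fraction | overlap needed to count a cell as recovered |

The pixel-area parameters (50, 500) and h = 3 are the pipeline's stated
operating points; the resize target, CLAHE settings and median window
are configuration defaults chosen for a ~1-megapixel frame. Whether the
contrast-equalized image feeds the threshold stage is configurable
(`clahe_feeds_threshold`); the default is yes, since Otsu's statistic is
computed on whatever raster is binarized, and equalization sharpens the
bimodality of darkfield histograms. The white-point threshold of 200
anchors to the observation that treated-stage histograms grow a
high-intensity tail above level 200.

## Numerical conventions

* **Otsu.** The between-class variance is maximized over all levels k
  with both classes non-empty; ties take the floored mean of the argmax
  set. Ties are real on two-level images, where every k between the
  levels maximizes the statistic.
* **Binarization** is strict (`> k`): pixels at or below the threshold
  are background.
* **Morphology borders.** Out-of-bounds pixels are background (darkfield
  borders are dark). Closing alone is computed on a frame padded by the
  element radius — the infinite-background-plane closing restricted to
  the frame — because crop-semantics erosion would otherwise eat
  foreground at the border and break extensivity (A ⊆ close(A)).
  Monotonicity then gives idempotence on the cropped frame as well.
* **Flooding determinism.** Surfaces are quantized to 0.1 px of distance
  before marker detection and flooding; the flood orders pixels by
  (quantized height, global FIFO insertion index), seeds are labelled in
  raster order, and neighbors are scanned in raster order of the
  neighborhood. Two runs on any platform produce identical label maps.
* **Extended minima edge case.** If h-suppression flattens the surface
  completely (no minimum deeper than h anywhere), no markers are
  returned rather than the all-true plateau.
* **Perimeter** is the Moore boundary chain length with √2 diagonal
  weights (hole boundaries added). This overestimates smooth contours by
  ~5 % (a digital disk's form factor measures ≈ 0.9), which is why the
  estimator is pinned down here: every perimeter-bearing descriptor
  inherits it.
* **Hull conventions.** Convex *area* uses the pixel-corner polygon, so
  Area ≤ ConvexArea holds exactly for pixel-count areas. Convex
  *perimeter* uses the pixel-center hull: the boundary chain passes
  through and encloses all pixel centers, so ConvexPerimeter ≤ Perimeter
  (Convexity ≤ 1) is guaranteed. For a digital disk the chain estimator
  still leaves Convexity ≈ 0.95; it is exactly 1 on digital convex
  polygons whose edges align with the chain directions (e.g.
  rectangles).
* **Feret diameters** are rotating-calipers extents on pixel centers
  (max = hull diameter, min = smallest edge-supported width); a 10×10
  square has MaxDiameter 9√2. A single-pixel region has zero diameters
  and its ratio descriptors are flagged undefined (`None`) rather than
  NaN.
* **Compactness** is implemented as √(4A/π)/Dmax — the equal-area-disk
  diameter over the max Feret — the dimensionally consistent reading
  under which the ideal circle scores exactly 1. The printed reference
  values for a square's roundness and compactness are mutually
  inconsistent with the formulas under any one diameter convention and
  are treated as typos; the circle column is the anchor.
* **Agreement metric.** The per-image score counts matched truth cells.
  Pixel-exact matching is available but no raster segmenter attains it
  on soft-edged objects; the default criterion is IoU ≥ 0.5 with greedy
  one-to-one assignment (descending IoU, ties to the smaller predicted
  label), which prevents a merged region from claiming two cells. The
  quantity is reported both as agreement and as error = 100 − agreement.

## Synthetic benchmark

The generator renders what the pipeline assumes: Gaussian background
(mean 8, sd 4, clipped), elliptical cells with a flat bright interior at
peak green 210 and a ~2 px soft rim, Poisson-like shot speckle on the
fluorescent signal, faint bleed of the green signal into red/blue, and
1–3 px radius white specks (area ≤ 29 px) as reflection artifacts. Cell
semi-axes are sampled in [16, 30] × [12, 30] px with a 600 px area
floor, safely above the 500 px cell filter; a `touching_fraction`
(default 0.2) of cells is placed overlapping a neighbor at 95 % of the
combined effective radii, giving fused pairs with distinct thickness
maxima. Stage A is a cell-free control; stages B/C/D hold 15/30/50 cells
per 1024² frame. The accuracy suite is 28 frames whose per-frame counts
cycle (40, 44, 48, 52), fixing the total at 1288 annotated cells by
construction; it is exposed as a generator because materializing all
frames and masks at once would hold over a gigabyte.

What passing the synthetic suite shows: the geometry of the method —
thresholding, cleaning, marker extraction, flooding, size filtering,
matching — recovers touching elliptical objects at the stated operating
points. What it does not show: robustness to uneven illumination, focus
drift, autofluorescence gradients, densely overlapping 3-D aggregates,
or debris larger than 50 px — none of which the generator emulates.
Results on real micrographs depend on those factors and on the resize
target, since the pixel-area parameters are not rescaled.

## Problem sizes

Default frames are 1024×1024 (the resize target, so synthetic frames
pass through unresampled); the accuracy suite is 28 such frames
(~50 s total), the counting check 10 separated-cell frames, and the
oracle-equivalence checks run on small rasters (8×8 – 16×16) where
brute-force enumeration is exact and fast.

## Known limitations

* The flood is implemented in pure Python over the foreground only;
  frames whose foreground approaches the full canvas will flood slowly.
* Perimeter-based descriptors carry the chain-code bias discussed above
  and are comparable across regions measured by this package, not
  across perimeter estimators.
* Cells touching the image border are segmented but their truncated
  geometry is reported as-is; no border exclusion is applied.
* Ground-truth masks of touching synthetic cells may overlap by a few
  pixels; the IoU criterion absorbs this, pixel-exact matching does not.
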