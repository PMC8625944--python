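"""Seeded generator of darkfield-like fluorescent-cell frames.

The generator emulates the features of darkfield hyperspectral RGB
captures that the segmentation pipeline depends on: a near-black noisy
background, bright green elliptical cells with a narrow soft edge (some
placed touching a neighbor), a handful of sub-50-px bright white specks
standing in for reflection artifacts and air bubbles, and a cell density
that rises with the treatment dose (stage A = untreated control with no
fluorescent cells, through stage D = highest dose).

Every generated frame comes with exact per-cell ground-truth masks (the
rasterized ellipses), so segmentation accuracy can be scored without any
manual annotation.  A single integer seed makes a sample, a four-stage
series, or the whole validation suite bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .validation import CellMask, GroundTruth

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "STAGE_CELL_COUNTS",
    "generate",
    "generate_stage_series",
    "validation_suite",
    "SUITE_CELL_COUNTS",
]

#: Cells per 1024x1024 frame at each treatment stage (dose-dependent density).
STAGE_CELL_COUNTS = {"A": 0, "B": 15, "C": 30, "D": 50}

#: Per-frame cell counts of the 28-image validation suite (7 cycles of the
#: pattern sum to 1288 annotated cells, the suite's construction-fixed scale).
SUITE_CELL_COUNTS = (40, 44, 48, 52) * 7


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic darkfield frame.

    Semi-axis ranges are in pixels, with ``semi_minor <= semi_major``
    per cell and axes resampled so every cell covers at least
    ``cell_min_area`` px (comfortably above the pipeline's 500-px
    complete-cell filter).  ``touching_fraction`` of the cells are placed
    overlapping a previously placed neighbor to emulate clustering.
    Artifacts are bright whitish specks of radius 1-3 px (< 50 px area,
    so the stated small-object filter removes them).
    """

    height: int = 1024
    width: int = 1024
    n_cells: int = 30
    semi_major: tuple[float, float] = (16.0, 30.0)
    semi_minor: tuple[float, float] = (12.0, 30.0)
    cell_min_area: float = 600.0
    peak_green: float = 210.0
    edge_width: float = 2.0
    touching_fraction: float = 0.2
    n_artifacts: int = 8
    background_mean: float = 8.0
    background_sd: float = 4.0
    stage: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_artifacts < 0:
            raise ValueError("counts must be >= 0")
        if self.semi_major[0] <= 0 or self.semi_minor[0] <= 0:
            raise ValueError("axes must be positive")
        if self.stage == "A" and self.n_cells != 0:
            raise ValueError("stage A is the untreated control: n_cells must be 0")

    @classmethod
    def for_stage(cls, stage: str, seed: int = 0, **overrides) -> "SyntheticSpec":
        if stage not in STAGE_CELL_COUNTS:
            raise ValueError(f"stage must be one of {sorted(STAGE_CELL_COUNTS)}")
        return cls(
            n_cells=STAGE_CELL_COUNTS[stage], stage=stage, seed=seed, **overrides
        )


@dataclass
class SyntheticSample:
    """A generated frame plus its exact ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    truth: GroundTruth
    spec: SyntheticSpec
    cell_params: list[dict] = field(default_factory=list, repr=False)


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed on the canvas without crowding."""


def _sample_axes(rng: np.random.Generator, spec: SyntheticSpec) -> tuple[float, float]:
    for _ in range(100):
        a = rng.uniform(*spec.semi_major)
        b = rng.uniform(spec.semi_minor[0], min(a, spec.semi_minor[1]))
        if np.pi * a * b >= spec.cell_min_area:
            return a, b
    # force the minor axis up to meet the area floor
    a = spec.semi_major[1]
    return a, max(spec.semi_minor[0], spec.cell_min_area / (np.pi * a))


def _place_cells(rng: np.random.Generator, spec: SyntheticSpec) -> list[dict]:
    """Choose per-cell geometry: center, semi-axes, orientation."""
    h, w = spec.height, spec.width
    cells: list[dict] = []
    for i in range(spec.n_cells):
        a, b = _sample_axes(rng, spec)
        touch = bool(cells) and rng.random() < spec.touching_fraction
        placed = False
        for _ in range(300):
            if touch:
                host = cells[int(rng.integers(len(cells)))]
                phi = rng.uniform(0, 2 * np.pi)
                re_host = np.sqrt(host["a"] * host["b"])
                re_new = np.sqrt(a * b)
                d = 0.95 * (re_host + re_new)
                cy = host["cy"] + d * np.sin(phi)
                cx = host["cx"] + d * np.cos(phi)
                others = [c for c in cells if c is not host]
            else:
                cy = rng.uniform(a + 4, h - a - 4)
                cx = rng.uniform(a + 4, w - a - 4)
                others = cells
            if not (a + 2 <= cy <= h - a - 2 and a + 2 <= cx <= w - a - 2):
                continue
            ok = all(
                np.hypot(cy - c["cy"], cx - c["cx"]) >= a + c["a"] + 3
                for c in others
            )
            if ok:
                cells.append(
                    {"cy": cy, "cx": cx, "a": a, "b": b,
                     "theta": rng.uniform(0, np.pi), "touching": touch}
                )
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{spec.n_cells} on a "
                f"{h}x{w} canvas after bounded retries"
            )
    return cells


def _rasterize_cell(cell: dict, spec: SyntheticSpec, shape) -> tuple[int, int, np.ndarray, np.ndarray]:
    """Return (row0, col0, intensity factor patch, truth patch)."""
    h, w = shape
    a, b = cell["a"], cell["b"]
    r0 = max(int(np.floor(cell["cy"] - a - 1)), 0)
    r1 = min(int(np.ceil(cell["cy"] + a + 2)), h)
    c0 = max(int(np.floor(cell["cx"] - a - 1)), 0)
    c1 = min(int(np.ceil(cell["cx"] + a + 2)), w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cell["cy"]
    dx = xx - cell["cx"]
    ct, st = np.cos(cell["theta"]), np.sin(cell["theta"])
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # flat bright interior with a soft rim of ~edge_width px
    factor = np.clip((1.0 - rho) * (b / spec.edge_width), 0.0, 1.0)
    return r0, c0, factor, rho <= 1.0


def generate(spec: SyntheticSpec) -> SyntheticSample:
    """Render one frame and its ground truth, deterministically per seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cells = _place_cells(rng, spec)

    signal = np.zeros((h, w), dtype=float)  # fluorescence factor in [0, 1]
    occupied = np.zeros((h, w), dtype=bool)
    truth_cells: list[CellMask] = []
    for cell in cells:
        r0, c0, factor, tmask = _rasterize_cell(cell, spec, (h, w))
        sl = np.s_[r0: r0 + factor.shape[0], c0: c0 + factor.shape[1]]
        np.maximum(signal[sl], factor, out=signal[sl])
        occupied[sl] |= tmask
        truth_cells.append(CellMask(r0, c0, tmask))

    green_cells = signal * spec.peak_green
    # Poisson-like shot speckle on the fluorescent signal
    speckle = rng.standard_normal((h, w)) * np.sqrt(np.maximum(green_cells, 0.0))
    green_cells = np.where(signal > 0, green_cells + 0.5 * speckle, 0.0)

    def background() -> np.ndarray:
        return np.clip(
            rng.normal(spec.background_mean, spec.background_sd, (h, w)), 0.0, 255.0
        )

    red = background() + 0.10 * green_cells
    green = np.maximum(background(), green_cells)
    blue = background() + 0.05 * green_cells

    # bright whitish specks (reflection artifacts), kept off the cells
    for _ in range(spec.n_artifacts):
        for _try in range(200):
            radius = int(rng.integers(1, 4))
            cy = int(rng.integers(radius + 1, h - radius - 1))
            cx = int(rng.integers(radius + 1, w - radius - 1))
            sl = np.s_[cy - radius - 3: cy + radius + 4, cx - radius - 3: cx + radius + 4]
            if not occupied[sl].any():
                yy, xx = np.mgrid[-radius: radius + 1, -radius: radius + 1]
                speck = (yy**2 + xx**2) <= radius**2
                level = rng.uniform(220, 250)
                asl = np.s_[cy - radius: cy + radius + 1, cx - radius: cx + radius + 1]
                for chan in (red, green, blue):
                    chan[asl] = np.where(speck, level, chan[asl])
                break

    image = np.clip(
        np.rint(np.stack([red, green, blue], axis=-1)), 0, 255
    ).astype(np.uint8)
    truth = GroundTruth(shape=(h, w), cells=truth_cells)
    return SyntheticSample(image=image, truth=truth, spec=spec, cell_params=cells)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_stage_series(
    base: SyntheticSpec | None = None, seed: int = 0
) -> list[SyntheticSample]:
    """Four frames A-D with strictly increasing cell counts.

    Canvas and noise parameters are shared; only the stage tag, the cell
    count and the per-stage child seed differ.
    """
    base = base or SyntheticSpec()
    seeds = _child_seeds(seed, 4)
    series = []
    for s, stage in zip(seeds, "ABCD"):
        spec = dataclasses.replace(
            base, stage=stage, n_cells=STAGE_CELL_COUNTS[stage], seed=s
        )
        series.append(generate(spec))
    return series


def validation_suite(seed: int = 0, base: SyntheticSpec | None = None) -> Iterator[SyntheticSample]:
    """Yield the 28-frame accuracy suite (~1300 annotated cells in total).

    Implemented as a generator: a materialized suite would hold over a
    gigabyte of frames and masks, while scoring only ever needs one
    frame at a time.
    """
    base = base or SyntheticSpec()
    seeds = _child_seeds(seed, len(SUITE_CELL_COUNTS))
    for s, n in zip(seeds, SUITE_CELL_COUNTS):
        spec = dataclasses.replace(base, stage=None, n_cells=n, seed=s)
        yield generate(spec)
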