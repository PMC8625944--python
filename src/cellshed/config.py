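"""Pipeline configuration.

Defaults follow the stated processing parameters of the segmentation
pipeline: disk structuring elements of radius 3, a 50-pixel small-object
/ hole filter, a minima depth of 3 with 8-connectivity, a 500-pixel
minimum cell area, and a white-point intensity threshold of 200.
"""

from __future__ import annotations

import dataclasses
import io
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """All tunable parameters of the segmentation pipeline.

    Attributes
    ----------
    max_side
        Longer image side after standardizing resize, px.
    median_window
        Median filter window (odd), px.
    clahe_clip
        CLAHE clip limit, fraction of tile pixel count in [0, 1].
    clahe_tiles
        CLAHE tile grid (rows, cols).
    clahe_feeds_threshold
        If True (default) the contrast-equalized image is thresholded;
        if False, Otsu runs on the median-filtered image and CLAHE is
        kept for inspection only.
    disk_radius
        Radius of the disk structuring element for opening/closing, px.
    noise_area
        Minimum surviving bright-component area (area opening), px.
    hole_area
        Minimum surviving dark-hole area (hole filling), px.
    minima_depth
        Depth h of the extended-minima marker transform, px of distance.
    connectivity
        Pixel connectivity for components and flooding (4 or 8).
    min_cell_area
        Minimum labelled-region area kept as a complete cell, px.
    white_threshold
        Intensity level above which a pixel counts as a white point.
    agreement_criterion
        Ground-truth match rule: "iou" or "exact".
    iou_threshold
        IoU at or above which a predicted region matches a truth cell.
    seed
        Seed for any randomized step (the pipeline itself is
        deterministic; the seed is recorded for provenance).
    """

    max_side: int = 1024
    median_window: int = 3
    clahe_clip: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_feeds_threshold: bool = True
    disk_radius: int = 3
    noise_area: int = 50
    hole_area: int = 50
    minima_depth: float = 3.0
    connectivity: int = 8
    min_cell_area: int = 500
    white_threshold: int = 200
    agreement_criterion: str = "iou"
    iou_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.agreement_criterion not in ("iou", "exact"):
            raise ValueError("agreement_criterion must be 'iou' or 'exact'")
        self.clahe_tiles = tuple(int(t) for t in self.clahe_tiles)  # type: ignore[assignment]

    # -- flat key=value (TOML) round-trip -----------------------------------

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, tuple):
                lines.append(f"{f.name} = [{', '.join(str(x) for x in v)}]")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "PipelineConfig":
        data = tomllib.load(io.BytesIO(text.encode()))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "clahe_tiles" in data:
            data["clahe_tiles"] = tuple(data["clahe_tiles"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_toml())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_toml(Path(path).read_text())
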