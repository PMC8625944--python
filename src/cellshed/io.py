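"""File I/O: images, label maps, ground truth, feature tables.

Everything uses open formats: per-cell features go to CSV with a
documented column order, per-image stage results to JSON, label maps to
16-bit PNG, ground truth to a directory of per-cell PNG masks plus a
JSON index (or a multi-page TIFF).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .features import RegionFeatures, StageResult
from .synthetic import SyntheticSample, SyntheticSpec
from .validation import CellMask, GroundTruth

__all__ = [
    "read_rgb",
    "write_png",
    "write_label_map",
    "read_label_map",
    "write_ground_truth",
    "read_ground_truth",
    "write_sample",
    "read_spec",
    "features_to_dataframe",
    "stage_result_to_dict",
    "FEATURE_COLUMNS",
]

#: Column order of the per-cell feature CSV.
FEATURE_COLUMNS = [
    "image", "stage", "label", "area", "filled_area", "perimeter",
    "convex_area", "convex_perimeter", "max_diameter", "min_diameter",
    "bounding_rectangle_area", "centroid_row", "centroid_col",
    "eccentricity", "form_factor", "roundness", "aspect_ratio",
    "solidity", "extent", "compactness", "convexity",
]


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB raster (TIFF/PNG); alpha is dropped if present."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path}: single-channel image, expected RGB")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 channels, got {arr.shape[2]}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit data, got {arr.dtype}")
    return arr


def write_png(path: str | Path, arr: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(arr))


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit PNG (or TIFF by extension)."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot go to 16-bit")
    out = labels.astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_label_map(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# ground truth


def write_ground_truth(directory: str | Path, truth: GroundTruth) -> None:
    """Write per-cell full-frame PNG masks plus an ``index.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, cell in enumerate(truth.cells):
        name = f"cell_{i:04d}.png"
        full = cell.to_full(truth.shape).astype(np.uint8) * 255
        iio.imwrite(directory / name, full)
        files.append(name)
    index = {"shape": list(truth.shape), "n": truth.n, "files": files}
    (directory / "index.json").write_text(json.dumps(index, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    """Read ground truth from a mask directory or a multi-page TIFF."""
    path = Path(path)
    if path.is_dir():
        index = json.loads((path / "index.json").read_text())
        shape = tuple(index["shape"])
        cells = [
            CellMask.from_full(iio.imread(path / name) > 0)
            for name in index["files"]
        ]
        return GroundTruth(shape=shape, cells=cells)
    pages = tifffile.imread(path)
    pages = np.atleast_3d(pages)
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2D masks")
    cells = [CellMask.from_full(page > 0) for page in pages]
    return GroundTruth(shape=tuple(pages.shape[1:]), cells=cells)


# ---------------------------------------------------------------------------
# synthetic samples


def write_sample(directory: str | Path, name: str, sample: SyntheticSample) -> None:
    """Write ``<name>.png``, ``<name>_truth/`` masks and ``<name>_spec.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{name}.png", sample.image)
    write_ground_truth(directory / f"{name}_truth", sample.truth)
    spec = dataclasses.asdict(sample.spec)
    spec["semi_major"] = list(spec["semi_major"])
    spec["semi_minor"] = list(spec["semi_minor"])
    (directory / f"{name}_spec.json").write_text(json.dumps(spec, indent=1))


def read_spec(path: str | Path) -> SyntheticSpec:
    data = json.loads(Path(path).read_text())
    data["semi_major"] = tuple(data["semi_major"])
    data["semi_minor"] = tuple(data["semi_minor"])
    return SyntheticSpec(**data)


# ---------------------------------------------------------------------------
# tables


def _region_row(image: str, stage: str, rf: RegionFeatures) -> dict:
    return {
        "image": image,
        "stage": stage,
        "label": rf.label,
        "area": rf.area,
        "filled_area": rf.filled_area,
        "perimeter": rf.perimeter,
        "convex_area": rf.convex_area,
        "convex_perimeter": rf.convex_perimeter,
        "max_diameter": rf.max_diameter,
        "min_diameter": rf.min_diameter,
        "bounding_rectangle_area": rf.bounding_rectangle_area,
        "centroid_row": rf.centroid[0],
        "centroid_col": rf.centroid[1],
        "eccentricity": rf.eccentricity,
        "form_factor": rf.form_factor,
        "roundness": rf.roundness,
        "aspect_ratio": rf.aspect_ratio,
        "solidity": rf.solidity,
        "extent": rf.extent,
        "compactness": rf.compactness,
        "convexity": rf.convexity,
    }


def features_to_dataframe(results: list[tuple[str, StageResult]]) -> pd.DataFrame:
    """One row per segmented cell across a batch of (image name, result)."""
    rows = [
        _region_row(name, res.stage, rf)
        for name, res in results
        for rf in res.regions
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def stage_result_to_dict(name: str, res: StageResult) -> dict:
    """JSON-ready summary of a StageResult (histogram included)."""
    return {
        "image": name,
        "stage": res.stage,
        "dose_ug_per_ml": res.dose,
        "percent_area": res.percent_area,
        "cell_count": res.cell_count,
        "percent_white_points": res.percent_white_points,
        "histogram": [int(c) for c in res.histogram],
    }
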