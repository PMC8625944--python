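from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from cellshed import PipelineConfig, SyntheticSpec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def small_spec() -> SyntheticSpec:
    """A small, quick-to-segment frame: 5 separated cells on a 320 px canvas."""
    return SyntheticSpec(
        height=320,
        width=320,
        n_cells=5,
        semi_major=(14.0, 20.0),
        semi_minor=(12.0, 18.0),
        touching_fraction=0.0,
        n_artifacts=4,
        seed=11,
    )


@pytest.fixture
def small_config() -> PipelineConfig:
    """Pipeline config matching the small synthetic canvas (no resize)."""
    return PipelineConfig(max_side=320)


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[:n, :n]
    return ((yy - c) ** 2 + (xx - c) ** 2) <= radius * radius
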