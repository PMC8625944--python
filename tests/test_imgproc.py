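"""Pre-processing primitives against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from cellshed import imgproc


# ---------------------------------------------------------------------------
# channel extraction / resize


def test_extract_green_is_channel_identity(rng):
    img = rng.integers(0, 256, (13, 17, 3), dtype=np.uint8)
    assert np.array_equal(imgproc.extract_green(img), img[:, :, 1])
    pure_green = np.zeros((4, 4, 3), np.uint8)
    pure_green[:, :, 1] = 255
    assert (imgproc.extract_green(pure_green) == 255).all()
    pure_red = np.zeros((4, 4, 3), np.uint8)
    pure_red[:, :, 0] = 255
    assert (imgproc.extract_green(pure_red) == 0).all()


def test_extract_green_rejects_non_rgb():
    with pytest.raises(ValueError):
        imgproc.extract_green(np.zeros((4, 4), np.uint8))


@pytest.mark.parametrize(
    "shape, max_side, expected",
    [
        ((64, 64), 64, (64, 64)),       # identity
        ((128, 64), 64, (64, 32)),      # ratio arithmetic
        ((100, 60), 50, (50, 30)),      # independent per-axis scale
        ((60, 100), 50, (30, 50)),
    ],
)
def test_resize_scale_factor(shape, max_side, expected):
    img = np.full(shape + (3,), 100, np.uint8)
    out = imgproc.resize_to_standard(img, max_side)
    scale = max_side / max(shape)
    assert out.shape[:2] == expected
    assert out.shape[:2] == (round(shape[0] * scale), round(shape[1] * scale))
    assert out.dtype == np.uint8


def test_resize_identity_preserves_pixels(rng):
    img = rng.integers(0, 256, (32, 48, 3), dtype=np.uint8)
    assert np.array_equal(imgproc.resize_to_standard(img, 48), img)


# ---------------------------------------------------------------------------
# median filter


def test_median_filter_constant_and_salt():
    const = np.full((9, 9), 42, np.uint8)
    assert np.array_equal(imgproc.median_filter(const, 3), const)
    salt = np.full((9, 9), 5, np.uint8)
    salt[4, 4] = 255
    assert imgproc.median_filter(salt, 3)[4, 4] == 5


def test_median_filter_matches_bruteforce(rng):
    for _ in range(5):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        assert np.array_equal(
            imgproc.median_filter(img, 3), oracles.median_filter(img, 3)
        )


def test_median_filter_rejects_even_window():
    with pytest.raises(ValueError):
        imgproc.median_filter(np.zeros((5, 5), np.uint8), 4)


# ---------------------------------------------------------------------------
# CLAHE


def test_clahe_constant_image_stays_constant():
    const = np.full((32, 32), 17, np.uint8)
    out = imgproc.clahe(const, 0.01, (4, 4))
    assert len(np.unique(out)) == 1


def test_clahe_single_tile_no_clip_equals_global_equalization(rng):
    img = rng.integers(0, 50, (24, 24), dtype=np.uint8)
    img[:8] = 200  # two-tone
    assert np.array_equal(
        imgproc.clahe(img, 1.0, (1, 1)), oracles.global_equalize(img)
    )


def test_clahe_expands_low_contrast_ramp():
    ramp = np.tile(np.linspace(90, 110, 64).astype(np.uint8), (64, 1))
    out = imgproc.clahe(ramp, 0.5, (2, 2))
    assert np.ptp(out) >= np.ptp(ramp)
    assert out.min() >= 0 and out.max() <= 255


# ---------------------------------------------------------------------------
# Otsu


def test_otsu_two_level_tie_rule():
    img = np.zeros((10, 10), np.uint8)
    img[5:] = 200
    img[:5] = 10
    # every k in [10, 199] separates the classes equally; tie rule takes
    # the floored mean of the tied set
    assert imgproc.otsu_threshold(img) == 104


def test_otsu_perfectly_separable():
    img = np.zeros((20, 20), np.uint8)
    img[0, :4] = 255  # 1% foreground
    k = imgproc.otsu_threshold(img)
    assert np.array_equal(imgproc.binarize(img, k), img == 255)


def test_otsu_equals_exhaustive_argmax(rng):
    for _ in range(100):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        if len(np.unique(img)) < 2:
            continue
        assert imgproc.otsu_threshold(img) == oracles.otsu_threshold(img)


def test_otsu_constant_image_raises():
    with pytest.raises(ValueError):
        imgproc.otsu_threshold(np.full((5, 5), 7, np.uint8))


def test_binarize_counting():
    assert not imgproc.binarize(np.zeros((4, 4), np.uint8), 0).any()
    assert imgproc.binarize(np.full((4, 4), 255, np.uint8), 0).all()
    ramp = np.arange(256, dtype=np.uint8).reshape(16, 16)
    assert imgproc.binarize(ramp, 127).sum() == 128


# ---------------------------------------------------------------------------
# morphology


def test_disk_se_shapes():
    plus = imgproc.disk_se(1)
    assert plus.sum() == 5 and plus.shape == (3, 3)
    d3 = imgproc.disk_se(3)
    assert d3.shape == (7, 7)
    assert d3.sum() == sum(
        1
        for y in range(-3, 4)
        for x in range(-3, 4)
        if y * y + x * x <= 9
    )  # lattice-point count = 29
    assert np.array_equal(d3, np.rot90(d3))
    with pytest.raises(ValueError):
        imgproc.disk_se(0)


def test_dilate_single_pixel_is_plus():
    m = np.zeros((5, 5), bool)
    m[2, 2] = True
    out = imgproc.dilate(m, imgproc.disk_se(1))
    expected = np.zeros((5, 5), bool)
    expected[2, 1:4] = True
    expected[1:4, 2] = True
    assert np.array_equal(out, expected)


def test_erode_by_single_pixel_is_identity(rng):
    m = rng.random((12, 12)) < 0.4
    se = np.ones((1, 1), bool)
    assert np.array_equal(imgproc.erode(m, se), m)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    arrays(bool, (12, 12), elements=st.booleans()),
    st.sampled_from([1, 2]),
)
def test_erosion_dilation_duality(mask, radius):
    """erode(A, B) == ~dilate(~A, reflect(B)) with foreground borders."""
    from scipy import ndimage as ndi

    se = imgproc.disk_se(radius)
    dual = ~ndi.binary_dilation(
        ~mask, structure=imgproc.reflect_se(se), border_value=1
    )
    assert np.array_equal(imgproc.erode(mask, se), dual)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(arrays(bool, (12, 12), elements=st.booleans()))
def test_open_close_idempotent_and_ordered(mask):
    se = imgproc.disk_se(1)
    opened = imgproc.binary_open(mask, se)
    closed = imgproc.binary_close(mask, se)
    assert (opened <= mask).all()  # anti-extensive
    assert (mask <= closed).all()  # extensive
    assert np.array_equal(imgproc.binary_open(opened, se), opened)
    assert np.array_equal(imgproc.binary_close(closed, se), closed)


def test_open_removes_speck_keeps_square():
    m = np.zeros((20, 20), bool)
    m[3, 3] = True  # 1-px speck
    m[8:18, 8:18] = True  # 10x10 square
    out = imgproc.binary_open(m, imgproc.disk_se(3))
    assert not out[3, 3]
    assert out[10:16, 10:16].all()  # interior away from corners survives
    assert (out <= m).all()


def test_opening_increasing(rng):
    a = rng.random((16, 16)) < 0.3
    c = a | (rng.random((16, 16)) < 0.2)
    se = imgproc.disk_se(1)
    assert (imgproc.binary_open(a, se) <= imgproc.binary_open(c, se)).all()


# ---------------------------------------------------------------------------
# area opening / hole filling


def test_area_open_boundary_case():
    m = np.zeros((30, 60), bool)
    m[5:12, 5:12] = True  # 49 px
    assert m[5:12, 5:12].sum() == 49
    m[5:15, 30:35] = True  # 50 px
    out = imgproc.area_open(m, 50)
    assert not out[5:12, 5:12].any()
    assert out[5:15, 30:35].all()
    assert not imgproc.area_open(np.zeros((5, 5), bool), 50).any()


def test_area_open_matches_component_census(rng):
    for _ in range(10):
        m = rng.random((16, 16)) < 0.35
        assert np.array_equal(
            imgproc.area_open(m, 4, connectivity=8),
            oracles.area_open(m, 4, connectivity=8),
        )


def test_fill_small_holes_ring_and_solid():
    ring = np.zeros((15, 15), bool)
    ring[3:12, 3:12] = True
    ring[6:9, 6:9] = False  # 9-px hole
    filled = imgproc.fill_small_holes(ring, 50)
    assert filled[6:9, 6:9].all()
    solid = np.zeros((10, 10), bool)
    solid[2:8, 2:8] = True
    assert np.array_equal(imgproc.fill_small_holes(solid, 50), solid)


def test_fill_small_holes_equals_complement_pipeline(rng):
    for _ in range(10):
        m = rng.random((20, 20)) < 0.6
        direct = imgproc.fill_small_holes(m, 8)
        # independent 3-step composition with the 4-connected census oracle
        indirect = ~oracles.area_open(~m, 8, connectivity=4)
        assert np.array_equal(direct, indirect)


def test_all_ops_preserve_shape_and_range(rng):
    img = rng.integers(0, 256, (20, 24), dtype=np.uint8)
    for out in (
        imgproc.median_filter(img, 3),
        imgproc.clahe(img, 0.02, (2, 2)),
        imgproc.equalize_global(img),
    ):
        assert out.shape == img.shape
        assert out.dtype == np.uint8
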