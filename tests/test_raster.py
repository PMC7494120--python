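"""Boundary tracing and preprocessing conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from voromorph.raster import (
    RasterImage,
    preprocess_binary,
    trace_binary_boundaries,
    trace_label_boundaries,
)

EIGHT = np.ones((3, 3), int)
FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def test_preprocess_fills_small_holes_and_drops_debris():
    a = np.ones((9, 9), int)
    a[4, 4] = 0  # 1-px hole
    img = preprocess_binary(RasterImage(np.pad(a, 1)), min_hole_area=21, min_object_area=5)
    assert img.values.sum() == 81
    assert len([b for b in trace_binary_boundaries(img) if b.kind == "interior"]) == 0

    small = np.zeros((9, 9), int)
    small[4, 4] = 1
    assert preprocess_binary(RasterImage(small), 0, 50).values.sum() == 0

    # identity with zero thresholds
    rng = np.random.default_rng(0)
    noise = (rng.random((12, 12)) < 0.4).astype(int)
    out = preprocess_binary(RasterImage(noise), 0, 0)
    assert np.array_equal(out.values, noise)


def test_preprocess_rejects_label_mode():
    img = RasterImage(np.zeros((4, 4), int), mode="label")
    with pytest.raises(ValueError):
        preprocess_binary(img)


def test_single_pixel_boundary_is_unit_square():
    bs = trace_binary_boundaries(RasterImage(np.array([[1]])))
    assert len(bs) == 1
    b = bs[0]
    assert b.kind == "exterior"
    assert b.enclosed_area == pytest.approx(1.0)
    assert b.perimeter == pytest.approx(4.0)
    assert np.all(np.abs(b.points * 2 - np.round(b.points * 2)) < 1e-12)


def test_half_pixel_bar_boundary():
    a = np.zeros((5, 9), int)
    a[2, 2:7] = 1
    bs = trace_binary_boundaries(RasterImage(a))
    assert len(bs) == 1
    assert bs[0].enclosed_area == pytest.approx(5.0)
    assert bs[0].perimeter == pytest.approx(12.0)


def test_diagonal_contact_separated_by_one_twentieth_px():
    a = np.zeros((4, 4), int)
    a[1, 1] = a[2, 2] = 1
    bs = trace_binary_boundaries(RasterImage(a))
    assert len(bs) == 1  # 8-connected foreground: one object, one boundary
    pts = bs[0].points
    d = np.hypot(pts[:, 0] - 1.5, pts[:, 1] - 1.5)
    near = pts[d < 0.1]
    assert len(near) == 2
    assert np.hypot(*(near[0] - near[1])) == pytest.approx(0.05, abs=1e-12)
    from shapely.geometry import LinearRing

    assert LinearRing(pts).is_simple


def test_label_tracing_conventions():
    # single-pixel label: 0.5-side square
    la = np.zeros((4, 4), int)
    la[1, 1] = 1
    bs = trace_label_boundaries(RasterImage(la, mode="label"))
    assert bs[0].enclosed_area == pytest.approx(0.25)
    assert bs[0].perimeter == pytest.approx(2.0)

    # touching labels: facing edges half a pixel apart
    la = np.zeros((4, 5), int)
    la[1, 1] = 1
    la[1, 2] = 2
    b1, b2 = trace_label_boundaries(RasterImage(la, mode="label"))
    assert b2.points[:, 0].min() - b1.points[:, 0].max() == pytest.approx(0.5)

    # largest 4-connected component only
    la = np.zeros((5, 9), int)
    la[1, 1:4] = 7
    la[3, 6:8] = 7
    bs = trace_label_boundaries(RasterImage(la, mode="label"))
    assert len(bs) == 1
    assert bs[0].enclosed_area == pytest.approx((3 - 0.5) * (1 - 0.5))


def test_label_solid_rectangle_area_quarter_pixel_rim():
    la = np.zeros((8, 9), int)
    la[2:6, 2:7] = 3  # 5 x 4 solid label
    bs = trace_label_boundaries(RasterImage(la, mode="label"))
    assert bs[0].enclosed_area == pytest.approx((5 - 0.5) * (4 - 0.5))


def test_label_zero_rejected():
    img = RasterImage(np.ones((3, 3), int), mode="label")
    with pytest.raises(ValueError):
        trace_label_boundaries(img, labels=[0])


def test_empty_foreground_gives_empty_set():
    assert trace_binary_boundaries(RasterImage(np.zeros((5, 5), int))) == []


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_tracing_counts_and_simplicity_on_random_masks(seed):
    """Exterior count = 8-connected components; interior count = holes;
    all polylines simple and mutually disjoint; exterior area = pixel
    count of the component plus its holes (small shift contribution)."""
    rng = np.random.default_rng(seed)
    a = (rng.random((14, 14)) < rng.uniform(0.25, 0.7)).astype(int)
    img = RasterImage(a)
    bs = trace_binary_boundaries(img)
    _, n_obj = ndimage.label(a, structure=EIGHT)
    bg_lab, nbg = ndimage.label(1 - a, structure=FOUR)
    border = np.unique(
        np.concatenate([bg_lab[0], bg_lab[-1], bg_lab[:, 0], bg_lab[:, -1]])
    )
    n_holes = len([k for k in range(1, nbg + 1) if k not in border])
    ext = [b for b in bs if b.kind == "exterior"]
    holes = [b for b in bs if b.kind == "interior"]
    assert len(ext) == n_obj
    assert len(holes) == n_holes

    from shapely import STRtree
    from shapely.geometry import LinearRing

    rings = [LinearRing(b.points) for b in bs]
    assert all(r.is_simple for r in rings)
    if len(rings) > 1:
        tree = STRtree(rings)
        for i, r in enumerate(rings):
            hits = [j for j in tree.query(r, predicate="intersects") if j != i]
            assert not hits

    # area bookkeeping: sum of signed areas = foreground pixel count
    # (each shifted corner contributes < 0.02 px^2)
    signed = sum(b.signed_area for b in bs)
    n_shift = sum(
        np.sum(np.abs(b.points * 2 - np.round(b.points * 2)) > 1e-9) for b in bs
    )
    assert abs(signed - a.sum()) <= 0.02 * max(n_shift, 1)
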