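import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from marrowdcc.imaging import (
    BBox,
    EmptyMaskError,
    box_iou,
    geometric_center,
    mask_iou,
    mask_to_bbox,
    resize_longest_side_pad,
    resize_mask_longest_side_pad,
    restore_mask,
    round_half_away,
)


class TestResizeLongestSidePad:
    def test_symmetric_pad_when_scale_is_one(self):
        img = np.full((128, 256), 7, dtype=np.uint8)
        out, rec = resize_longest_side_pad(img, 256)
        assert out.shape == (256, 256)
        assert rec.pad_top == rec.pad_bottom == 64
        assert (out[:64] == 0).all() and (out[-64:] == 0).all()
        assert (out[64:192] == 7).all()

    def test_short_side_rounded_and_deficit_split_floor_ceil(self):
        img = np.zeros((100, 120), dtype=np.uint8)
        out, rec = resize_longest_side_pad(img, 256)
        # 100 * 256/120 = 213.33 -> 213; deficit 43 split 21/22
        assert out.shape == (256, 256)
        assert (rec.pad_top, rec.pad_bottom) == (21, 22)
        assert (rec.pad_left, rec.pad_right) == (0, 0)

    def test_identity_when_already_target(self):
        img = np.arange(256 * 256, dtype=np.uint8).reshape(256, 256)
        out, rec = resize_longest_side_pad(img, 256)
        assert np.array_equal(out, img)
        assert rec.pad_top == rec.pad_bottom == rec.pad_left == rec.pad_right == 0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            resize_longest_side_pad(np.zeros((0, 5), dtype=np.uint8), 64)

    @given(
        h=st.integers(1, 80),
        w=st.integers(1, 80),
        target=st.integers(8, 128),
    )
    def test_output_square_and_padding_zero(self, h, w, target):
        img = np.full((h, w), 200, dtype=np.uint8)
        out, rec = resize_longest_side_pad(img, target)
        assert out.shape == (target, target)
        if rec.pad_top:
            assert (out[: rec.pad_top] == 0).all()
        if rec.pad_bottom:
            assert (out[-rec.pad_bottom :] == 0).all()
        if rec.pad_left:
            assert (out[:, : rec.pad_left] == 0).all()
        if rec.pad_right:
            assert (out[:, -rec.pad_right :] == 0).all()


class TestRestoreMask:
    def test_all_ones_roundtrip(self):
        mask = np.ones((37, 81), dtype=np.uint8)
        padded, rec = resize_mask_longest_side_pad(mask, 64)
        back = restore_mask(padded, rec)
        assert np.array_equal(back, mask)

    @given(h=st.integers(1, 60), w=st.integers(1, 60))
    def test_shape_contract(self, h, w):
        mask = np.zeros((h, w), dtype=np.uint8)
        mask[h // 2, w // 2] = 1
        padded, rec = resize_mask_longest_side_pad(mask, 48)
        assert restore_mask(padded, rec).shape == (h, w)

    def test_single_pixel_maps_to_nearest_original_location(self):
        # 4×6 toy: upscale is 48/6 = 8× on cols, rows scaled to 32 then padded
        mask = np.zeros((4, 6), dtype=np.uint8)
        mask[1, 2] = 1
        padded, rec = resize_mask_longest_side_pad(mask, 48)
        back = restore_mask(padded, rec)
        # nearest-neighbour oracle: the foreground must survive, in one block,
        # and its centroid must be the original pixel
        assert back.sum() == 1
        assert back[1, 2] == 1

    def test_shape_mismatch_rejected(self):
        mask = np.ones((10, 10), dtype=np.uint8)
        _, rec = resize_mask_longest_side_pad(mask, 32)
        with pytest.raises(ValueError):
            restore_mask(np.ones((16, 16), dtype=np.uint8), rec)


class TestMaskToBBox:
    def test_tight_half_open_box(self):
        m = np.zeros((10, 12), dtype=np.uint8)
        m[2:6, 3:8] = 1  # rows 2..5, cols 3..7 inclusive
        assert mask_to_bbox(m) == BBox(3, 2, 8, 6)

    def test_single_pixel(self):
        m = np.zeros((8, 12), dtype=np.uint8)
        m[4, 9] = 1
        assert mask_to_bbox(m) == BBox(9, 4, 10, 5)

    def test_two_disjoint_blobs_spanned(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[1:3, 2:4] = 1
        m[15:18, 10:16] = 1
        rows, cols = np.nonzero(m)
        expected = BBox(int(cols.min()), int(rows.min()), int(cols.max()) + 1, int(rows.max()) + 1)
        assert mask_to_bbox(m) == expected

    def test_empty_mask_signals(self):
        with pytest.raises(EmptyMaskError):
            mask_to_bbox(np.zeros((5, 5), dtype=np.uint8))

    @given(st.integers(0, 10 ** 6))
    def test_box_area_at_least_foreground_count(self, seed):
        m = (np.random.default_rng(seed).random((15, 15)) < 0.3).astype(np.uint8)
        if m.sum() == 0:
            m[0, 0] = 1
        assert mask_to_bbox(m).area >= m.sum()


class TestIoU:
    def test_identical_boxes(self):
        b = BBox(3, 4, 10, 12)
        assert box_iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou(BBox(0, 0, 2, 2), BBox(5, 5, 7, 7)) == 0.0

    def test_partial_overlap_pixel_count_oracle(self):
        assert box_iou(BBox(0, 0, 2, 2), BBox(1, 0, 3, 2)) == pytest.approx(2 / 6)

    @given(
        a=st.tuples(st.integers(0, 10), st.integers(0, 10), st.integers(1, 10), st.integers(1, 10)),
        b=st.tuples(st.integers(0, 10), st.integers(0, 10), st.integers(1, 10), st.integers(1, 10)),
    )
    def test_symmetric_bounded_and_matches_pixel_oracle(self, a, b):
        ba = BBox(a[0], a[1], a[0] + a[2], a[1] + a[3])
        bb = BBox(b[0], b[1], b[0] + b[2], b[1] + b[3])
        iou = box_iou(ba, bb)
        assert iou == box_iou(bb, ba)
        assert 0.0 <= iou <= 1.0
        # rasterised oracle
        grid_a = np.zeros((25, 25), dtype=bool)
        grid_b = np.zeros((25, 25), dtype=bool)
        grid_a[ba.y0 : ba.y1, ba.x0 : ba.x1] = True
        grid_b[bb.y0 : bb.y1, bb.x0 : bb.x1] = True
        assert iou == pytest.approx(mask_iou(grid_a, grid_b))
        assert (iou == 1.0) == (ba == bb)


class TestGeometricCenter:
    def test_solid_square_center(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[0:3, 0:3] = 1
        assert geometric_center(m) == (1, 1)

    def test_single_pixel_returns_xy(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[7, 2] = 1
        assert geometric_center(m) == (2, 7)

    def test_ring_snaps_to_nearest_foreground(self):
        m = np.ones((7, 7), dtype=np.uint8)
        m[2:5, 2:5] = 0  # square annulus, hole centred at (3, 3)
        x, y = geometric_center(m)
        assert m[y, x] == 1
        # exhaustive oracle: nearest foreground to the true centroid, ties by
        # smallest row then column
        rows, cols = np.nonzero(m)
        cy, cx = rows.mean(), cols.mean()
        d2 = (rows - cy) ** 2 + (cols - cx) ** 2
        best = np.lexsort((cols, rows, d2))[0]
        assert (x, y) == (cols[best], rows[best])

    def test_empty_mask_signals(self):
        with pytest.raises(EmptyMaskError):
            geometric_center(np.zeros((3, 3), dtype=np.uint8))


def test_round_half_away_from_zero():
    assert round_half_away(0.5) == 1
    assert round_half_away(1.5) == 2
    assert round_half_away(2.5) == 3
    assert round_half_away(-0.5) == -1
    assert list(round_half_away(np.array([0.49, 2.5, -1.5]))) == [0, 3, -2]
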