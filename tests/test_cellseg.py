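import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from marrowdcc.cellseg import (
    MaskCandidate,
    OraclePromptableSegmenter,
    ReferencePromptableSegmenter,
    build_point_grid,
    nms,
    prompts_from_gt,
    recall_at_iou,
    seg_every,
)
from marrowdcc.imaging import BBox, box_iou, geometric_center
from marrowdcc.synthetic import SceneParams, generate_case, render_tile


def _cand(x0, y0, x1, y1, score, area=None):
    b = BBox(x0, y0, x1, y1)
    return MaskCandidate(score=score, bbox=b, prompt=(x0, y0), area=area or b.area)


def nms_bruteforce(cands, thr):
    """Independent trace of greedy suppression using an explicit worklist."""
    remaining = list(range(len(cands)))
    kept = []
    while remaining:
        best = min(remaining, key=lambda i: (-cands[i].score, -cands[i].area, i))
        kept.append(best)
        remaining = [
            i for i in remaining if i != best and box_iou(cands[i].bbox, cands[best].bbox) < thr
        ]
    return [cands[i] for i in kept]


class TestPointGrid:
    def test_two_by_two_centres(self):
        assert build_point_grid(1024, 2) == [(256, 256), (768, 256), (256, 768), (768, 768)]

    def test_single_centre_point(self):
        assert build_point_grid(100, 1) == [(50, 50)]

    def test_dense_grid_inside_bounds(self):
        pts = build_point_grid(1024, 32)
        assert len(pts) == 1024
        assert all(0 <= x < 1024 and 0 <= y < 1024 for x, y in pts)


class TestNMS:
    def test_disjoint_candidates_all_survive(self):
        cands = [_cand(0, 0, 10, 10, 0.9), _cand(20, 20, 30, 30, 0.5)]
        assert len(nms(cands, 0.5)) == 2

    def test_identical_pair_keeps_higher_score(self):
        cands = [_cand(0, 0, 10, 10, 0.8), _cand(0, 0, 10, 10, 0.9)]
        out = nms(cands, 0.5)
        assert len(out) == 1 and out[0].score == 0.9

    def test_overlap_chain_keeps_ends(self):
        # A–B IoU ≥ thr, B–C IoU ≥ thr, A–C below thr → {A, C}
        a = _cand(0, 0, 10, 10, 0.9)
        b = _cand(0, 3, 10, 13, 0.85)
        c = _cand(0, 6, 10, 16, 0.8)
        assert box_iou(a.bbox, b.bbox) >= 0.5 and box_iou(b.bbox, c.bbox) >= 0.5
        assert box_iou(a.bbox, c.bbox) < 0.5
        out = nms([a, b, c], 0.5)
        assert [o.score for o in out] == [0.9, 0.8]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        cands = [
            _cand(x, y, x + w, y + h, s)
            for x, y, w, h, s in zip(
                rng.integers(0, 30, 20), rng.integers(0, 30, 20),
                rng.integers(2, 15, 20), rng.integers(2, 15, 20), rng.random(20),
            )
        ]
        once = nms(cands, 0.4)
        assert nms(once, 0.4) == once

    @given(st.integers(0, 10 ** 6))
    def test_matches_bruteforce_on_small_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        cands = [
            _cand(int(x), int(y), int(x + w), int(y + h), float(np.round(s, 2)))
            for x, y, w, h, s in zip(
                rng.integers(0, 12, n), rng.integers(0, 12, n),
                rng.integers(2, 10, n), rng.integers(2, 10, n), rng.random(n),
            )
        ]
        thr = float(rng.uniform(0.2, 0.8))
        assert nms(cands, thr) == nms_bruteforce(cands, thr)


class TestRecallAtIoU:
    def test_exact_predictions_give_full_recall(self):
        gts = [BBox(0, 0, 10, 10), BBox(20, 0, 30, 10)]
        preds = [(b, 0.9) for b in gts]
        for thr in (0.5, 0.75, 1.0):
            assert recall_at_iou(preds, gts, thr) == 1.0

    def test_no_predictions(self):
        assert recall_at_iou([], [BBox(0, 0, 5, 5)], 0.5) == 0.0

    def test_two_of_three_matched(self):
        gts = [BBox(0, 0, 10, 10), BBox(20, 0, 30, 10), BBox(40, 0, 50, 10)]
        # two preds overlapping distinct GT at IoU 10·8/(2·100-80)=2/3... use shifts
        preds = [(BBox(0, 1, 10, 11), 0.9), (BBox(20, 1, 30, 11), 0.8)]
        iou = box_iou(preds[0][0], gts[0])
        assert iou >= 0.75
        assert recall_at_iou(preds, gts, 0.75) == pytest.approx(2 / 3)
        assert recall_at_iou(preds, gts, 0.50) == pytest.approx(2 / 3)

    def test_empty_ground_truth_undefined(self):
        with pytest.raises(ValueError):
            recall_at_iou([(BBox(0, 0, 5, 5), 0.5)], [], 0.5)

    @given(st.integers(0, 10 ** 6))
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        gts = [
            BBox(int(x), int(y), int(x) + 8, int(y) + 8)
            for x, y in zip(rng.integers(0, 40, 5), rng.integers(0, 40, 5))
        ]
        preds = [
            (BBox(int(x), int(y), int(x) + 8, int(y) + 8), float(s))
            for x, y, s in zip(rng.integers(0, 40, 5), rng.integers(0, 40, 5), rng.random(5))
        ]
        r50 = recall_at_iou(preds, gts, 0.50)
        r75 = recall_at_iou(preds, gts, 0.75)
        assert r50 >= r75

    @given(st.integers(0, 10 ** 6))
    def test_greedy_agrees_with_exhaustive_assignment(self, seed):
        rng = np.random.default_rng(seed)
        n_gt, n_pred = int(rng.integers(1, 5)), int(rng.integers(0, 5))
        gts = [
            BBox(int(x), int(y), int(x + w), int(y + h))
            for x, y, w, h in zip(
                rng.integers(0, 20, n_gt), rng.integers(0, 20, n_gt),
                rng.integers(3, 12, n_gt), rng.integers(3, 12, n_gt),
            )
        ]
        preds = [
            (BBox(int(x), int(y), int(x + w), int(y + h)), float(s))
            for x, y, w, h, s in zip(
                rng.integers(0, 20, n_pred), rng.integers(0, 20, n_pred),
                rng.integers(3, 12, n_pred), rng.integers(3, 12, n_pred), rng.random(n_pred),
            )
        ]
        thr = 0.5
        # exhaustive one-to-one assignment maximising matches at IoU ≥ thr
        best = 0
        for k in range(min(n_gt, n_pred), 0, -1):
            for pred_subset in itertools.permutations(range(n_pred), k):
                for gt_subset in itertools.combinations(range(n_gt), k):
                    ok = sum(
                        box_iou(preds[p][0], gts[g]) >= thr
                        for p, g in zip(pred_subset, gt_subset)
                    )
                    best = max(best, ok)
            if best == k:
                break
        assert recall_at_iou(preds, gts, thr) == pytest.approx(best / n_gt)


def _toi_tile_params():
    return SceneParams(
        wsi_height=800, wsi_width=800, tile_size=800, thumb_factor=100,
        band_fractions=(0.0, 1.0, 0.0), cells_per_good_tile=6.0, bad_tile_fraction=0.0,
    )


class TestReferenceSegmenter:
    def test_point_in_cell_recovers_most_of_it(self):
        p = _toi_tile_params()
        img, masks = render_tile(p, "toi", 0, n_cells=4)
        backend = ReferencePromptableSegmenter()
        for gt_mask, _ in masks:
            point = geometric_center(gt_mask)
            pred, score = backend.predict(img, point)
            overlap = (pred & gt_mask).sum() / gt_mask.sum()
            assert overlap >= 0.9
            assert score > 0.5

    def test_background_point_gives_empty_mask(self):
        p = _toi_tile_params()
        img, masks = render_tile(p, "toi", 1, n_cells=2)
        backend = ReferencePromptableSegmenter()
        occupied = np.zeros(img.shape[:2], dtype=bool)
        for m, _ in masks:
            occupied |= m.astype(bool)
        ys, xs = np.nonzero(~occupied)
        # corner background pixel
        pred, score = backend.predict(img, (int(xs[0]), int(ys[0])))
        assert pred.sum() == 0 and score == 0.0

    def test_circular_blob_scores_near_isoperimetric_maximum(self):
        img = np.full((200, 200), 240, dtype=np.uint8)
        yy, xx = np.mgrid[:200, :200]
        disc = (yy - 100) ** 2 + (xx - 100) ** 2 <= 40 ** 2
        img[disc] = 60
        _, score = ReferencePromptableSegmenter().predict(img, (100, 100))
        assert score > 0.9


class TestSegEvery:
    def test_oracle_backend_finds_every_cell_exactly_once(self, small_banded_case):
        case = small_banded_case
        backend = OraclePromptableSegmenter(case, seg_size=1024)
        from marrowdcc.imaging import resize_image

        grid = build_point_grid(1024, 64)
        for t in case.tile_refs:
            spec = case.tile_specs[(t.row_index, t.col_index)]
            if spec.kind != "toi" or not spec.cells:
                continue
            img = resize_image(case.tile_image(t.row_index, t.col_index), (1024, 1024))
            cands = seg_every(img, backend, grid, ref=t)
            assert len(cands) == len(spec.cells)
            break
        else:
            pytest.fail("no populated TOI tile in fixture")

    def test_count_monotone_in_score_threshold(self):
        p = _toi_tile_params()
        img, _ = render_tile(p, "toi", 2, n_cells=6)
        from marrowdcc.imaging import resize_image

        seg_img = resize_image(img, (1024, 1024))
        backend = ReferencePromptableSegmenter()
        grid = build_point_grid(1024, 24)
        counts = [
            len(seg_every(seg_img, backend, grid, score_min=smin))
            for smin in (0.0, 0.5, 0.9, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)


class TestPromptsFromGT:
    def test_one_triple_per_mask_with_centre_on_foreground(self):
        p = _toi_tile_params()
        img, masks = render_tile(p, "toi", 3, n_cells=5)
        triples = prompts_from_gt(img, [m for m, _ in masks])
        assert len(triples) == 5
        for _, (x, y), mask in triples:
            assert mask[y, x] == 1

    def test_empty_masks_skipped(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        masks = [np.zeros((10, 10), dtype=np.uint8), np.ones((10, 10), dtype=np.uint8)]
        assert len(prompts_from_gt(img, masks)) == 1

    def test_centred_square_mask_prompts_its_centre(self):
        m = np.zeros((21, 21), dtype=np.uint8)
        m[8:13, 8:13] = 1
        img = np.zeros((21, 21, 3), dtype=np.uint8)
        assert prompts_from_gt(img, [m])[0][1] == (10, 10)
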