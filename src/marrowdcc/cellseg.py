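"""Segment-everything orchestration over a promptable segmenter backend.

A promptable segmenter predicts one mask per foreground point prompt. The
segment-everything driver prompts it at every node of a uniform point grid
on the 1024×1024 working raster, drops empty/low-quality/out-of-size
predictions, and removes duplicate masks with greedy non-maximum
suppression (NMS) on mask-derived bounding boxes. The same module provides
the prompt-set builder for fine-tuning data preparation (one geometric
centre point per annotated cell mask) and detection recall at an IoU
threshold, the paper-standard Recall50/Recall75 metric pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import perimeter as _perimeter

from .imaging import (
    BBox,
    EmptyMaskError,
    box_iou,
    geometric_center,
    mask_to_bbox,
    resize_mask,
    round_half_away,
    to_grayscale,
)

logger = logging.getLogger(__name__)

SEG_WORKING_SIZE = 1024


class PromptableSegmenter(Protocol):
    def predict(
        self, image: np.ndarray, point: tuple[int, int], ref=None
    ) -> tuple[np.ndarray, float]: ...


@dataclass(frozen=True)
class MaskCandidate:
    """A segmented cell candidate: mask, quality score and derived geometry.

    ``mask`` may be ``None`` for candidates whose pixels have been released
    after the derived geometry was computed (bounding box and area are what
    downstream stages consume).
    """

    score: float
    bbox: BBox
    prompt: tuple[int, int]
    area: int
    mask: np.ndarray | None = None

    @classmethod
    def from_mask(
        cls, mask: np.ndarray, score: float, prompt: tuple[int, int]
    ) -> "MaskCandidate":
        return cls(
            score=float(score),
            bbox=mask_to_bbox(mask),
            prompt=prompt,
            area=int(np.count_nonzero(mask)),
            mask=mask,
        )


def build_point_grid(image_side: int, n_per_side: int) -> list[tuple[int, int]]:
    """``n²`` prompts at the cell centres of a uniform n×n partition."""
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    step = image_side / n_per_side
    coords = [int(round_half_away((i + 0.5) * step)) for i in range(n_per_side)]
    coords = [min(c, image_side - 1) for c in coords]
    return [(x, y) for y in coords for x in coords]


def nms(candidates: Sequence[MaskCandidate], iou_threshold: float) -> list[MaskCandidate]:
    """Greedy non-maximum suppression on bounding-box IoU.

    Repeatedly keeps the highest-scoring remaining candidate and removes all
    others whose box IoU with it is at or above the threshold. Ties are
    broken by larger area, then by input (prompt raster) order.
    """
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i].score, -candidates[i].area, i),
    )
    kept: list[MaskCandidate] = []
    kept_boxes: list[BBox] = []
    for i in order:
        c = candidates[i]
        if all(box_iou(c.bbox, kb) < iou_threshold for kb in kept_boxes):
            kept.append(c)
            kept_boxes.append(c.bbox)
    return kept


def seg_every(
    image: np.ndarray,
    backend: PromptableSegmenter,
    grid: Sequence[tuple[int, int]] | None = None,
    score_min: float = 0.5,
    area_range: tuple[int, int] = (80, 40_000),
    nms_iou: float = 0.7,
    ref=None,
) -> list[MaskCandidate]:
    """Prompt the backend at every grid point and deduplicate the masks.

    Pipeline: per-point prediction → drop empty masks, scores below
    ``score_min`` and areas outside ``area_range`` → greedy box-IoU NMS →
    survivors sorted by score descending. Backends frequently return the
    identical mask object for prompts landing on the same object; geometry
    is computed once per distinct mask array.
    """
    if grid is None:
        grid = build_point_grid(image.shape[0], 32)
    geometry_cache: dict[int, MaskCandidate] = {}
    candidates: list[MaskCandidate] = []
    for point in grid:
        try:
            mask, score = backend.predict(image, point, ref=ref)
        except Exception:  # pragma: no cover - defensive: skip failing prompt
            logger.exception("segmenter backend failed on prompt %s; skipped", point)
            continue
        cached = geometry_cache.get(id(mask))
        if cached is not None:
            cand = MaskCandidate(float(score), cached.bbox, point, cached.area, mask)
        else:
            if not np.any(mask):
                continue
            cand = MaskCandidate.from_mask(mask, score, point)
            geometry_cache[id(mask)] = cand
        if cand.score < score_min:
            continue
        if not (area_range[0] <= cand.area <= area_range[1]):
            continue
        candidates.append(cand)
    survivors = nms(candidates, nms_iou)
    return sorted(survivors, key=lambda c: -c.score)


def map_candidate_to_native(
    cand: MaskCandidate, seg_size: int, native_size: int
) -> MaskCandidate:
    """Rescale a working-raster candidate to native tile coordinates.

    The bbox-local mask crop is nearest-neighbour resized by the scale
    factor and the box/area re-derived from it; the full-frame native mask
    is not materialised.
    """
    if cand.mask is None:
        raise ValueError("candidate has no mask to rescale")
    scale = native_size / seg_size
    b = cand.bbox
    local = cand.mask[b.y0 : b.y1, b.x0 : b.x1]
    nh = max(1, int(round_half_away(b.height * scale)))
    nw = max(1, int(round_half_away(b.width * scale)))
    local_native = resize_mask(np.asarray(local, dtype=np.uint8), (nh, nw))
    oy = int(round_half_away(b.y0 * scale))
    ox = int(round_half_away(b.x0 * scale))
    rows, cols = np.nonzero(local_native)
    if rows.size == 0:  # degenerate after downscale; fall back to scaled box
        nb = b.scaled(scale)
        return MaskCandidate(cand.score, nb, cand.prompt, max(1, int(cand.area * scale**2)))
    nb = BBox(
        ox + int(cols.min()),
        oy + int(rows.min()),
        ox + int(cols.max()) + 1,
        oy + int(rows.max()) + 1,
    )
    return MaskCandidate(cand.score, nb, cand.prompt, int(rows.size))


# ---------------------------------------------------------------------------
# reference backend: global dark-object threshold + connected components


class ReferencePromptableSegmenter:
    """Classical stand-in for a promptable segmenter.

    Dark objects are separated from the pale smear background by an Otsu
    threshold on luminance; the prediction for a point is the connected
    component containing it (empty mask, score 0 on background). The
    quality score is the isoperimetric circularity ``4πA/P²`` clipped to
    [0, 1] — compact round cells score near 1, ragged debris lower.

    Component masks are cached per image, so prompting the same image at
    many grid points is cheap and prompts on one cell share a mask array.
    """

    backend_id = "reference-otsu"

    def __init__(self) -> None:
        self._cache: tuple | None = None  # (image ref, labels, {label: (mask, score)})

    def _analyse(self, image: np.ndarray):
        if self._cache is not None and self._cache[0] is image:
            return self._cache[1], self._cache[2]
        gray = to_grayscale(image)
        if gray.std() < 2.0:
            labels = np.zeros(gray.shape, dtype=np.int32)
        else:
            dark = gray < threshold_otsu(gray)
            labels, _ = ndimage.label(dark)
        self._cache = (image, labels, {})
        return labels, self._cache[2]

    def predict(
        self, image: np.ndarray, point: tuple[int, int], ref=None
    ) -> tuple[np.ndarray, float]:
        labels, comp_cache = self._analyse(image)
        x, y = point
        lab = int(labels[y, x])
        if lab == 0:
            return np.zeros(labels.shape, dtype=np.uint8), 0.0
        if lab not in comp_cache:
            mask = (labels == lab).astype(np.uint8)
            area = int(mask.sum())
            b = mask_to_bbox(mask)
            per = _perimeter(mask[b.y0 : b.y1, b.x0 : b.x1], neighborhood=4)
            score = 1.0 if per == 0 else min(1.0, 4 * np.pi * area / per**2)
            comp_cache[lab] = (mask, float(score))
        return comp_cache[lab]


class OraclePromptableSegmenter:
    """Testing backend returning the ground-truth mask containing the point.

    Ground-truth cell polygons are rasterised once per tile onto the
    working raster; a prompt inside instance *i* returns instance *i*'s
    mask with score 1, a background prompt returns an empty mask with
    score 0.
    """

    backend_id = "oracle"

    def __init__(self, case, seg_size: int = SEG_WORKING_SIZE) -> None:
        self.case = case
        self.seg_size = seg_size
        self._cache: dict = {}

    def _tile_raster(self, ref):
        key = (ref.row_index, ref.col_index)
        if key in self._cache:
            return self._cache[key]
        from skimage.draw import polygon as draw_polygon

        spec = self.case.tile_specs[key]
        scale = self.seg_size / self.case.params.tile_size
        labels = np.zeros((self.seg_size, self.seg_size), dtype=np.int32)
        for i, cell in enumerate(spec.cells, start=1):
            poly = cell.polygon * scale
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], labels.shape)
            labels[rr, cc] = i
        self._cache = {key: (labels, {})}  # single-tile cache
        return self._cache[key]

    def predict(
        self, image: np.ndarray, point: tuple[int, int], ref=None
    ) -> tuple[np.ndarray, float]:
        if ref is None:
            raise ValueError("oracle segmenter needs the tile reference")
        labels, masks = self._tile_raster(ref)
        x, y = point
        lab = int(labels[y, x])
        if lab == 0:
            return np.zeros(labels.shape, dtype=np.uint8), 0.0
        if lab not in masks:
            masks[lab] = (labels == lab).astype(np.uint8)
        return masks[lab], 1.0


# ---------------------------------------------------------------------------
# fine-tuning prompt preparation and detection recall


def prompts_from_gt(
    image: np.ndarray, cell_masks: Sequence[np.ndarray]
) -> list[tuple[np.ndarray, tuple[int, int], np.ndarray]]:
    """One (image, centre point, mask) training triple per annotated cell."""
    triples = []
    for i, mask in enumerate(cell_masks):
        try:
            point = geometric_center(mask)
        except EmptyMaskError:
            logger.warning("skipping empty ground-truth mask %d", i)
            continue
        triples.append((image, point, mask))
    return triples


def recall_at_iou(
    predictions: Sequence[tuple[BBox, float]],
    gt_boxes: Sequence[BBox],
    thr: float,
) -> float:
    """Fraction of ground-truth boxes matched one-to-one at IoU >= ``thr``.

    Predictions are visited in descending score order; each claims the
    unmatched ground-truth box of highest IoU if that IoU reaches the
    threshold. Raises on an empty ground-truth set (recall undefined).
    """
    if not 0.0 < thr <= 1.0:
        raise ValueError("thr must be in (0, 1]")
    if len(gt_boxes) == 0:
        raise ValueError("recall undefined for empty ground truth")
    order = sorted(range(len(predictions)), key=lambda i: -predictions[i][1])
    matched = [False] * len(gt_boxes)
    n_matched = 0
    for i in order:
        box = predictions[i][0]
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gt_boxes):
            if matched[j]:
                continue
            iou = box_iou(box, gt)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= thr:
            matched[best_j] = True
            n_matched += 1
    return n_matched / len(gt_boxes)
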