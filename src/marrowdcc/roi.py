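"""ROI (body–tail junction) segmentation on smear thumbnails.

The junction band is the only part of a smear where nucleated cells lie in
a countable monolayer. Segmentation runs behind a backend contract: the
thumbnail is resized (longest side to 256, zero-padded square), handed to a
backend that returns a 256×256 binary mask, and the mask is restored to the
thumbnail's native shape. A classical texture backend is shipped as the
reference implementation: the junction shows intermediate local texture
energy between the dense body and the sparse tail, so a banded local
variance threshold followed by largest-component extraction recovers it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import ndimage
from skimage import morphology

from .imaging import (
    PaddingRecord,
    resize_longest_side_pad,
    resize_mask_longest_side_pad,
    restore_mask,
    to_grayscale,
    validate_mask,
)


class ROISegmenterBackend(Protocol):
    """Contract: 256×256 image in, binary 256×256 mask out."""

    def predict(self, thumbnail_256: np.ndarray, ref=None) -> np.ndarray: ...


@dataclass(frozen=True)
class ROIResult:
    mask_thumb: np.ndarray  # binary, at original thumbnail shape
    padding: PaddingRecord
    backend_id: str


def segment_roi(
    thumbnail: np.ndarray,
    backend: ROISegmenterBackend,
    target_size: int = 256,
    ref=None,
) -> ROIResult:
    """Pad-resize the thumbnail, run the backend, restore the mask."""
    padded, rec = resize_longest_side_pad(thumbnail, target_size)
    raw = backend.predict(padded, ref=ref)
    raw = np.asarray(raw)
    if raw.shape != (target_size, target_size):
        raise ValueError(
            f"backend returned shape {raw.shape}, expected ({target_size}, {target_size})"
        )
    mask = validate_mask(raw)
    restored = restore_mask(mask, rec)
    backend_id = getattr(backend, "backend_id", type(backend).__name__)
    return ROIResult(mask_thumb=restored, padding=rec, backend_id=backend_id)


# ---------------------------------------------------------------------------
# reference backend: banded local-variance texture segmentation


def reference_texture_roi(
    thumbnail_256: np.ndarray,
    window: int = 15,
    quantiles: tuple[float, float] = (0.30, 0.70),
) -> np.ndarray:
    """Junction segmentation by intermediate local texture energy.

    A local-variance map (uniform ``window``×``window`` filter) is
    thresholded to keep pixels whose variance lies between the two quantile
    cut-offs of the variance distribution — the junction's mottled monolayer
    sits between the high-contrast body and the flat tail. The largest
    connected component is kept and closed morphologically. May return an
    empty mask (uniform input has zero variance everywhere).
    """
    gray = to_grayscale(thumbnail_256)
    mean = ndimage.uniform_filter(gray, window)
    mean_sq = ndimage.uniform_filter(gray**2, window)
    var = np.maximum(mean_sq - mean**2, 0.0)
    lo, hi = np.quantile(var, quantiles[0]), np.quantile(var, quantiles[1])
    keep = (var > lo) & (var <= hi) & (var > 1e-12)
    if not keep.any():
        return np.zeros_like(keep, dtype=np.uint8)
    labels, n = ndimage.label(keep)
    if n == 0:
        return np.zeros_like(keep, dtype=np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    mask = morphology.closing(mask, footprint=morphology.disk(5)).astype(bool)
    return mask.astype(np.uint8)


@dataclass(frozen=True)
class ReferenceTextureROIBackend:
    """Shipped classical backend wrapping :func:`reference_texture_roi`."""

    window: int = 15
    quantiles: tuple[float, float] = (0.30, 0.70)
    backend_id: str = "reference-texture"

    def predict(self, thumbnail_256: np.ndarray, ref=None) -> np.ndarray:
        return reference_texture_roi(thumbnail_256, self.window, self.quantiles)


@dataclass(frozen=True)
class OracleROIBackend:
    """Testing backend that returns the ground-truth junction mask.

    The ground-truth mask lives at thumbnail scale, so it is pushed through
    the same pad-resize transform the thumbnail undergoes.
    """

    roi_mask_gt: np.ndarray
    target_size: int = 256
    backend_id: str = "oracle"

    def predict(self, thumbnail_256: np.ndarray, ref=None) -> np.ndarray:
        mask, _ = resize_mask_longest_side_pad(self.roi_mask_gt, self.target_size)
        return mask


@dataclass(frozen=True)
class ConstantROIBackend:
    """Returns an all-zeros or all-ones mask; useful for degenerate paths."""

    value: int = 0
    backend_id: str = "constant"

    def predict(self, thumbnail_256: np.ndarray, ref=None) -> np.ndarray:
        return np.full(thumbnail_256.shape[:2], self.value, dtype=np.uint8)


# ---------------------------------------------------------------------------
# segmentation metrics


def seg_metrics(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float, float]:
    """(IoU, Dice, pixel accuracy) of a predicted mask against ground truth.

    When both masks are empty there is nothing to disagree about: IoU and
    Dice are defined as 1.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = np.logical_and(pred, gt).sum()
    fp = np.logical_and(pred, ~gt).sum()
    fn = np.logical_and(~pred, gt).sum()
    tn = pred.size - tp - fp - fn
    union = tp + fp + fn
    iou = 1.0 if union == 0 else tp / union
    dice = 1.0 if union == 0 else 2 * tp / (2 * tp + fp + fn)
    pa = (tp + tn) / pred.size
    return float(iou), float(dice), float(pa)
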