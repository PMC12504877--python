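"""Raster conventions and geometry primitives shared by every pipeline stage.

Conventions, stated once and used everywhere:

* images are ``numpy`` arrays, ``H×W`` (grayscale) or ``H×W×3`` (RGB),
  ``uint8``;
* binary masks are ``H×W`` arrays with values in ``{0, 1}``;
* coordinates are 0-based; a point is ``(x, y) == (col, row)``;
* bounding boxes are half-open: ``[x0, x1) × [y0, y1)``;
* pixel arithmetic rounds half away from zero (:func:`round_half_away`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize


# ---------------------------------------------------------------------------
# rounding and validation helpers


def round_half_away(x: float | np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero.

    ``numpy.round`` rounds halves to even, which would make pixel
    coordinates depend on parity; this variant is the single rounding rule
    used for all pixel arithmetic in the package.
    """
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x)).astype(np.int64)


def validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim not in (2, 3):
        raise ValueError(f"image must be 2-D or 3-D, got ndim={img.ndim}")
    if img.ndim == 3 and img.shape[2] != 3:
        raise ValueError(f"RGB image must have 3 channels, got {img.shape[2]}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"empty image: shape {img.shape}")
    return img


def validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got ndim={mask.ndim}")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask values must be 0/1")
    return mask.astype(np.uint8)


class EmptyMaskError(ValueError):
    """Raised when an operation needs at least one foreground pixel."""


# ---------------------------------------------------------------------------
# bounding boxes


@dataclass(frozen=True)
class BBox:
    """Half-open axis-aligned box ``[x0, x1) × [y0, y1)`` in pixel units."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate box: {self}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def scaled(self, factor: float) -> "BBox":
        """Box with every coordinate multiplied by ``factor`` and rounded."""
        x0, y0, x1, y1 = (int(round_half_away(v * factor)) for v in (self.x0, self.y0, self.x1, self.y1))
        return BBox(x0, y0, max(x1, x0 + 1), max(y1, y0 + 1))


def mask_to_bbox(mask: np.ndarray) -> BBox:
    """Tightest half-open box containing all foreground pixels."""
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("empty-mask")
    return BBox(int(cols.min()), int(rows.min()), int(cols.max()) + 1, int(rows.max()) + 1)


def box_iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two half-open boxes; 0 when disjoint."""
    ix = min(a.x1, b.x1) - max(a.x0, b.x0)
    iy = min(a.y1, b.y1) - max(a.y0, b.y0)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / float(a.area + b.area - inter)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixelwise intersection over union of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def geometric_center(mask: np.ndarray) -> tuple[int, int]:
    """Integer ``(x, y)`` centroid of the foreground, snapped onto it.

    The centroid of the foreground coordinates is rounded to the nearest
    pixel; if that pixel is background (a ring-shaped cell, say) the nearest
    foreground pixel is returned instead, ties broken by smallest row then
    smallest column.
    """
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("empty-mask")
    cy, cx = float(rows.mean()), float(cols.mean())
    ry, rx = int(round_half_away(cy)), int(round_half_away(cx))
    if 0 <= ry < mask.shape[0] and 0 <= rx < mask.shape[1] and mask[ry, rx]:
        return rx, ry
    d2 = (rows - cy) ** 2 + (cols - cx) ** 2
    order = np.lexsort((cols, rows, d2))  # distance, then row, then col
    best = order[0]
    return int(cols[best]), int(rows[best])


# ---------------------------------------------------------------------------
# resize-longest-side with zero padding, and its inverse for masks


@dataclass(frozen=True)
class PaddingRecord:
    """Bookkeeping needed to undo :func:`resize_longest_side_pad` on a mask."""

    scale: float
    pad_top: int
    pad_bottom: int
    pad_left: int
    pad_right: int
    original_height: int
    original_width: int

    @property
    def padded_side(self) -> int:
        inner_h = int(round_half_away(self.original_height * self.scale))
        return inner_h + self.pad_top + self.pad_bottom


def _resize(img: np.ndarray, shape: tuple[int, int], *, nearest: bool) -> np.ndarray:
    order = 0 if nearest else 1
    out = _sk_resize(
        img.astype(float),
        shape,
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out


def resize_longest_side_pad(img: np.ndarray, target: int) -> tuple[np.ndarray, PaddingRecord]:
    """Scale the long side to ``target`` and zero-pad the short side square.

    The aspect ratio is preserved (short side rounded to the nearest pixel)
    and the short-side deficit ``d`` is split ``floor(d/2)`` leading /
    ``ceil(d/2)`` trailing. Returns the padded ``target×target`` image and a
    :class:`PaddingRecord` that lets :func:`restore_mask` undo the shape
    transform exactly.
    """
    img = validate_image(img)
    if target < 1:
        raise ValueError("target must be >= 1")
    h, w = img.shape[:2]
    scale = target / max(h, w)
    new_h = int(round_half_away(h * scale)) if h != max(h, w) else target
    new_w = int(round_half_away(w * scale)) if w != max(h, w) else target
    new_h, new_w = max(1, min(new_h, target)), max(1, min(new_w, target))
    resized = _resize(img, (new_h, new_w), nearest=False)
    dh, dw = target - new_h, target - new_w
    pad_top, pad_bottom = dh // 2, dh - dh // 2
    pad_left, pad_right = dw // 2, dw - dw // 2
    pad_spec = [(pad_top, pad_bottom), (pad_left, pad_right)] + ([(0, 0)] if img.ndim == 3 else [])
    padded = np.pad(resized, pad_spec, mode="constant")
    rec = PaddingRecord(scale, pad_top, pad_bottom, pad_left, pad_right, h, w)
    out = np.clip(round_half_away(padded), 0, 255).astype(np.uint8)
    return out, rec


def resize_mask_longest_side_pad(mask: np.ndarray, target: int) -> tuple[np.ndarray, PaddingRecord]:
    """Mask counterpart of :func:`resize_longest_side_pad` (nearest neighbour)."""
    mask = validate_mask(mask)
    if target < 1:
        raise ValueError("target must be >= 1")
    h, w = mask.shape
    scale = target / max(h, w)
    new_h = target if h == max(h, w) else max(1, min(int(round_half_away(h * scale)), target))
    new_w = target if w == max(h, w) else max(1, min(int(round_half_away(w * scale)), target))
    resized = _resize(mask, (new_h, new_w), nearest=True)
    dh, dw = target - new_h, target - new_w
    pad_top, pad_bottom = dh // 2, dh - dh // 2
    pad_left, pad_right = dw // 2, dw - dw // 2
    padded = np.pad(resized, [(pad_top, pad_bottom), (pad_left, pad_right)], mode="constant")
    rec = PaddingRecord(scale, pad_top, pad_bottom, pad_left, pad_right, h, w)
    return padded.astype(np.uint8), rec


def restore_mask(mask: np.ndarray, rec: PaddingRecord) -> np.ndarray:
    """Undo padding then rescale a mask back to its pre-resize shape.

    Padding rows/columns are stripped first (the inverse of the forward
    order), then the inner raster is rescaled to
    ``(original_height, original_width)`` with nearest-neighbour
    interpolation, which keeps values in ``{0, 1}``.
    """
    mask = validate_mask(mask)
    side = rec.padded_side
    if mask.shape != (side, side):
        raise ValueError(f"mask shape {mask.shape} does not match padded shape ({side}, {side})")
    inner = mask[
        rec.pad_top : side - rec.pad_bottom,
        rec.pad_left : side - rec.pad_right,
    ]
    restored = _resize(inner, (rec.original_height, rec.original_width), nearest=True)
    return (restored > 0.5).astype(np.uint8)


def resize_image(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``shape`` (rows, cols), returned as uint8."""
    img = validate_image(img)
    out = _resize(img, shape, nearest=False)
    return np.clip(round_half_away(out), 0, 255).astype(np.uint8)


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour mask resize to ``shape`` (rows, cols)."""
    mask = validate_mask(mask)
    return (_resize(mask, shape, nearest=True) > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# disk I/O — images as PNG/TIFF, masks as single-channel PNG (0/255 on disk)


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    return validate_image(iio.imread(path))


def write_image(path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, validate_image(img).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return (raw > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (validate_mask(mask) * 255).astype(np.uint8))


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Luminance (Rec. 601 weights) as float64 in [0, 255]."""
    img = validate_image(img)
    if img.ndim == 2:
        return img.astype(float)
    return img.astype(float) @ np.array([0.299, 0.587, 0.114])
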