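"""Tile-of-interest filtering, training-set augmentation, classification metrics.

Retained tiles still include regions unusable for counting (blank spaces,
over-staining, debris), so a binary TOI / non-TOI classifier runs on each
tile after a bilinear resize to 224×224. The classifier sits behind a
backend contract; the shipped reference backend uses three classical
features — dark-blob count, mean luminance and luminance variance — with
soft gates, which is enough to separate well-populated monolayer tiles
from blank, over-stained, body and tail tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .imaging import resize_image, to_grayscale, validate_image
from .tiling import TileRef

TOI = "TOI"
NON_TOI = "non-TOI"


class TileClassifierBackend(Protocol):
    def predict(self, tile_224: np.ndarray, ref: TileRef | None = None) -> tuple[str, float]: ...


def classify_tiles(
    tiles: Sequence[tuple[TileRef, np.ndarray]],
    backend: TileClassifierBackend,
    target_size: int = 224,
) -> list[tuple[TileRef, str, float]]:
    """Resize each tile to 224×224 and score it; order is preserved."""
    out = []
    for ref, img in tiles:
        small = resize_image(validate_image(img), (target_size, target_size))
        label, score = backend.predict(small, ref=ref)
        if label not in (TOI, NON_TOI):
            raise ValueError(f"backend label {label!r} not in {{TOI, non-TOI}}")
        out.append((ref, label, float(score)))
    return out


# ---------------------------------------------------------------------------
# reference backend


def _blob_count_and_luminance(tile: np.ndarray) -> tuple[int, float, float]:
    gray = to_grayscale(tile)
    mean_lum = float(gray.mean())
    var_lum = float(gray.var())
    # dark objects against a pale background; Otsu fails on flat tiles
    if gray.std() < 2.0:
        return 0, mean_lum, var_lum
    thr = threshold_otsu(gray)
    dark = gray < min(thr, mean_lum - 10)
    if not dark.any():
        return 0, mean_lum, var_lum
    labels, n = ndimage.label(dark)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        n = int((sizes >= 4).sum())  # ignore speckle
    return n, mean_lum, var_lum


def _soft_gate(x: float, lo: float, hi: float, softness: float) -> float:
    """Smooth indicator of lo <= x <= hi, 0.5 exactly at the edges."""
    s_lo = 1.0 / (1.0 + np.exp(-(x - lo) / softness))
    s_hi = 1.0 / (1.0 + np.exp((x - hi) / softness))
    return float(s_lo * s_hi)


@dataclass(frozen=True)
class ReferenceTOIBackend:
    """Classical TOI rule: enough separate cells on a pale, clean field.

    A tile is of interest iff its dark-blob count is in ``[n_lo, n_hi]``
    (blank and sparse-tail tiles fall below, dense body texture explodes
    above) and its mean luminance is in ``[l_lo, l_hi]`` (over-stained
    tiles are dark). The score is the product of per-feature soft gates.
    """

    n_lo: float = 8.0
    n_hi: float = 150.0
    l_lo: float = 180.0
    l_hi: float = 252.0
    backend_id: str = "reference-blob"

    def predict(self, tile_224: np.ndarray, ref: TileRef | None = None) -> tuple[str, float]:
        n, lum, _ = _blob_count_and_luminance(tile_224)
        in_range = self.n_lo <= n <= self.n_hi and self.l_lo <= lum <= self.l_hi
        score = _soft_gate(n, self.n_lo, self.n_hi, 2.0) * _soft_gate(lum, self.l_lo, self.l_hi, 4.0)
        return (TOI if in_range else NON_TOI), score


@dataclass(frozen=True)
class OracleTOIBackend:
    """Testing backend that reads the generator's tile labels."""

    tile_labels_gt: dict
    backend_id: str = "oracle"

    def predict(self, tile_224: np.ndarray, ref: TileRef | None = None) -> tuple[str, float]:
        if ref is None:
            raise ValueError("oracle TOI backend needs the tile reference")
        label = self.tile_labels_gt[ref]
        return label, 1.0 if label == TOI else 0.0


@dataclass(frozen=True)
class ConstantTOIBackend:
    label: str = NON_TOI
    backend_id: str = "constant"

    def predict(self, tile_224: np.ndarray, ref: TileRef | None = None) -> tuple[str, float]:
        return self.label, 1.0 if self.label == TOI else 0.0


# ---------------------------------------------------------------------------
# augmentation


_GEOMETRIC_OPS = {
    "hflip": lambda a: np.flip(a, axis=1),
    "vflip": lambda a: np.flip(a, axis=0),
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "rot270": lambda a: np.rot90(a, 3),
}


@dataclass(frozen=True)
class AugmentationSpec:
    """Which transforms may be sampled and how many images per class to reach."""

    ops: tuple[str, ...] = ("hflip", "vflip", "rot90", "rot180", "rot270", "brightness", "contrast")
    brightness_range: tuple[float, float] = (0.8, 1.2)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    target_count_per_class: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(_GEOMETRIC_OPS) | {"brightness", "contrast"}
        unknown = set(self.ops) - known
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")


def apply_augmentation(
    img: np.ndarray, op: str, spec: AugmentationSpec, rng: np.random.Generator
) -> np.ndarray:
    if op in _GEOMETRIC_OPS:
        return np.ascontiguousarray(_GEOMETRIC_OPS[op](img))
    x = img.astype(float)
    if op == "brightness":
        x = x * rng.uniform(*spec.brightness_range)
    elif op == "contrast":
        x = (x - 128.0) * rng.uniform(*spec.contrast_range) + 128.0
    else:
        raise ValueError(f"unknown op {op!r}")
    return np.clip(np.round(x), 0, 255).astype(np.uint8)


def augment_training_set(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    spec: AugmentationSpec,
) -> tuple[list[np.ndarray], list[str]]:
    """Top each class up to ``target_count_per_class`` with augmented copies.

    All originals are kept; the per-class deficit is filled by sampling
    (image, op) pairs uniformly with replacement under the spec's seed, so
    the output is reproducible and its size exact.
    """
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    rng = np.random.default_rng(spec.seed)
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    out_imgs: list[np.ndarray] = list(images)
    out_labels: list[str] = list(labels)
    for lab in sorted(by_class):
        idxs = by_class[lab]
        deficit = spec.target_count_per_class - len(idxs)
        if deficit < 0:
            raise ValueError(
                f"target_count_per_class={spec.target_count_per_class} below the "
                f"{len(idxs)} originals of class {lab!r}"
            )
        for _ in range(deficit):
            src = idxs[int(rng.integers(len(idxs)))]
            op = spec.ops[int(rng.integers(len(spec.ops)))]
            out_imgs.append(apply_augmentation(images[src], op, spec, rng))
            out_labels.append(lab)
    return out_imgs, out_labels


# ---------------------------------------------------------------------------
# classification metrics


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float | None  # None when undefined (single-class truth)
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auroc": self.auroc,
        }


def cls_metrics(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    scores: np.ndarray | Sequence[float] | None = None,
    positive_label: str | None = None,
    class_order: Sequence[str] | None = None,
) -> ClassificationMetrics:
    """Accuracy / precision / recall / F1 / AUROC.

    Binary mode (``positive_label`` given): metrics for the positive class,
    AUROC from the positive-class score by the rank statistic with tied
    ranks averaged. Multiclass mode: macro-averaged precision/recall/F1 and
    macro one-vs-rest AUROC from a score matrix whose columns follow
    ``class_order``. AUROC is ``None`` whenever the truth is single-class.
    """
    from sklearn import metrics as skm

    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels) or not true_labels:
        raise ValueError("label sequences must be nonempty and equal length")
    acc = float(np.mean([t == p for t, p in zip(true_labels, pred_labels)]))

    if positive_label is not None:
        yt = np.array([t == positive_label for t in true_labels], dtype=int)
        yp = np.array([p == positive_label for p in pred_labels], dtype=int)
        prec = skm.precision_score(yt, yp, zero_division=0)
        rec = skm.recall_score(yt, yp, zero_division=0)
        f1 = skm.f1_score(yt, yp, zero_division=0)
        auroc = None
        if scores is not None and len(np.unique(yt)) == 2:
            auroc = float(skm.roc_auc_score(yt, np.asarray(scores, dtype=float)))
        per_class = {}
    else:
        order = list(class_order) if class_order is not None else sorted(set(true_labels) | set(pred_labels))
        prec = skm.precision_score(true_labels, pred_labels, labels=order, average="macro", zero_division=0)
        rec = skm.recall_score(true_labels, pred_labels, labels=order, average="macro", zero_division=0)
        f1 = skm.f1_score(true_labels, pred_labels, labels=order, average="macro", zero_division=0)
        auroc = None
        per_class = {}
        if scores is not None:
            s = np.asarray(scores, dtype=float)
            present = [c for c in order if c in set(true_labels)]
            aucs = []
            for c in present:
                yt = np.array([t == c for t in true_labels], dtype=int)
                if len(np.unique(yt)) == 2:
                    a = float(skm.roc_auc_score(yt, s[:, order.index(c)]))
                    per_class[c] = a
                    aucs.append(a)
            auroc = float(np.mean(aucs)) if aucs else None
    return ClassificationMetrics(acc, float(prec), float(rec), float(f1), auroc, per_class)
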