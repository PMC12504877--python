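"""Cell crop extraction, 22-class classification, and review-gating policy.

Each surviving mask candidate is cropped from its tile as a square with a
configurable box offset, resized to 224×224 and classified by a backend
returning a probability vector over the 22-class taxonomy. Two safety
policies follow clinical screening practice: a per-cell review flag when
the top-class confidence falls below a threshold (default 60%), and a
slide-level "automatic rescreening" alert when more than one class shows a
misclassification rate of at least 10% on a labelled validation run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Protocol, Sequence

import numpy as np

from .cellseg import MaskCandidate
from .imaging import BBox, box_iou, resize_image, round_half_away, to_grayscale
from .taxonomy import DEFAULT_TAXONOMY, CellTaxonomy
from .tiling import TileRef

logger = logging.getLogger(__name__)

REVIEW_THRESHOLD = 0.60
RESCREEN_RATE = 0.10


class CellClassifierBackend(Protocol):
    def predict(self, crop_224: np.ndarray, record=None) -> np.ndarray: ...


@dataclass(frozen=True)
class CellRecord:
    """A segmented cell on its way through classification."""

    tile: TileRef
    candidate: MaskCandidate
    crop: np.ndarray | None = None
    label: str | None = None
    confidence: float | None = None
    needs_review: bool = False


def crop_with_offset(tile: np.ndarray, bbox: BBox, offset: int) -> np.ndarray:
    """Square crop of side ``max(w, h) + 2·offset`` centred on the box.

    Regions of the square that fall outside the tile are zero-padded, so
    the output side is exact regardless of where the box sits.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    side = max(bbox.width, bbox.height) + 2 * offset
    cx, cy = bbox.center
    x0 = int(round_half_away(cx)) - side // 2
    y0 = int(round_half_away(cy)) - side // 2
    out_shape = (side, side, 3) if tile.ndim == 3 else (side, side)
    out = np.zeros(out_shape, dtype=tile.dtype)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + side, tile.shape[1]), min(y0 + side, tile.shape[0])
    if sx1 > sx0 and sy1 > sy0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = tile[sy0:sy1, sx0:sx1]
    return out


def classify_cells(
    records: Sequence[CellRecord],
    backend: CellClassifierBackend,
    taxonomy: CellTaxonomy = DEFAULT_TAXONOMY,
    review_threshold: float = REVIEW_THRESHOLD,
    crop_size: int = 224,
) -> list[CellRecord]:
    """Label each record by argmax probability and set the review flag.

    Ties in the probability vector resolve to the lowest taxonomy index.
    Records whose backend output is malformed (wrong length, negative
    entries, or probabilities not summing to 1) are dropped with a log
    message rather than poisoning the count.
    """
    out: list[CellRecord] = []
    for rec in records:
        if rec.crop is None:
            raise ValueError("record has no crop; run crop_with_offset first")
        crop = resize_image(rec.crop, (crop_size, crop_size))
        probs = np.asarray(backend.predict(crop, record=rec), dtype=float)
        if probs.shape != (len(taxonomy),) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-6:
            logger.warning("malformed probability vector for cell at %s; record dropped", rec.candidate.prompt)
            continue
        idx = int(np.argmax(probs))  # argmax takes the first (lowest-index) maximum
        conf = float(probs[idx])
        out.append(
            replace(
                rec,
                label=taxonomy.names[idx],
                confidence=conf,
                needs_review=conf < review_threshold,
            )
        )
    return out


# ---------------------------------------------------------------------------
# reference backend: nearest class prototype on colour/size features


def _crop_features(crop: np.ndarray) -> np.ndarray:
    """(area fraction, mean object RGB, mean nucleus RGB) — 7 features.

    The object is the dark region of the crop (below the midpoint between
    the darkest and brightest luminance); the nucleus proxy is its darkest
    40% of pixels.
    """
    gray = to_grayscale(crop)
    lo, hi = float(gray.min()), float(gray.max())
    if hi - lo < 8:  # featureless crop: no object to measure
        return None
    obj = gray < (lo + hi) / 2.0
    area_frac = float(obj.mean())
    rgb = crop.reshape(-1, 3).astype(float) if crop.ndim == 3 else np.repeat(
        crop.reshape(-1, 1).astype(float), 3, axis=1
    )
    flat_obj = obj.ravel()
    obj_rgb = rgb[flat_obj].mean(axis=0)
    g = gray.ravel()[flat_obj]
    nuc_cut = np.quantile(g, 0.4)
    nuc_sel = flat_obj.copy()
    nuc_sel[flat_obj] = g <= nuc_cut
    nuc_rgb = rgb[nuc_sel].mean(axis=0) if nuc_sel.any() else obj_rgb
    return np.concatenate([[area_frac * 255.0], obj_rgb, nuc_rgb])


class ReferenceCellClassifier:
    """Nearest-centroid classifier over simple colour/size features.

    Per-class prototypes are fitted from a labelled set of crops (one mean
    feature vector per class, features standardised by the training
    statistics); prediction is a softmax over negative squared distances to
    the prototypes. The softmax temperature is set so that on a balanced
    validation split the fraction of confident (≥60%) predictions tracks
    the accuracy, keeping the review gate informative. Classes absent from the training set keep a far-away
    placeholder prototype and effectively receive near-zero probability.
    """

    backend_id = "reference-centroid"

    def __init__(self, taxonomy: CellTaxonomy = DEFAULT_TAXONOMY, temperature: float = 0.5):
        self.taxonomy = taxonomy
        self.temperature = temperature
        self.prototypes: np.ndarray | None = None
        self._mu: np.ndarray | None = None
        self._sigma: np.ndarray | None = None

    def fit(self, crops: Sequence[np.ndarray], labels: Sequence[str]) -> "ReferenceCellClassifier":
        if len(crops) != len(labels) or not crops:
            raise ValueError("need equal numbers of crops and labels, at least one")
        all_feats = [_crop_features(resize_image(c, (224, 224))) for c in crops]
        keep = [i for i, f in enumerate(all_feats) if f is not None]
        if not keep:
            raise ValueError("no training crop contains a measurable object")
        labels = [labels[i] for i in keep]
        feats = np.stack([all_feats[i] for i in keep])
        self._mu = feats.mean(axis=0)
        self._sigma = feats.std(axis=0) + 1e-6
        z = (feats - self._mu) / self._sigma
        protos = np.full((len(self.taxonomy), z.shape[1]), 1e3)
        for i, name in enumerate(self.taxonomy.names):
            sel = [j for j, lab in enumerate(labels) if lab == name]
            if sel:
                protos[i] = z[sel].mean(axis=0)
        self.prototypes = protos
        return self

    def predict(self, crop_224: np.ndarray, record=None) -> np.ndarray:
        if self.prototypes is None:
            raise RuntimeError("classifier not fitted")
        raw = _crop_features(crop_224)
        if raw is None:  # featureless crop: no evidence for any class
            return np.full(len(self.taxonomy), 1.0 / len(self.taxonomy))
        f = (raw - self._mu) / self._sigma
        d2 = ((self.prototypes - f) ** 2).sum(axis=1)
        logits = -d2 / self.temperature
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()


class OracleCellClassifier:
    """Testing backend: one-hot ground-truth label by best mask overlap.

    The candidate box (native tile coordinates) is matched to the
    ground-truth instance of the same tile with the highest box IoU; the
    matched instance's label becomes a one-hot probability vector. With no
    overlapping instance the vector is uniform (maximally unconfident).
    """

    backend_id = "oracle"

    def __init__(self, case, taxonomy: CellTaxonomy = DEFAULT_TAXONOMY):
        self.case = case
        self.taxonomy = taxonomy
        self._boxes: dict = {}

    def _tile_gt(self, ref: TileRef):
        key = (ref.row_index, ref.col_index)
        if key not in self._boxes:
            spec = self.case.tile_specs[key]
            size = self.case.params.tile_size
            self._boxes[key] = [(c.bbox(size), c.label) for c in spec.cells]
        return self._boxes[key]

    def predict(self, crop_224: np.ndarray, record=None) -> np.ndarray:
        n = len(self.taxonomy)
        if record is None:
            return np.full(n, 1.0 / n)
        best_label, best_iou = None, 0.0
        for gt_box, label in self._tile_gt(record.tile):
            iou = box_iou(record.candidate.bbox, gt_box)
            if iou > best_iou:
                best_label, best_iou = label, iou
        if best_label is None:
            return np.full(n, 1.0 / n)
        p = np.zeros(n)
        p[self.taxonomy.index(best_label)] = 1.0
        return p


# ---------------------------------------------------------------------------
# rescreening alert


def rescreen_alert(
    confusion: np.ndarray,
    taxonomy: CellTaxonomy = DEFAULT_TAXONOMY,
    rate_threshold: float = RESCREEN_RATE,
) -> tuple[bool, list[str]]:
    """Slide-level alert when misclassification is broad, not isolated.

    ``confusion[i, j]`` counts cells of true class ``i`` predicted as
    ``j``. The per-class misclassification rate is ``1 - diag/rowsum``;
    the alert fires iff **more than one** class reaches ``rate_threshold``.
    Classes with empty rows have no defined rate and are excluded; if every
    row is empty the alert is undefined and an error is raised.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    row_sums = confusion.sum(axis=1)
    if (row_sums == 0).all():
        raise ValueError("undefined: confusion matrix has no populated rows")
    offenders = []
    for i, total in enumerate(row_sums):
        if total == 0:
            continue
        rate = (total - confusion[i, i]) / total  # exact at x/10 rates
        if rate >= rate_threshold:
            name = taxonomy.names[i] if i < len(taxonomy) else f"class_{i}"
            offenders.append(name)
    return len(offenders) > 1, offenders


def confusion_matrix(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    taxonomy: CellTaxonomy = DEFAULT_TAXONOMY,
) -> np.ndarray:
    m = np.zeros((len(taxonomy), len(taxonomy)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        m[taxonomy.index(t), taxonomy.index(p)] += 1
    return m
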