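"""End-to-end orchestration: thumbnail → ROI → tiles → TOI → cells → DCC.

The pipeline wires the stage modules together behind a validated
configuration object and a backend registry. Backends are resolved by name
(``reference`` classical implementations, ``oracle`` ground-truth-reading
test backends, degenerate ``constant`` backends), so trained models can be
plugged in without touching orchestration code. All randomness is routed
through one seed, fanned out per stage by a CRC-based derivation so stages
are independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from . import cellcls, cellseg, dcc, roi, tiling, toi
from .imaging import resize_image
from .synthetic import SceneParams, SyntheticCase, generate_case
from .taxonomy import DEFAULT_TAXONOMY

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage substream seed: CRC32 of the stage name folded into the seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ROIConfig:
    backend: str = "reference"
    target_size: int = 256
    window: int = 15
    quantiles: tuple[float, float] = (0.30, 0.70)


@dataclass(frozen=True)
class TileConfig:
    coverage_tau: float = 0.5


@dataclass(frozen=True)
class TOIConfig:
    backend: str = "reference"
    threshold: float = 0.5


@dataclass(frozen=True)
class CellSegConfig:
    backend: str = "reference"
    seg_size: int = 1024
    grid_n: int = 32
    score_min: float = 0.5
    area_min: int = 80
    area_max: int = 40_000
    nms_iou: float = 0.7


@dataclass(frozen=True)
class CellClsConfig:
    backend: str = "reference"
    offset: int = 12
    review_threshold: float = 0.60
    crop_size: int = 224


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    roi: ROIConfig = field(default_factory=ROIConfig)
    tile: TileConfig = field(default_factory=TileConfig)
    toi: TOIConfig = field(default_factory=TOIConfig)
    cellseg: CellSegConfig = field(default_factory=CellSegConfig)
    cellcls: CellClsConfig = field(default_factory=CellClsConfig)
    count_needs_review: bool = True  # review-flagged cells still counted by default

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Strict construction: unknown keys anywhere are rejected."""
        d = dict(d)
        sections = {"roi": ROIConfig, "tile": TileConfig, "toi": TOIConfig,
                    "cellseg": CellSegConfig, "cellcls": CellClsConfig}
        kwargs: dict = {}
        for name, section_cls in sections.items():
            if name in d:
                sub = dict(d.pop(name))
                allowed = set(section_cls.__dataclass_fields__)
                unknown = set(sub) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
                if "quantiles" in sub:
                    sub["quantiles"] = tuple(sub["quantiles"])
                kwargs[name] = section_cls(**sub)
        allowed_top = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed_top
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @classmethod
    def all_oracle(cls, **overrides) -> "PipelineConfig":
        """Oracle backends everywhere, with a grid dense enough to hit every cell."""
        base = cls(
            roi=ROIConfig(backend="oracle"),
            toi=TOIConfig(backend="oracle"),
            cellseg=CellSegConfig(backend="oracle", grid_n=64),
            cellcls=CellClsConfig(backend="oracle"),
        )
        return replace(base, **overrides)


# ---------------------------------------------------------------------------
# backend registry


BackendFactory = Callable[[PipelineConfig, SyntheticCase | None], object]
_REGISTRY: dict[tuple[str, str], BackendFactory] = {}


def register_backend(stage: str, name: str, factory: BackendFactory) -> None:
    _REGISTRY[(stage, name)] = factory


def resolve_backend(stage: str, name: str, config: PipelineConfig, case=None):
    try:
        factory = _REGISTRY[(stage, name)]
    except KeyError:
        known = sorted(n for s, n in _REGISTRY if s == stage)
        raise KeyError(f"no backend {name!r} for stage {stage!r}; known: {known}") from None
    return factory(config, case)


def _training_scene(tile_size: int) -> SceneParams:
    """Balanced all-junction scene used to fit the reference cell classifier."""
    uniform = {n: 1.0 / 22.0 for n in DEFAULT_TAXONOMY.names}
    return SceneParams(
        wsi_height=3 * tile_size,
        wsi_width=3 * tile_size,
        tile_size=tile_size,
        thumb_factor=max(1, tile_size // 16),
        band_fractions=(0.0, 1.0, 0.0),
        bad_tile_fraction=0.0,
        cells_per_good_tile=40.0,
        class_proportions=uniform,
    )


def fit_reference_cell_classifier(
    tile_size: int = 1600, seed: int = 12345, offset: int = 12
) -> cellcls.ReferenceCellClassifier:
    """Fit nearest-centroid prototypes on a balanced labelled synthetic split."""
    case = generate_case(_training_scene(tile_size), seed)
    crops, labels = [], []
    for inst in case.cell_instances_gt:
        img = case.tile_image(inst.tile.row_index, inst.tile.col_index)
        box = inst.spec.bbox(case.params.tile_size)
        crops.append(cellcls.crop_with_offset(img, box, offset))
        labels.append(inst.label)
    return cellcls.ReferenceCellClassifier().fit(crops, labels)


def _register_defaults() -> None:
    register_backend("roi", "reference", lambda cfg, case: roi.ReferenceTextureROIBackend(
        window=cfg.roi.window, quantiles=cfg.roi.quantiles))
    register_backend("roi", "oracle", lambda cfg, case: roi.OracleROIBackend(
        case.roi_mask_gt, cfg.roi.target_size))
    register_backend("roi", "zeros", lambda cfg, case: roi.ConstantROIBackend(0))
    register_backend("roi", "ones", lambda cfg, case: roi.ConstantROIBackend(1))
    register_backend("toi", "reference", lambda cfg, case: toi.ReferenceTOIBackend())
    register_backend("toi", "oracle", lambda cfg, case: toi.OracleTOIBackend(case.tile_labels_gt))
    register_backend("toi", "always-non-toi", lambda cfg, case: toi.ConstantTOIBackend(toi.NON_TOI))
    register_backend("cellseg", "reference", lambda cfg, case: cellseg.ReferencePromptableSegmenter())
    register_backend("cellseg", "oracle", lambda cfg, case: cellseg.OraclePromptableSegmenter(
        case, cfg.cellseg.seg_size))
    register_backend("cellcls", "reference", lambda cfg, case: fit_reference_cell_classifier(
        tile_size=case.params.tile_size if case is not None else 1600,
        seed=stage_seed(cfg.seed, "cellcls-train"),
        offset=cfg.cellcls.offset))
    register_backend("cellcls", "oracle", lambda cfg, case: cellcls.OracleCellClassifier(case))


_register_defaults()


# ---------------------------------------------------------------------------
# run report


@dataclass
class RunReport:
    status: str
    seed: int
    config: dict
    n_tiles: int
    n_retained: int
    n_toi: int
    n_candidates: int
    n_cells: int
    n_needs_review: int
    dcc_result: dcc.DCCResult | None
    stage_seconds: dict = field(default_factory=dict)
    # heavy per-stage artefacts, kept for evaluation but not serialised
    roi_result: roi.ROIResult | None = None
    retained_tiles: list = field(default_factory=list)
    toi_decisions: list = field(default_factory=list)  # (TileRef, label, score)
    cell_records: list = field(default_factory=list)

    def to_dict(self, include_timings: bool = True) -> dict:
        d = {
            "status": self.status,
            "seed": self.seed,
            "config": self.config,
            "counts": {
                "tiles": self.n_tiles,
                "retained": self.n_retained,
                "toi": self.n_toi,
                "candidates": self.n_candidates,
                "cells": self.n_cells,
                "needs_review": self.n_needs_review,
            },
            "dcc": self.dcc_result.to_dict() if self.dcc_result else None,
        }
        if include_timings:
            d["stage_seconds"] = dict(self.stage_seconds)
        return d

    def to_json(self, include_timings: bool = True) -> str:
        return json.dumps(self.to_dict(include_timings), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# the run itself


def run_pipeline(
    case: SyntheticCase,
    config: PipelineConfig | None = None,
    backends: dict[str, object] | None = None,
) -> RunReport:
    """Execute the full differential-count workflow on one case.

    ``backends`` may supply pre-built backend instances per stage name,
    otherwise they are resolved from the registry by the configured names.
    Degenerate situations (empty ROI, no TOI tiles, no countable cells)
    terminate gracefully with a diagnostic ``status``.
    """
    config = config or PipelineConfig()
    backends = backends or {}
    params = case.params
    t_all: dict[str, float] = {}

    def _backend(stage: str, name: str):
        return backends.get(stage) or resolve_backend(stage, name, config, case)

    t0 = time.perf_counter()
    roi_backend = _backend("roi", config.roi.backend)
    roi_result = roi.segment_roi(case.thumbnail, roi_backend, config.roi.target_size, ref=case)
    t_all["roi"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tiles = tiling.grid_tiles(params.wsi_height, params.wsi_width, params.tile_size)
    retained = tiling.retain_tiles(
        tiles, roi_result.mask_thumb, params.thumb_factor, config.tile.coverage_tau
    )
    t_all["tiling"] = time.perf_counter() - t0
    report = RunReport(
        status="ok",
        seed=config.seed,
        config=config.to_dict(),
        n_tiles=len(tiles),
        n_retained=len(retained),
        n_toi=0,
        n_candidates=0,
        n_cells=0,
        n_needs_review=0,
        dcc_result=None,
        stage_seconds=t_all,
        roi_result=roi_result,
        retained_tiles=retained,
    )
    if not retained:
        report.status = "empty-roi"
        return report

    t0 = time.perf_counter()
    toi_backend = _backend("toi", config.toi.backend)
    decisions = toi.classify_tiles(
        [(t, case.tile_image(t.row_index, t.col_index)) for t in retained], toi_backend
    )
    report.toi_decisions = decisions
    toi_tiles = [t for t, label, _ in decisions if label == toi.TOI]
    report.n_toi = len(toi_tiles)
    t_all["toi"] = time.perf_counter() - t0
    if not toi_tiles:
        report.status = "no-toi"
        return report

    t0 = time.perf_counter()
    seg_backend = _backend("cellseg", config.cellseg.backend)
    cls_backend = _backend("cellcls", config.cellcls.backend)
    grid = cellseg.build_point_grid(config.cellseg.seg_size, config.cellseg.grid_n)
    records: list[cellcls.CellRecord] = []
    n_candidates = 0
    for t in toi_tiles:
        img = case.tile_image(t.row_index, t.col_index)
        seg_img = resize_image(img, (config.cellseg.seg_size, config.cellseg.seg_size))
        cands = cellseg.seg_every(
            seg_img,
            seg_backend,
            grid,
            score_min=config.cellseg.score_min,
            area_range=(config.cellseg.area_min, config.cellseg.area_max),
            nms_iou=config.cellseg.nms_iou,
            ref=t,
        )
        n_candidates += len(cands)
        batch = []
        for cand in cands:
            native = cellseg.map_candidate_to_native(
                cand, config.cellseg.seg_size, params.tile_size
            )
            crop = cellcls.crop_with_offset(img, native.bbox, config.cellcls.offset)
            batch.append(cellcls.CellRecord(tile=t, candidate=native, crop=crop))
        classified = cellcls.classify_cells(
            batch,
            cls_backend,
            review_threshold=config.cellcls.review_threshold,
            crop_size=config.cellcls.crop_size,
        )
        records.extend(replace(r, crop=None) for r in classified)  # release pixels
    report.n_candidates = n_candidates
    report.cell_records = records
    report.n_cells = len(records)
    report.n_needs_review = sum(r.needs_review for r in records)
    t_all["cells"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    counted = records if config.count_needs_review else [r for r in records if not r.needs_review]
    try:
        report.dcc_result = dcc.aggregate_dcc([r.label for r in counted])
    except dcc.NoCountableCellsError:
        report.status = "no-countable-cells"
    t_all["dcc"] = time.perf_counter() - t0
    return report


# ---------------------------------------------------------------------------
# evaluation against ground truth


def _gt_boxes_by_tile(case: SyntheticCase, tile_keys) -> dict:
    """Rasterise each ground-truth polygon once: {tile: [(BBox, label)]}."""
    size = case.params.tile_size
    return {
        key: [(c.bbox(size), c.label) for c in case.tile_specs[key].cells]
        for key in tile_keys
    }


def evaluate_run(report: RunReport, case: SyntheticCase) -> dict:
    """Stage metrics and count agreement of a run against case ground truth.

    Returns a bundle with explicit ``None`` gaps where a ground-truth
    component or a pipeline product is missing.
    """
    bundle: dict = {}

    if report.roi_result is not None:
        iou, dice, pa = roi.seg_metrics(report.roi_result.mask_thumb, case.roi_mask_gt)
        bundle["roi"] = {"iou": iou, "dice": dice, "pixel_accuracy": pa}
    else:
        bundle["roi"] = None

    if report.toi_decisions:
        gt = case.tile_labels_gt
        refs = [t for t, _, _ in report.toi_decisions]
        m = toi.cls_metrics(
            [gt[t] for t in refs],
            [label for _, label, _ in report.toi_decisions],
            scores=[s for _, _, s in report.toi_decisions],
            positive_label=toi.TOI,
        )
        bundle["toi"] = m.to_dict()
    else:
        bundle["toi"] = None

    # detection recall pooled over the tiles the pipeline actually processed
    processed = {(r.tile.row_index, r.tile.col_index) for r in report.cell_records}
    gt_by_tile = _gt_boxes_by_tile(case, sorted(processed))
    total_gt = matched50 = matched75 = 0
    for key in sorted(processed):
        gt_boxes = [b for b, _ in gt_by_tile[key]]
        if not gt_boxes:
            continue
        preds = [
            (r.candidate.bbox, r.candidate.score)
            for r in report.cell_records
            if (r.tile.row_index, r.tile.col_index) == key
        ]
        total_gt += len(gt_boxes)
        matched50 += round(cellseg.recall_at_iou(preds, gt_boxes, 0.50) * len(gt_boxes))
        matched75 += round(cellseg.recall_at_iou(preds, gt_boxes, 0.75) * len(gt_boxes))
    if total_gt:
        bundle["cellseg"] = {
            "recall50": matched50 / total_gt,
            "recall75": matched75 / total_gt,
            "n_gt_cells": total_gt,
        }
    else:
        bundle["cellseg"] = None

    from .imaging import box_iou

    pairs = []
    for rec in report.cell_records:
        best, best_iou = None, 0.0
        for gt_box, label in gt_by_tile.get((rec.tile.row_index, rec.tile.col_index), ()):
            iou = box_iou(rec.candidate.bbox, gt_box)
            if iou > best_iou:
                best, best_iou = label, iou
        if best is not None:
            pairs.append((best, rec.label))
    if pairs:
        true_labels = [t for t, _ in pairs]
        pred_labels = [p for _, p in pairs]
        present = [n for n in DEFAULT_TAXONOMY.names if n in set(true_labels) | set(pred_labels)]
        m = toi.cls_metrics(true_labels, pred_labels, class_order=present)
        bundle["cellcls"] = m.to_dict()
        conf = cellcls.confusion_matrix(true_labels, pred_labels)
        alert, offenders = cellcls.rescreen_alert(conf)
        bundle["rescreen"] = {"alert": alert, "offending_classes": offenders}
    else:
        bundle["cellcls"] = None
        bundle["rescreen"] = None

    if report.dcc_result is not None and case.dcc_gt is not None:
        agreement = dcc.dcc_agreement(report.dcc_result, case.dcc_gt.as_vector())
        diffs = report.dcc_result.as_vector() - case.dcc_gt.as_vector()
        bundle["dcc"] = {
            **agreement.to_dict(),
            "max_abs_error": float(np.abs(diffs).max()),
        }
    else:
        bundle["dcc"] = None
    return bundle


# ---------------------------------------------------------------------------
# run artefact serialisation (consumed by the CLI evaluate/report commands)


def write_run_artifacts(report: RunReport, out_dir) -> Path:
    import pandas as pd

    from .imaging import write_mask

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    if report.roi_result is not None:
        write_mask(out / "roi_mask_pred.png", report.roi_result.mask_thumb)
    pd.DataFrame(
        [
            {"tile_id": t.tile_id, "row": t.row_index, "col": t.col_index,
             "label": label, "score": score}
            for t, label, score in report.toi_decisions
        ]
    ).to_csv(out / "toi_manifest.csv", index=False)
    pd.DataFrame(
        [
            {
                "cell_id": i,
                "tile_id": r.tile.tile_id,
                "row": r.tile.row_index,
                "col": r.tile.col_index,
                "x0": r.candidate.bbox.x0,
                "y0": r.candidate.bbox.y0,
                "x1": r.candidate.bbox.x1,
                "y1": r.candidate.bbox.y1,
                "score": r.candidate.score,
                "label": r.label,
                "confidence": r.confidence,
                "needs_review": r.needs_review,
            }
            for i, r in enumerate(report.cell_records)
        ],
        columns=["cell_id", "tile_id", "row", "col", "x0", "y0", "x1", "y1",
                 "score", "label", "confidence", "needs_review"],
    ).to_csv(out / "cell_table.csv", index=False)
    if report.dcc_result is not None:
        (out / "dcc.json").write_text(json.dumps(report.dcc_result.to_dict(), indent=1))
        pd.DataFrame(
            [
                {"class": k, "count": report.dcc_result.counts[k],
                 "proportion": report.dcc_result.proportions[k]}
                for k in report.dcc_result.counts
            ]
        ).to_csv(out / "dcc.csv", index=False)
    return out
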