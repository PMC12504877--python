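"""Seeded synthetic bone-marrow smear generator with full ground truth.

Real whole-slide aspirate scans are gigapixel images of Wright–Giemsa
stained smears in which only the body–tail junction band holds a countable
monolayer. This module emulates that structure at desk scale so that every
pipeline stage can be exercised against exact ground truth:

* the slide is split into three horizontal texture bands — a dense,
  high-contrast **body**, a mottled monolayer **junction** (the ROI) and a
  sparse pale **tail**;
* the junction is tiled with "good" tiles carrying non-overlapping
  elliptical nucleated cells (class-dependent size and colour pair drawn
  from a 22-class proportion vector) plus a configurable fraction of bad
  tiles (blank or over-stained);
* the thumbnail is the true block-mean downscale of the rendered tiles, so
  thumbnail-scale decisions provably correspond to full-resolution content;
* the ground-truth differential count is computed from the drawn labels by
  the same aggregation the pipeline uses, giving exact oracle closure.

Cells are rasterised from 64-point boundary polygons; the same polygons are
serialised to Labelme-style JSON, so a mask re-rasterised from disk equals
the original bit for bit.

Not modelled: photorealistic stain texture, touching/overlapping cells,
scanner artefacts beyond brightness/contrast jitter.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import polygon as _draw_polygon

from .dcc import DCCResult, NoCountableCellsError, aggregate_dcc
from .imaging import BBox, write_image, write_mask
from .taxonomy import DEFAULT_TAXONOMY
from .tiling import TileRef, grid_tiles

TileKind = Literal["toi", "blank", "overstained", "body", "tail"]

# ---------------------------------------------------------------------------
# per-class rendering style: radius range (native px) and colour pair

_RADIUS_TABLE: dict[str, tuple[int, int]] = {
    "apoptotic cell": (28, 36),
    "atypical lymphocyte": (30, 40),
    "band neutrophil": (34, 42),
    "basophil": (32, 40),
    "early erythroblast": (40, 48),
    "eosinophil": (36, 44),
    "immature lymphocyte": (30, 40),
    "immature monocyte": (42, 50),
    "intermediate erythroblast": (34, 42),
    "intermediate neutrophilic myelocyte": (40, 48),
    "late erythroblast": (28, 36),
    "late neutrophilic myelocyte": (36, 44),
    "lymphocyte": (28, 36),
    "monocyte": (40, 50),
    "myeloblast": (44, 54),
    "plasma cell": (36, 46),
    "prolymphocyte": (32, 42),
    "promonocyte": (44, 52),
    "promyelocyte": (46, 56),
    "segmented neutrophil": (32, 40),
    "smudge cell": (30, 44),
    "others": (28, 40),
}

# A hand-set marrow-like differential: granulocytic series dominant,
# erythroid series ~20%, lymphocytes ~17%, rare precursors/excluded classes
# at fractions of a percent. Sums to 1 exactly.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "apoptotic cell": 0.005,
    "atypical lymphocyte": 0.005,
    "band neutrophil": 0.13,
    "basophil": 0.005,
    "early erythroblast": 0.02,
    "eosinophil": 0.02,
    "immature lymphocyte": 0.005,
    "immature monocyte": 0.005,
    "intermediate erythroblast": 0.08,
    "intermediate neutrophilic myelocyte": 0.05,
    "late erythroblast": 0.10,
    "late neutrophilic myelocyte": 0.08,
    "lymphocyte": 0.17,
    "monocyte": 0.03,
    "myeloblast": 0.015,
    "plasma cell": 0.01,
    "prolymphocyte": 0.005,
    "promonocyte": 0.005,
    "promyelocyte": 0.02,
    "segmented neutrophil": 0.22,
    "smudge cell": 0.01,
    "others": 0.01,
}


def _class_colours() -> dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]]:
    """Deterministic (cytoplasm, nucleus) RGB pair per class.

    Classes are spread over 11 hues × 2 value rings so that colour distance
    between any two classes is large enough for a nearest-centroid reference
    classifier; all cytoplasm colours stay well below background luminance
    so a global dark-object threshold captures whole cells.
    """
    out = {}
    for i, name in enumerate(DEFAULT_TAXONOMY.names):
        hue = (i // 2) / 11.0
        # both rings kept well below background luminance so a global dark
        # threshold segments the full cytoplasm, not just the nucleus
        value = 0.48 + 0.12 * (i % 2)
        cyto = colorsys.hsv_to_rgb(hue, 0.42, value)
        nuc = colorsys.hsv_to_rgb((hue + 0.06) % 1.0, 0.72, 0.30)
        out[name] = (
            tuple(int(round(c * 255)) for c in cyto),
            tuple(int(round(c * 255)) for c in nuc),
        )
    return out


CLASS_COLOURS = _class_colours()

_BACKGROUND = np.array([244.0, 240.0, 243.0])
_CLUTTER = np.array([233.0, 208.0, 214.0])


# ---------------------------------------------------------------------------
# parameters and ground-truth containers


@dataclass(frozen=True)
class SceneParams:
    """Scene geometry, band structure and cell statistics of one smear."""

    wsi_height: int = 16000
    wsi_width: int = 16000
    thumb_factor: int = 100
    tile_size: int = 1600
    band_fractions: tuple[float, float, float] = (0.40, 0.30, 0.30)  # body, junction, tail
    cells_per_good_tile: float = 40.0
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    cell_radius_range: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_RADIUS_TABLE)
    )
    stain_jitter: tuple[float, float] = (0.05, 0.05)  # brightness, contrast half-ranges
    bad_tile_fraction: float = 0.15
    min_cell_gap: int = 8

    def validate(self) -> None:
        if self.wsi_height < self.tile_size or self.wsi_width < self.tile_size:
            raise ValueError("slide smaller than one tile")
        if self.tile_size % self.thumb_factor != 0:
            raise ValueError("tile_size must be divisible by thumb_factor")
        if abs(sum(self.band_fractions) - 1.0) > 1e-9 or any(
            not 0 <= f <= 1 for f in self.band_fractions
        ):
            raise ValueError("band fractions must lie in [0,1] and sum to 1")
        props = self.class_proportions
        if set(props) != set(DEFAULT_TAXONOMY.names):
            raise ValueError("class_proportions must cover the 22-class taxonomy")
        if abs(sum(props.values()) - 1.0) > 1e-9 or any(p < 0 for p in props.values()):
            raise ValueError("class proportions must be nonnegative and sum to 1")
        for name, (lo, hi) in self.cell_radius_range.items():
            if lo < 2 or hi < lo:
                raise ValueError(f"bad radius range for {name}: ({lo}, {hi})")
        if not 0 <= self.bad_tile_fraction <= 1:
            raise ValueError("bad_tile_fraction must be in [0,1]")

    @property
    def thumb_shape(self) -> tuple[int, int]:
        return self.wsi_height // self.thumb_factor, self.wsi_width // self.thumb_factor


def small_scene(**overrides) -> SceneParams:
    """A 4800×4800 scene (9 tiles of 1600) for fast tests and examples."""
    defaults = dict(wsi_height=4800, wsi_width=4800, tile_size=1600, thumb_factor=100)
    defaults.update(overrides)
    return SceneParams(**defaults)


@dataclass(frozen=True)
class CellSpec:
    """One rendered cell: boundary polygon plus its generative parameters."""

    polygon: np.ndarray  # N×2 float array of (x, y) tile-local coords
    label: str
    center: tuple[float, float] | None = None
    axes: tuple[float, float] | None = None
    angle: float | None = None

    def pixel_coords(self, tile_size: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the rasterised polygon, clipped to the tile."""
        rr, cc = _draw_polygon(self.polygon[:, 1], self.polygon[:, 0], (tile_size, tile_size))
        return rr, cc

    def mask(self, tile_size: int) -> np.ndarray:
        m = np.zeros((tile_size, tile_size), dtype=np.uint8)
        rr, cc = self.pixel_coords(tile_size)
        m[rr, cc] = 1
        return m

    def bbox(self, tile_size: int) -> BBox:
        rr, cc = self.pixel_coords(tile_size)
        return BBox(int(cc.min()), int(rr.min()), int(cc.max()) + 1, int(rr.max()) + 1)


@dataclass(frozen=True)
class TileSpec:
    row: int
    col: int
    band: str  # body / junction / tail
    kind: str  # toi / blank / overstained / body / tail
    cells: tuple[CellSpec, ...] = ()
    shortfall: int = 0  # cells dropped by rejection-sampling failure

    @property
    def is_toi(self) -> bool:
        return self.kind == "toi"


@dataclass(frozen=True)
class CellInstance:
    """Ground-truth cell: its tile, geometry and class label."""

    tile: TileRef
    spec: CellSpec

    @property
    def label(self) -> str:
        return self.spec.label


@dataclass
class SyntheticCase:
    """A generated smear with complete ground truth at every stage."""

    params: SceneParams
    seed: int
    tile_specs: dict[tuple[int, int], TileSpec]
    thumbnail: np.ndarray
    roi_mask_gt: np.ndarray
    dcc_gt: DCCResult | None
    tile_image_paths: dict[tuple[int, int], Path] | None = None
    _render_cache: dict = field(default_factory=dict, repr=False)

    # -- derived ground truth ------------------------------------------------

    @property
    def tile_refs(self) -> list[TileRef]:
        return grid_tiles(self.params.wsi_height, self.params.wsi_width, self.params.tile_size)

    @property
    def tile_labels_gt(self) -> dict[TileRef, str]:
        return {
            t: ("TOI" if self.tile_specs[(t.row_index, t.col_index)].is_toi else "non-TOI")
            for t in self.tile_refs
        }

    @property
    def cell_instances_gt(self) -> list[CellInstance]:
        by_index = {(t.row_index, t.col_index): t for t in self.tile_refs}
        out = []
        for key, spec in sorted(self.tile_specs.items()):
            for cell in spec.cells:
                out.append(CellInstance(by_index[key], cell))
        return out

    def junction_tile_refs(self) -> list[TileRef]:
        return [
            t
            for t in self.tile_refs
            if self.tile_specs[(t.row_index, t.col_index)].band == "junction"
        ]

    # -- pixels --------------------------------------------------------------

    def tile_image(self, row: int, col: int) -> np.ndarray:
        key = (row, col)
        if key in self._render_cache:
            return self._render_cache[key]
        if self.tile_image_paths is not None:
            from .imaging import read_image

            img = read_image(self.tile_image_paths[key])
        else:
            spec = self.tile_specs[key]
            img = _render_tile_pixels(self.params, spec, _tile_rng(self.seed, row, col, 2))
        if len(self._render_cache) > 8:
            self._render_cache.clear()
        self._render_cache[key] = img
        return img


# ---------------------------------------------------------------------------
# rendering


def _tile_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _render_background(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.empty((size, size, 3), dtype=np.float32)
    img[:] = _BACKGROUND
    # luminance-only sensor noise, shared across channels (cheap and realistic)
    img += 2.5 * rng.standard_normal((size, size, 1), dtype=np.float32)
    return img


def _paint_clutter(img: np.ndarray, n: int, rng: np.random.Generator) -> None:
    """Faint red-cell discs: visible texture, well above any cell darkness."""
    size = img.shape[0]
    for _ in range(n):
        cy, cx = rng.uniform(0, size, 2)
        r = rng.uniform(0.008 * size, 0.02 * size)
        rr, cc = _draw_ellipse(cy, cx, r, r * rng.uniform(0.8, 1.0), shape=(size, size))
        img[rr, cc] = _CLUTTER + rng.normal(0, 3, 3)


def _paint_cell(img: np.ndarray, cell: CellSpec, rng: np.random.Generator) -> None:
    cyto, nuc = CLASS_COLOURS[cell.label]
    size = img.shape[0]
    rr, cc = cell.pixel_coords(size)
    img[rr, cc] = np.array(cyto, dtype=float) + rng.normal(0, 2, 3)
    cx, cy = cell.center
    a, b = cell.axes
    nrr, ncc = _draw_ellipse(cy, cx, 0.55 * b, 0.55 * a, rotation=cell.angle, shape=(size, size))
    img[nrr, ncc] = np.array(nuc, dtype=float) + rng.normal(0, 2, 3)


def _apply_stain_jitter(img: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    jb, jc = params.stain_jitter
    b = rng.uniform(1 - jb, 1 + jb)
    c = rng.uniform(1 - jc, 1 + jc)
    out = ((img.astype(np.float32) - 128.0) * np.float32(c) + 128.0) * np.float32(b)
    out += 1.5 * rng.standard_normal((img.shape[0], img.shape[1], 1), dtype=np.float32)
    return np.clip(out, 0, 255)


def _render_body_texture(size: int, rng: np.random.Generator) -> np.ndarray:
    """Thick-smear texture: coarse high-contrast dark/pale blotches.

    The blotch scale (400 px, i.e. several thumbnail pixels at the default
    100× downscale) is what makes the body band the highest-texture-energy
    region of the thumbnail, above the junction's cell-level mottling.
    """
    block = 400
    n = size // block + 1
    palette = np.array([[78.0, 62.0, 96.0], [150.0, 128.0, 158.0], [232.0, 224.0, 230.0]])
    choice = rng.choice(3, size=(n, n), p=[0.45, 0.2, 0.35])
    coarse = palette[choice].astype(np.float32)
    img = np.repeat(np.repeat(coarse, block, axis=0), block, axis=1)[:size, :size]
    img = img + 4.0 * rng.standard_normal((size, size, 1), dtype=np.float32)
    return img


def _sample_tile_cells(
    params: SceneParams, rng: np.random.Generator, n_cells: int
) -> tuple[tuple[CellSpec, ...], int]:
    """Rejection-sample non-overlapping elliptical cells for one tile."""
    size = params.tile_size
    names = list(DEFAULT_TAXONOMY.names)
    probs = np.array([params.class_proportions[n] for n in names])
    placed: list[tuple[float, float, float]] = []  # (cx, cy, bounding radius)
    cells: list[CellSpec] = []
    shortfall = 0
    for _ in range(n_cells):
        label = names[int(rng.choice(len(names), p=probs))]
        lo, hi = params.cell_radius_range[label]
        a = rng.uniform(lo, hi)
        b = a * rng.uniform(0.75, 1.0)
        angle = rng.uniform(0, np.pi)
        r_bound = max(a, b)
        ok = False
        for _attempt in range(200):
            margin = r_bound + 3
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            if all(
                (cx - px) ** 2 + (cy - py) ** 2 > (r_bound + pr + params.min_cell_gap) ** 2
                for px, py, pr in placed
            ):
                ok = True
                break
        if not ok:
            shortfall += 1
            continue
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ex = a * np.cos(theta)
        ey = b * np.sin(theta)
        rot_x = cx + ex * np.cos(angle) - ey * np.sin(angle)
        rot_y = cy + ex * np.sin(angle) + ey * np.cos(angle)
        poly = np.column_stack([rot_x, rot_y])
        placed.append((cx, cy, r_bound))
        cells.append(CellSpec(poly, label, (cx, cy), (a, b), angle))
    return tuple(cells), shortfall


def _render_tile_pixels(
    params: SceneParams, spec: TileSpec, rng: np.random.Generator
) -> np.ndarray:
    size = params.tile_size
    kind = spec.kind
    if kind == "body":
        img = _render_body_texture(size, rng)
    elif kind == "tail":
        img = _render_background(size, rng)
        _paint_clutter(img, max(3, size // 90), rng)
    elif kind == "blank":
        img = _render_background(size, rng)
    else:  # toi or overstained
        img = _render_background(size, rng)
        _paint_clutter(img, max(8, size // 26), rng)
        for cell in spec.cells:
            _paint_cell(img, cell, rng)
        if kind == "overstained":
            img = img * np.array([0.42, 0.34, 0.50]) + np.array([30.0, 20.0, 38.0])
    img = _apply_stain_jitter(img, params, rng)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_tile(
    params: SceneParams, tile_kind: TileKind, seed: int, n_cells: int | None = None
) -> tuple[np.ndarray, list[tuple[np.ndarray, str]]]:
    """Render one standalone tile of the given kind.

    Returns the image and, for cell-bearing kinds, the exact rendered cell
    masks with their class labels.
    """
    params.validate()
    rng = _tile_rng(seed, 0, 0, 3)
    cells: tuple[CellSpec, ...] = ()
    if tile_kind in ("toi", "overstained"):
        n = n_cells if n_cells is not None else int(rng.poisson(params.cells_per_good_tile))
        cells, _ = _sample_tile_cells(params, rng, n)
    spec = TileSpec(0, 0, "junction", tile_kind, cells)
    img = _render_tile_pixels(params, spec, _tile_rng(seed, 0, 0, 2))
    masks = [(c.mask(params.tile_size), c.label) for c in cells]
    return img, masks


# ---------------------------------------------------------------------------
# case generation


def _band_of(params: SceneParams, tile: TileRef) -> str:
    body_f, junc_f, _ = params.band_fractions
    center_frac = (tile.footprint.y0 + tile.footprint.y1) / 2.0 / params.wsi_height
    if center_frac < body_f:
        return "body"
    if center_frac < body_f + junc_f:
        return "junction"
    return "tail"


def generate_case(params: SceneParams, seed: int) -> SyntheticCase:
    """Generate one deterministic smear case with full ground truth."""
    params.validate()
    refs = grid_tiles(params.wsi_height, params.wsi_width, params.tile_size)
    layout_rng = _tile_rng(seed, 97)
    tile_specs: dict[tuple[int, int], TileSpec] = {}
    for t in refs:
        band = _band_of(params, t)
        if band == "junction":
            if layout_rng.random() < params.bad_tile_fraction:
                kind = "blank" if layout_rng.random() < 0.5 else "overstained"
            else:
                kind = "toi"
        else:
            kind = band
        cells: tuple[CellSpec, ...] = ()
        shortfall = 0
        if kind == "toi":
            cell_rng = _tile_rng(seed, t.row_index, t.col_index, 1)
            n = int(cell_rng.poisson(params.cells_per_good_tile))
            cells, shortfall = _sample_tile_cells(params, cell_rng, n)
        tile_specs[(t.row_index, t.col_index)] = TileSpec(
            t.row_index, t.col_index, band, kind, cells, shortfall
        )

    # ground-truth DCC straight from the drawn labels
    labels = [c.label for spec in tile_specs.values() for c in spec.cells]
    try:
        dcc_gt: DCCResult | None = aggregate_dcc(labels)
    except NoCountableCellsError:
        dcc_gt = None

    # thumbnail: true block-mean downscale of the rendered tiles
    th, tw = params.thumb_shape
    f = params.thumb_factor
    tpx = params.tile_size // f
    thumbnail = np.zeros((th, tw, 3), dtype=float)
    thumbnail[:] = _BACKGROUND
    for t in refs:
        spec = tile_specs[(t.row_index, t.col_index)]
        img = _render_tile_pixels(params, spec, _tile_rng(seed, t.row_index, t.col_index, 2))
        n_blocks = params.tile_size // f
        block = img.astype(float).reshape(n_blocks, f, n_blocks, f, 3).mean(axis=(1, 3))
        r0 = t.row_index * tpx
        c0 = t.col_index * tpx
        thumbnail[r0 : r0 + n_blocks, c0 : c0 + n_blocks] = block
    thumbnail = np.clip(np.round(thumbnail), 0, 255).astype(np.uint8)

    # ROI ground truth: the junction band at thumbnail scale
    body_f, junc_f, _ = params.band_fractions
    roi = np.zeros((th, tw), dtype=np.uint8)
    r_lo = int(round(body_f * th))
    r_hi = int(round((body_f + junc_f) * th))
    roi[r_lo:r_hi, :] = 1

    return SyntheticCase(params, seed, tile_specs, thumbnail, roi, dcc_gt)


# ---------------------------------------------------------------------------
# on-disk layout: PNG tiles + Labelme-style polygon JSON + CSV label tables


def _labelme_dict(spec: TileSpec, tile_size: int) -> dict:
    return {
        "shapes": [
            {
                "label": c.label,
                "points": [[float(x), float(y)] for x, y in c.polygon],
                "shape_type": "polygon",
            }
            for c in spec.cells
        ],
        "imageHeight": tile_size,
        "imageWidth": tile_size,
    }


def write_case(case: SyntheticCase, directory) -> Path:
    """Serialise a case: PNG pixels, polygon JSON annotations, CSV labels."""
    import pandas as pd

    d = Path(directory)
    (d / "tiles").mkdir(parents=True, exist_ok=True)
    (d / "annotations").mkdir(exist_ok=True)
    p = case.params
    meta = {
        "seed": case.seed,
        "params": {
            "wsi_height": p.wsi_height,
            "wsi_width": p.wsi_width,
            "thumb_factor": p.thumb_factor,
            "tile_size": p.tile_size,
            "band_fractions": list(p.band_fractions),
            "cells_per_good_tile": p.cells_per_good_tile,
            "class_proportions": p.class_proportions,
            "cell_radius_range": {k: list(v) for k, v in p.cell_radius_range.items()},
            "stain_jitter": list(p.stain_jitter),
            "bad_tile_fraction": p.bad_tile_fraction,
            "min_cell_gap": p.min_cell_gap,
        },
    }
    (d / "case.json").write_text(json.dumps(meta, indent=1))
    write_image(d / "thumbnail.png", case.thumbnail)
    write_mask(d / "roi_mask_gt.png", case.roi_mask_gt)

    tile_rows = []
    cell_rows = []
    for (r, c), spec in sorted(case.tile_specs.items()):
        tid = f"r{r:03d}_c{c:03d}"
        write_image(d / "tiles" / f"{tid}.png", case.tile_image(r, c))
        tile_rows.append(
            {
                "tile_id": tid,
                "row": r,
                "col": c,
                "band": spec.band,
                "kind": spec.kind,
                "label": "TOI" if spec.is_toi else "non-TOI",
                "shortfall": spec.shortfall,
            }
        )
        if spec.cells:
            (d / "annotations" / f"{tid}.json").write_text(
                json.dumps(_labelme_dict(spec, p.tile_size))
            )
        for i, cell in enumerate(spec.cells):
            cell_rows.append({"tile_id": tid, "cell_index": i, "label": cell.label})
    pd.DataFrame(tile_rows).to_csv(d / "tile_labels.csv", index=False)
    pd.DataFrame(cell_rows, columns=["tile_id", "cell_index", "label"]).to_csv(
        d / "cell_labels.csv", index=False
    )
    if case.dcc_gt is not None:
        (d / "dcc_gt.json").write_text(json.dumps(case.dcc_gt.to_dict(), indent=1))
    return d


def read_case(directory) -> SyntheticCase:
    """Load a case written by :func:`write_case` (pixels read lazily)."""
    import pandas as pd

    from .imaging import read_image, read_mask

    d = Path(directory)
    for required in ("case.json", "thumbnail.png", "roi_mask_gt.png", "tile_labels.csv"):
        if not (d / required).exists():
            raise FileNotFoundError(f"case directory {d} is missing {required}")
    meta = json.loads((d / "case.json").read_text())
    pm = meta["params"]
    params = SceneParams(
        wsi_height=pm["wsi_height"],
        wsi_width=pm["wsi_width"],
        thumb_factor=pm["thumb_factor"],
        tile_size=pm["tile_size"],
        band_fractions=tuple(pm["band_fractions"]),
        cells_per_good_tile=pm["cells_per_good_tile"],
        class_proportions=pm["class_proportions"],
        cell_radius_range={k: tuple(v) for k, v in pm["cell_radius_range"].items()},
        stain_jitter=tuple(pm["stain_jitter"]),
        bad_tile_fraction=pm["bad_tile_fraction"],
        min_cell_gap=pm["min_cell_gap"],
    )
    tiles_df = pd.read_csv(d / "tile_labels.csv")
    tile_specs: dict[tuple[int, int], TileSpec] = {}
    paths: dict[tuple[int, int], Path] = {}
    for rec in tiles_df.to_dict("records"):
        r, c = int(rec["row"]), int(rec["col"])
        tid = rec["tile_id"]
        cells: list[CellSpec] = []
        ann = d / "annotations" / f"{tid}.json"
        if ann.exists():
            for shape in json.loads(ann.read_text())["shapes"]:
                poly = np.asarray(shape["points"], dtype=float)
                cells.append(CellSpec(poly, shape["label"]))
        tile_specs[(r, c)] = TileSpec(
            r, c, rec["band"], rec["kind"], tuple(cells), int(rec.get("shortfall", 0))
        )
        paths[(r, c)] = d / "tiles" / f"{tid}.png"
    labels = [cell.label for spec in tile_specs.values() for cell in spec.cells]
    try:
        dcc_gt: DCCResult | None = aggregate_dcc(labels)
    except NoCountableCellsError:
        dcc_gt = None
    return SyntheticCase(
        params=params,
        seed=int(meta["seed"]),
        tile_specs=tile_specs,
        thumbnail=read_image(d / "thumbnail.png"),
        roi_mask_gt=read_mask(d / "roi_mask_gt.png"),
        dcc_gt=dcc_gt,
        tile_image_paths=paths,
    )
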