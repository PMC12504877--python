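"""Grid tiling of whole-slide images and ROI-based tile retention.

The slide is sliced into non-overlapping ``tile_size`` squares anchored at
the origin (trailing partial tiles are dropped so downstream shapes stay
uniform). Retention decisions are made at thumbnail scale: each tile
footprint is projected onto the thumbnail raster by the downscale factor
and its area-weighted ROI coverage is compared against a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imaging import BBox


@dataclass(frozen=True)
class TileRef:
    """A tile's grid index and full-resolution pixel footprint."""

    row_index: int
    col_index: int
    footprint: BBox
    tile_size: int

    @property
    def tile_id(self) -> str:
        return f"r{self.row_index:03d}_c{self.col_index:03d}"


def grid_tiles(wsi_height: int, wsi_width: int, tile_size: int) -> list[TileRef]:
    """Row-major non-overlapping grid anchored at (0, 0); partials dropped."""
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    n_rows = wsi_height // tile_size
    n_cols = wsi_width // tile_size
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            fp = BBox(c * tile_size, r * tile_size, (c + 1) * tile_size, (r + 1) * tile_size)
            tiles.append(TileRef(r, c, fp, tile_size))
    return tiles


def _axis_overlap_weights(lo: float, hi: float, n: int) -> tuple[int, np.ndarray]:
    """Overlap length of [lo, hi) with each unit pixel cell it touches.

    Returns the index of the first touched pixel and the per-pixel overlap
    lengths, clipped to the raster ``[0, n)``.
    """
    lo = max(lo, 0.0)
    hi = min(hi, float(n))
    if hi <= lo:
        return 0, np.zeros(0)
    first = int(np.floor(lo))
    last = int(np.ceil(hi))  # exclusive
    edges = np.arange(first, last + 1, dtype=float)
    w = np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)
    return first, w


def roi_coverage(tile: TileRef, roi_mask: np.ndarray, thumb_factor: float) -> float:
    """Fraction of the tile footprint covered by ROI foreground.

    Computed on the thumbnail raster: the footprint is divided by
    ``thumb_factor`` and partial thumbnail pixels are area-weighted.
    """
    roi_mask = np.asarray(roi_mask)
    h, w = roi_mask.shape
    fp = tile.footprint
    y0, y1 = fp.y0 / thumb_factor, fp.y1 / thumb_factor
    x0, x1 = fp.x0 / thumb_factor, fp.x1 / thumb_factor
    r0, wy = _axis_overlap_weights(y0, y1, h)
    c0, wx = _axis_overlap_weights(x0, x1, w)
    if wy.size == 0 or wx.size == 0:
        return 0.0
    block = roi_mask[r0 : r0 + wy.size, c0 : c0 + wx.size].astype(float)
    covered = float(wy @ block @ wx)
    total = (y1 - y0) * (x1 - x0)
    return covered / total if total > 0 else 0.0


def retain_tiles(
    tiles: Sequence[TileRef],
    roi_mask: np.ndarray,
    thumb_factor: float,
    tau: float = 0.5,
) -> list[TileRef]:
    """Tiles whose ROI coverage is at least ``tau``, in row-major order."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    return [t for t in tiles if roi_coverage(t, roi_mask, thumb_factor) >= tau]


def tile_manifest(
    tiles: Sequence[TileRef],
    roi_mask: np.ndarray,
    thumb_factor: float,
    tau: float = 0.5,
):
    """Per-tile coverage/retention table as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for t in tiles:
        cov = roi_coverage(t, roi_mask, thumb_factor)
        rows.append(
            {
                "tile_id": t.tile_id,
                "row": t.row_index,
                "col": t.col_index,
                "x0": t.footprint.x0,
                "y0": t.footprint.y0,
                "coverage": cov,
                "retained": cov >= tau,
            }
        )
    return pd.DataFrame(rows)
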