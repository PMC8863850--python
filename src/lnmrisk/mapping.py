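"""Whole-slide tile-probability color maps.

Each grid cell of a tiled slide is painted from the tile's prediction:
metastasis-predicted cancer tiles (``p_met > 0.5``) on a red ramp whose
brightness grows with ``p_met``; negative-predicted cancer tiles on a green
ramp scaled by the non-metastatic probability; non-tumor tiles flat gray;
tiles rejected by the tissue threshold in the background color.  A
probability of 0.5 maps to the darkest *visible* shade of its ramp (not
black) so the red/green direction stays readable at low confidence.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
from PIL import Image

from .tiling import DEFAULT_TILE_MICRONS, TileManifest

DEFAULT_CELL_SIZE = 8
GRAY_NONTUMOR = (128, 128, 128)
BACKGROUND = (235, 235, 235)
#: minimum ramp brightness (at probability 0.5), out of 255
RAMP_FLOOR = 64


def ramp_brightness(p: float) -> int:
    """Linear brightness for a ramp probability in [0.5, 1]."""
    frac = (min(max(p, 0.5), 1.0) - 0.5) / 0.5
    return int(round(RAMP_FLOOR + (255 - RAMP_FLOOR) * frac))


def tile_color(p_met: float | None, is_cancer: bool = True) -> tuple[int, int, int]:
    """RGB for one kept tile; ``p_met=None`` or non-cancer → gray."""
    if not is_cancer or p_met is None:
        return GRAY_NONTUMOR
    if p_met > 0.5:
        return (ramp_brightness(p_met), 0, 0)
    return (0, ramp_brightness(1.0 - p_met), 0)


def render_map(
    manifest: TileManifest,
    records: pd.DataFrame,
    cell_size: int = DEFAULT_CELL_SIZE,
) -> np.ndarray:
    """Paint the slide grid into an RGB raster (uint8).

    ``records`` carries ``row``, ``col``, ``p_met`` and optionally
    ``is_cancer`` (default True) for a subset of the manifest's kept tiles;
    kept tiles without a record are drawn gray (non-tumor), rejected tiles
    in the background color.  A record addressing a grid cell outside the
    manifest is an error.  Output is deterministic.
    """
    n_rows, n_cols = manifest.n_rows, manifest.n_cols
    grid = np.empty((n_rows, n_cols, 3), dtype=np.uint8)
    kept = {(t.row, t.col): t.kept for t in manifest.tiles}
    for (r, c), k in kept.items():
        grid[r, c] = GRAY_NONTUMOR if k else BACKGROUND

    has_cancer_col = "is_cancer" in records.columns
    for rec in records.itertuples(index=False):
        key = (int(rec.row), int(rec.col))
        if key not in kept:
            raise ValueError(f"record addresses tile {key} absent from manifest")
        is_cancer = bool(getattr(rec, "is_cancer")) if has_cancer_col else True
        grid[key] = tile_color(float(rec.p_met), is_cancer)

    return np.repeat(np.repeat(grid, cell_size, axis=0), cell_size, axis=1)


def save_map(
    manifest: TileManifest,
    records: pd.DataFrame,
    path: str | os.PathLike,
    cell_size: int = DEFAULT_CELL_SIZE,
) -> None:
    """Render and write the PNG plus a legend JSON sidecar."""
    img = render_map(manifest, records, cell_size=cell_size)
    Image.fromarray(img).save(path)
    legend = {
        "red": "metastasis-predicted cancer tile; brightness ~ p_met",
        "green": "negative-predicted cancer tile; brightness ~ 1 - p_met",
        "gray": "non-tumor tissue tile",
        "background": "no tissue (rejected by pixel threshold)",
        "cell_size_px": cell_size,
        "tile_pitch_um": DEFAULT_TILE_MICRONS * manifest.tile_size / 299,
        "ramp_floor": RAMP_FLOOR,
    }
    with open(f"{os.fspath(path)}.legend.json", "w") as fh:
        json.dump(legend, fh, indent=2)
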