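"""Whole-slide tessellation into fixed-size tiles and background filtering.

A slide (or any raster image) is cut into a dense grid of non-overlapping
square tiles, 299 px (273 µm) by default.  Partial edge strips that cannot
hold a complete tile are dropped rather than padded, so no fabricated pixels
enter the analysis.  Tiles with no tissue are removed by a gray-scale pixel
threshold: a tile is kept iff the minimum gray value of its 8-bit luminance
conversion is at or below the threshold (default 110), i.e. it contains at
least one sufficiently dark pixel — a proxy for at least one nucleated cell.
The boundary is inclusive: a tile whose darkest pixel is exactly 110 is kept.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

DEFAULT_TILE_SIZE = 299
DEFAULT_GRAY_THRESHOLD = 110
#: physical tile pitch in microns at the default scan resolution
DEFAULT_TILE_MICRONS = 273.0

# ITU-R BT.601 luma weights; fixed here so min-gray values are bit-stable
# across pillow versions.
_LUMA = np.array([0.299, 0.587, 0.114])


class EmptyManifestError(ValueError):
    """Image is smaller than a single tile in at least one dimension."""


@dataclass(frozen=True)
class Tile:
    """One grid-addressed square patch of a slide.

    ``x0, y0`` are top-left pixel offsets; the pixel span is half-open,
    ``[x0, x0+size_px) x [y0, y0+size_px)``.  ``min_gray`` is the darkest
    8-bit luminance value inside the patch; ``kept`` records whether the
    patch passed the tissue threshold.
    """

    slide_id: str
    row: int
    col: int
    x0: int
    y0: int
    size_px: int = DEFAULT_TILE_SIZE
    min_gray: int | None = None
    kept: bool | None = None

    @property
    def size_um(self) -> float:
        return self.size_px * DEFAULT_TILE_MICRONS / DEFAULT_TILE_SIZE


@dataclass
class TileManifest:
    """Full tiling of one slide: every complete grid cell, kept or not."""

    slide_id: str
    width: int
    height: int
    tile_size: int
    threshold: int
    tiles: list[Tile] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.height // self.tile_size

    @property
    def n_cols(self) -> int:
        return self.width // self.tile_size

    def kept_tiles(self) -> list[Tile]:
        return [t for t in self.tiles if t.kept]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": [t.slide_id for t in self.tiles],
                "row": [t.row for t in self.tiles],
                "col": [t.col for t in self.tiles],
                "x0": [t.x0 for t in self.tiles],
                "y0": [t.y0 for t in self.tiles],
                "min_gray": [t.min_gray for t in self.tiles],
                "kept": [t.kept for t in self.tiles],
            }
        )

    def write_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a raster array to 8-bit luminance (0–255).

    Accepts 2-D gray arrays (uint8 or float in [0,1] or [0,255]) and 3-D
    RGB(A) arrays; alpha is ignored.  Luminance uses BT.601 weights and
    rounds half-up to the nearest integer.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            raise ValueError(f"expected RGB(A) image, got shape {arr.shape}")
        arr = arr[..., :3].astype(float) @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"cannot interpret array of shape {arr.shape} as an image")
    arr = arr.astype(float)
    if arr.size and arr.max() <= 1.0 and np.issubdtype(np.asarray(image).dtype, np.floating):
        arr = arr * 255.0
    return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)


def passes_pixel_threshold(
    tile_image: np.ndarray, threshold: int = DEFAULT_GRAY_THRESHOLD
) -> bool:
    """True iff the tile contains at least one pixel with gray <= threshold."""
    gray = to_grayscale(tile_image)
    return bool(gray.min() <= threshold)


def tessellate(
    image: np.ndarray,
    slide_id: str = "slide",
    tile_size: int = DEFAULT_TILE_SIZE,
    threshold: int = DEFAULT_GRAY_THRESHOLD,
) -> TileManifest:
    """Cut an image into non-overlapping ``tile_size`` squares.

    Produces ``floor(W/s) * floor(H/s)`` tiles in row-major order; edge
    remainders are dropped.  Each tile is annotated with its minimum gray
    value and the kept/rejected flag from the pixel threshold.

    Raises
    ------
    EmptyManifestError
        If the image cannot hold even a single complete tile.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    gray = to_grayscale(image)
    height, width = gray.shape
    n_rows, n_cols = height // tile_size, width // tile_size
    if n_rows == 0 or n_cols == 0:
        raise EmptyManifestError(
            f"image {width}x{height} smaller than one {tile_size}-px tile"
        )
    tiles: list[Tile] = []
    for row in range(n_rows):
        for col in range(n_cols):
            y0, x0 = row * tile_size, col * tile_size
            patch = gray[y0 : y0 + tile_size, x0 : x0 + tile_size]
            mg = int(patch.min())
            tiles.append(
                Tile(
                    slide_id=slide_id,
                    row=row,
                    col=col,
                    x0=x0,
                    y0=y0,
                    size_px=tile_size,
                    min_gray=mg,
                    kept=mg <= threshold,
                )
            )
    return TileManifest(
        slide_id=slide_id,
        width=width,
        height=height,
        tile_size=tile_size,
        threshold=threshold,
        tiles=tiles,
    )


def extract_tile_image(image: np.ndarray, tile: Tile) -> np.ndarray:
    """Slice the pixel block addressed by ``tile`` out of the source raster."""
    return np.asarray(image)[
        tile.y0 : tile.y0 + tile.size_px, tile.x0 : tile.x0 + tile.size_px
    ]


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF raster into a numpy array (level 0 only)."""
    with Image.open(path) as im:
        return np.asarray(im)


def save_tiles(
    image: np.ndarray,
    manifest: TileManifest,
    out_dir: str | os.PathLike,
    kept_only: bool = True,
) -> list[str]:
    """Write tile PNGs named ``<slide>_r<row>_c<col>.png``; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for t in manifest.tiles:
        if kept_only and not t.kept:
            continue
        patch = extract_tile_image(image, t)
        p = os.path.join(out_dir, f"{t.slide_id}_r{t.row}_c{t.col}.png")
        Image.fromarray(patch).save(p)
        paths.append(p)
    return paths
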