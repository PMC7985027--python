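"""Deterministic tile geometry, whitespace filtering, and crop augmentation.

Whole-slide images are processed as square tiles on a regular grid.  Training
uses a non-overlapping grid and drops ragged edges; inference uses an
overlapping grid with extra edge-flush origins so that every pixel is covered.
Coordinates are 0-based with half-open boxes ``[row, row+tile) x [col,
col+tile)`` in row-major order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

#: Grayscale intensity above which a pixel counts as whitespace (0-255 scale).
DEFAULT_WHITE_THRESHOLD = 230

#: Maximum tolerated whitespace fraction for a training tile.
DEFAULT_MAX_WHITE = 0.08

STAINS = ("HE", "trichrome", "virtual_trichrome")


@dataclass
class SlideImage:
    """An RGB 8-bit slide raster with an identifier and stain label."""

    pixels: np.ndarray
    slide_id: str
    stain: str = "HE"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"slide pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("slide must have height >= 1 and width >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.stain not in STAINS:
            raise ValueError(f"unknown stain {self.stain!r}; expected one of {STAINS}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class TileGrid:
    """Tile origins over a slide; every box fits inside ``slide_dims``."""

    tile_size: int
    stride: int
    origins: list[tuple[int, int]]
    slide_dims: tuple[int, int]

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        h, w = self.slide_dims
        for r, c in self.origins:
            if not (0 <= r and r + self.tile_size <= h and 0 <= c and c + self.tile_size <= w):
                raise ValueError(f"tile at ({r}, {c}) exceeds slide dims {self.slide_dims}")
        if sorted(set(self.origins)) != list(self.origins):
            raise ValueError("origins must be unique and sorted row-major")

    def __len__(self) -> int:
        return len(self.origins)


def _axis_origins(dim: int, tile_size: int, stride: int, edge_flush: bool) -> list[int]:
    starts = list(range(0, dim - tile_size + 1, stride))
    if edge_flush and starts[-1] != dim - tile_size:
        starts.append(dim - tile_size)
    return starts


def grid_origins(
    height: int,
    width: int,
    tile_size: int,
    stride: int,
    edge_flush: bool = True,
) -> TileGrid:
    """Build the tile grid for a ``height x width`` slide.

    Per axis the origins are ``0, stride, 2*stride, ...`` capped so boxes fit;
    with ``edge_flush`` (the inference default) an extra origin flush with the
    image edge is appended when the last regular box does not reach it, so the
    grid covers every pixel.  Training grids use ``edge_flush=False`` and
    simply drop the ragged edge.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if tile_size > min(height, width):
        raise ValueError(
            f"tile_size {tile_size} exceeds slide dims ({height}, {width})"
        )
    rows = _axis_origins(height, tile_size, stride, edge_flush)
    cols = _axis_origins(width, tile_size, stride, edge_flush)
    origins = [(r, c) for r in rows for c in cols]
    return TileGrid(tile_size=tile_size, stride=stride, origins=origins,
                    slide_dims=(height, width))


def white_fraction(tile: np.ndarray, brightness_threshold: int = DEFAULT_WHITE_THRESHOLD) -> float:
    """Fraction of pixels whose grayscale intensity exceeds the threshold.

    Grayscale is the rounded mean of the R, G, B channels.
    """
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValueError("tile is empty")
    gray = np.rint(tile.astype(np.float64).mean(axis=-1))
    return float(np.mean(gray > brightness_threshold))


def extract_training_tiles(
    slide: SlideImage,
    tile_size: int,
    max_white: float = DEFAULT_MAX_WHITE,
    brightness_threshold: int = DEFAULT_WHITE_THRESHOLD,
) -> tuple[list[np.ndarray], list[tuple[int, int]]]:
    """Non-overlapping tiles that pass the whitespace filter, row-major.

    Tiles with ``white_fraction > max_white`` are discarded.  A slide smaller
    than the tile yields an empty list with a warning rather than an error.
    """
    if not 0.0 <= max_white <= 1.0:
        raise ValueError("max_white must lie in [0, 1]")
    h, w = slide.shape
    if tile_size > min(h, w):
        logger.warning(
            "slide %s (%dx%d) smaller than tile_size %d; no training tiles",
            slide.slide_id, h, w, tile_size,
        )
        return [], []
    grid = grid_origins(h, w, tile_size, stride=tile_size, edge_flush=False)
    tiles: list[np.ndarray] = []
    kept_origins: list[tuple[int, int]] = []
    for r, c in grid.origins:
        tile = slide.pixels[r:r + tile_size, c:c + tile_size]
        if white_fraction(tile, brightness_threshold) <= max_white:
            tiles.append(tile)
            kept_origins.append((r, c))
    return tiles, kept_origins


def random_crop(tile: np.ndarray, crop_size: int, rng: np.random.Generator | int) -> np.ndarray:
    """Uniform random square crop; same seed gives the same crop."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h, w = tile.shape[:2]
    if crop_size > min(h, w):
        raise ValueError(f"crop_size {crop_size} exceeds tile dims ({h}, {w})")
    r = int(rng.integers(0, h - crop_size + 1))
    c = int(rng.integers(0, w - crop_size + 1))
    return tile[r:r + crop_size, c:c + crop_size]


def write_tile_set(
    slide: SlideImage,
    tile_size: int,
    out_dir: str | Path,
    max_white: float = DEFAULT_MAX_WHITE,
    brightness_threshold: int = DEFAULT_WHITE_THRESHOLD,
) -> pd.DataFrame:
    """Write surviving tiles as PNGs plus a manifest of every grid position.

    The manifest lists all grid tiles with their whitespace fraction and
    whether they were kept, so the filter is auditable after the fact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h, w = slide.shape
    records = []
    if tile_size <= min(h, w):
        grid = grid_origins(h, w, tile_size, stride=tile_size, edge_flush=False)
        for r, c in grid.origins:
            tile = slide.pixels[r:r + tile_size, c:c + tile_size]
            wf = white_fraction(tile, brightness_threshold)
            kept = wf <= max_white
            if kept:
                Image.fromarray(tile).save(out_dir / f"{slide.slide_id}_{r}_{c}.png")
            records.append({"slide_id": slide.slide_id, "row": r, "col": c,
                            "white_fraction": wf, "kept": kept})
    else:
        logger.warning("slide %s smaller than tile_size %d", slide.slide_id, tile_size)
    manifest = pd.DataFrame(records, columns=["slide_id", "row", "col", "white_fraction", "kept"])
    manifest.to_csv(out_dir / f"{slide.slide_id}_manifest.tsv", sep="\t", index=False)
    return manifest


def load_image(path: str | Path, slide_id: str | None = None, stain: str = "HE") -> SlideImage:
    """Read a PNG/TIFF raster as a SlideImage (level 0 for pyramidal TIFF)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        px = tifffile.imread(path)
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
    else:
        px = np.asarray(Image.open(path).convert("RGB"))
    return SlideImage(pixels=np.ascontiguousarray(px[..., :3], dtype=np.uint8),
                      slide_id=slide_id or path.stem, stain=stain)


def load_tile_dir(tile_dir: str | Path) -> list[np.ndarray]:
    """Load every PNG tile in a directory, sorted by filename."""
    paths = sorted(Path(tile_dir).glob("*.png"))
    return [np.asarray(Image.open(p).convert("RGB"), dtype=np.uint8) for p in paths]
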