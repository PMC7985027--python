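"""Whole-slide virtual staining: overlapped-tile translation and blending.

A slide is covered by an edge-flush tile grid, each tile is translated
independently, and the translated tiles are combined as a weighted average
(per-pixel sum of weight x value divided by the sum of weights).  Because the
normalization divides by the accumulated weights, any partition-of-unity
concerns vanish: an identity translator reproduces the input bit-exactly at
any stride, and per-pixel colour maps commute with the blending up to 8-bit
quantization.  Feathered (raised-cosine) weights down-weight tile borders so
seams from imperfect translators are smoothed.

Accumulation is in float64; quantization to 8-bit happens once at the end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile
from PIL import Image

from .tiling import SlideImage, grid_origins
from .translator import TranslatorState, translate_tile

logger = logging.getLogger(__name__)

TileTranslator = Callable[[np.ndarray], np.ndarray]


@dataclass
class BlendWeightMap:
    """Per-pixel blending weights for one tile; strictly positive inside."""

    weights: np.ndarray
    construction: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if not np.isfinite(w).all() or (w <= 0).any():
            raise ValueError("blend weights must be finite and strictly positive")
        self.weights = w


def uniform_weights(tile_size: int) -> BlendWeightMap:
    return BlendWeightMap(np.ones((tile_size, tile_size)), "uniform")


def feathered_weights(tile_size: int) -> BlendWeightMap:
    """Separable raised-cosine window ``w(r,c) = h(r) h(c)``.

    ``h(i) = 0.5 - 0.5 cos(2 pi (i + 0.5) / tile_size)`` is strictly positive
    and symmetric under ``i <-> tile_size - 1 - i``, peaking at the tile
    centre.
    """
    if tile_size < 2:
        raise ValueError("tile_size must be >= 2")
    i = np.arange(tile_size)
    h = 0.5 - 0.5 * np.cos(2.0 * np.pi * (i + 0.5) / tile_size)
    return BlendWeightMap(np.outer(h, h), "feathered")


def _tile_fn(state_or_fn: TranslatorState | TileTranslator, direction: str) -> TileTranslator:
    if isinstance(state_or_fn, TranslatorState):
        return lambda tile: translate_tile(state_or_fn, tile, direction)
    if callable(state_or_fn):
        return state_or_fn
    raise TypeError("expected a TranslatorState or a tile -> tile callable")


def translate_wsi(
    translator: TranslatorState | TileTranslator,
    slide: SlideImage,
    tile_size: int,
    stride: int,
    weights: str = "feathered",
    direction: str = "a2b",
) -> SlideImage:
    """Translate a whole slide by overlapped tiling and weighted blending.

    ``translator`` is either a trained :class:`TranslatorState` or any
    uint8-tile -> uint8-tile callable.  ``stride`` must not exceed
    ``tile_size``; a slide smaller than one tile is reflection-padded,
    translated as a single tile, and cropped back.
    """
    if stride > tile_size:
        raise ValueError("stride > tile_size leaves uncovered pixels")
    fn = _tile_fn(translator, direction)
    h, w = slide.shape

    if min(h, w) < tile_size:
        pad_h, pad_w = max(0, tile_size - h), max(0, tile_size - w)
        padded = np.pad(slide.pixels, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
        out = fn(padded)[:h, :w]
        return SlideImage(out.astype(np.uint8), slide.slide_id, "virtual_trichrome")

    wmap = feathered_weights(tile_size) if weights == "feathered" else uniform_weights(tile_size)
    grid = grid_origins(h, w, tile_size, stride, edge_flush=True)
    acc = np.zeros((h, w, 3), dtype=np.float64)
    wsum = np.zeros((h, w), dtype=np.float64)
    wt = wmap.weights
    for r, c in grid.origins:
        tile = slide.pixels[r:r + tile_size, c:c + tile_size]
        translated = fn(tile).astype(np.float64)
        acc[r:r + tile_size, c:c + tile_size] += wt[..., None] * translated
        wsum[r:r + tile_size, c:c + tile_size] += wt
    out = np.clip(np.rint(acc / wsum[..., None]), 0, 255).astype(np.uint8)
    return SlideImage(out, slide.slide_id, "virtual_trichrome")


def seam_discontinuity(slide: SlideImage, columns: Sequence[int]) -> float:
    """Maximum per-pixel absolute jump across the given seam columns."""
    px = slide.pixels.astype(np.float64)
    jumps = [np.abs(px[:, c] - px[:, c - 1]).max() for c in columns if 0 < c < px.shape[1]]
    return float(max(jumps)) if jumps else 0.0


def render_checkpoint_gallery(
    checkpoints: Sequence[TranslatorState],
    slides: Sequence[SlideImage],
    tile_size: int,
    stride: int,
    out_dir: str | Path,
    direction: str = "a2b",
) -> list[Path]:
    """Render every (checkpoint, slide) pair plus a real|virtual montage.

    Filenames encode the training iteration so a reviewer can scan model
    quality over the training trajectory, mirroring periodic whole-slide
    review for model selection.
    """
    if not checkpoints or not slides:
        raise ValueError("need at least one checkpoint and one slide")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for state in checkpoints:
        for slide in slides:
            try:
                virt = translate_wsi(state, slide, tile_size, stride, direction=direction)
                vpath = out_dir / f"virtual_iter{state.iteration:06d}_{slide.slide_id}.png"
                Image.fromarray(virt.pixels).save(vpath)
                montage = np.concatenate([slide.pixels, virt.pixels], axis=1)
                mpath = out_dir / f"montage_iter{state.iteration:06d}_{slide.slide_id}.png"
                Image.fromarray(montage).save(mpath)
                written.extend([vpath, mpath])
            except OSError as exc:  # pragma: no cover - I/O environment dependent
                logger.error("failed to write render for iter %d slide %s: %s",
                             state.iteration, slide.slide_id, exc)
    return written


def _halve(level: np.ndarray) -> np.ndarray:
    """2x2 block mean with rounding; odd dims replicate the last row/col."""
    h, w = level.shape[:2]
    if h % 2:
        level = np.concatenate([level, level[-1:]], axis=0)
    if w % 2:
        level = np.concatenate([level, level[:, -1:]], axis=1)
    blocks = level.reshape(level.shape[0] // 2, 2, level.shape[1] // 2, 2, 3)
    return np.clip(np.rint(blocks.astype(np.float64).mean(axis=(1, 3))), 0, 255).astype(np.uint8)


def pyramid_levels(pixels: np.ndarray, min_dim: int = 512) -> list[np.ndarray]:
    """Power-of-two downsampled levels until the max dimension is <= min_dim."""
    levels = [pixels]
    while max(levels[-1].shape[:2]) > min_dim:
        levels.append(_halve(levels[-1]))
    return levels


def export_viewer(slide: SlideImage, path: str | Path, min_dim: int = 512,
                  tile: int = 256) -> list[tuple[int, int]]:
    """Write a tiled, multi-resolution TIFF readable by standard WSI viewers.

    Level 0 round-trips bit-exactly; lower levels are 2x2 block means.
    Returns the (height, width) of each written level.
    """
    path = Path(path)
    levels = pyramid_levels(slide.pixels, min_dim=min_dim)
    tile_kw = (tile, tile) if max(slide.pixels.shape[:2]) >= tile else None
    with tifffile.TiffWriter(path, bigtiff=False) as tw:
        tw.write(levels[0], subifds=len(levels) - 1, tile=tile_kw,
                 photometric="rgb", compression=None)
        for lvl in levels[1:]:
            tw.write(lvl, subfiletype=1, tile=tile_kw, photometric="rgb",
                     compression=None)
    return [lvl.shape[:2] for lvl in levels]


def read_viewer_level(path: str | Path, level: int = 0) -> np.ndarray:
    with tifffile.TiffFile(Path(path)) as tf:
        series = tf.series[0]
        return series.levels[level].asarray()
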