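"""Slide tiling: fixed-size grid crops with background filtering.

Slides are partitioned into non-overlapping ``tile_size`` x ``tile_size``
crops on a grid anchored at the top-left pixel; partial tiles at the right
and bottom edges are dropped so every tile has the fixed network input
shape. A pixel counts as background iff all three channels are at or above
the whiteness threshold, and tiles with more than ``max_background``
background are discarded. Each retained tile keeps its 0-based (row, col)
grid position, which also round-trips through the tile filename.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .synthetic import SlideRecord

__all__ = [
    "Tile",
    "tile_slide",
    "tile_filename",
    "parse_tile_filename",
    "background_mask",
    "read_cohort",
    "write_tiles",
]

DEFAULT_TILE_SIZE = 128
DEFAULT_MAX_BACKGROUND = 0.5
DEFAULT_WHITENESS = 220

_FILENAME_RE = re.compile(r"^(?P<slide_id>.+)__r(?P<row>\d+)_c(?P<col>\d+)\.png$")


@dataclass
class Tile:
    slide_id: str
    row: int
    col: int
    pixels: np.ndarray            # (tile_size, tile_size, 3) uint8
    background_fraction: float


def background_mask(pixels: np.ndarray, whiteness_threshold: int = DEFAULT_WHITENESS) -> np.ndarray:
    """Boolean mask of background pixels: all channels >= threshold."""
    return (pixels >= whiteness_threshold).all(axis=-1)


def tile_slide(record: SlideRecord, tile_size: int = DEFAULT_TILE_SIZE,
               max_background: float = DEFAULT_MAX_BACKGROUND,
               whiteness_threshold: int = DEFAULT_WHITENESS) -> list[Tile]:
    """Cut one slide into retained tiles.

    An image smaller than one tile yields an empty list with a warning
    rather than an exception, so cohort loops survive degenerate slides.
    """
    img = record.image
    h, w = img.shape[:2]
    if h < tile_size or w < tile_size:
        warnings.warn(f"slide {record.slide_id}: image {h}x{w} smaller than one "
                      f"{tile_size}px tile; no tiles produced", stacklevel=2)
        return []
    tiles: list[Tile] = []
    for row in range(h // tile_size):
        for col in range(w // tile_size):
            crop = img[row * tile_size:(row + 1) * tile_size,
                       col * tile_size:(col + 1) * tile_size]
            bg = float(background_mask(crop, whiteness_threshold).mean())
            if bg > max_background:
                continue
            tiles.append(Tile(record.slide_id, row, col, crop, bg))
    return tiles


def tile_filename(tile: Tile) -> str:
    """``{slide_id}__r{row}_c{col}.png``; slide_id must not contain path separators."""
    if "/" in tile.slide_id or "\\" in tile.slide_id:
        raise ValueError(f"slide_id {tile.slide_id!r} contains a path separator")
    return f"{tile.slide_id}__r{tile.row}_c{tile.col}.png"


def parse_tile_filename(name: str) -> tuple[str, int, int]:
    m = _FILENAME_RE.match(name)
    if not m:
        raise ValueError(f"malformed tile filename {name!r}: expected "
                         "'{slide_id}__r{row}_c{col}.png'")
    return m.group("slide_id"), int(m.group("row")), int(m.group("col"))


def write_tiles(tiles: list[Tile], out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in tiles:
        p = out / tile_filename(t)
        Image.fromarray(t.pixels).save(p)
        paths.append(p)
    return paths


def read_cohort(cohort_dir: str | Path, load_truth: bool = False
                ) -> tuple[list[SlideRecord], pd.DataFrame]:
    """Read a cohort written by :func:`hetile.synthetic.write_cohort`."""
    d = Path(cohort_dir)
    table = pd.read_csv(d / "traits.csv")
    trait_cols = [c for c in table.columns
                  if c not in ("slide_id", "patient_id", "timepoint")]
    records = []
    for _, row in table.iterrows():
        img = np.asarray(Image.open(d / f"{row.slide_id}.png").convert("RGB"))
        truth = None
        tpath = d / "truth" / f"{row.slide_id}_truth.tif"
        if load_truth and tpath.exists():
            truth = tifffile.imread(tpath)
        records.append(SlideRecord(
            slide_id=row.slide_id, patient_id=row.patient_id,
            timepoint=int(row.timepoint), image=img,
            traits={c: float(row[c]) for c in trait_cols}, truth_map=truth))
    return records, table
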