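"""Sliding-window slide inference.

Applies the trained tile model over the detected tissue on a regular
stride grid, yielding per-label probability grids (rendered as heatmaps)
and per-tile feature sequences for the recurrent aggregator. The default
stride is 256 px; halving it to 128 doubles heatmap resolution at four
times the cost.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from skimage.transform import downscale_local_mean

from .backbones import normalize_pixels
from .labels import LABELS
from .preprocess import TileRef, TissueMask

log = logging.getLogger(__name__)

DEFAULT_STRIDE = 256
FINE_STRIDE = 128

#: overlay colours per label (RGB)
LABEL_COLORS = {
    "adenocarcinoma": (214, 39, 40),
    "adenoma": (255, 187, 18),
    "non_neoplastic": (44, 160, 44),
}


@dataclass
class TileProbGrid:
    """Per-label probabilities over the sliding-window grid."""

    origin: tuple  # (x, y) of grid cell (0, 0)
    stride: int
    tile_size: int
    probs: np.ndarray  # rows x cols x 3, simplex on tissue cells
    tissue: np.ndarray  # rows x cols bool

    @property
    def shape(self) -> tuple:
        return self.tissue.shape

    def tissue_probs(self) -> np.ndarray:
        """(n_tissue, 3) probabilities in raster order."""
        return self.probs[self.tissue]


@dataclass
class FeatureSequence:
    """Ordered per-tile feature vectors for one slide (raster order)."""

    slide_id: str
    tiles: list  # list[TileRef]
    features: np.ndarray  # (len(tiles), feature_dim)

    def __len__(self) -> int:
        return len(self.tiles)


def enumerate_grid(
    slide_dims: tuple,
    tile_size: int,
    stride: int,
    mask: TissueMask | None = None,
    min_tissue_fraction: float = 0.0,
) -> tuple:
    """Raster-order sliding-window positions fully inside the slide.

    Returns (tiles, tissue_flags, (rows, cols)). Position (i, j) has
    origin (j*stride, i*stride); the number of columns is
    floor((W - tile_size)/stride) + 1 and likewise for rows. A position
    counts as tissue when its tile overlaps the mask (by more than
    ``min_tissue_fraction`` of its area; the default keeps any overlap).
    """
    width, height = slide_dims
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if tile_size > width or tile_size > height:
        raise ValueError(f"tile size {tile_size} exceeds slide dims {slide_dims}")
    if stride > tile_size:
        log.warning("stride %d > tile size %d leaves gaps between tiles", stride, tile_size)
    cols = (width - tile_size) // stride + 1
    rows = (height - tile_size) // stride + 1
    tiles, flags = [], np.zeros((rows, cols), dtype=bool)
    for i in range(rows):
        for j in range(cols):
            x0, y0 = j * stride, i * stride
            tiles.append(TileRef(x0=x0, y0=y0, size=tile_size))
            flags[i, j] = (
                True
                if mask is None
                else _tissue_overlap(mask, x0, y0, tile_size) > min_tissue_fraction
            )
    return tiles, flags, (rows, cols)


def _tissue_overlap(mask: TissueMask, x0: int, y0: int, size: int) -> float:
    ds = mask.downsample
    sub = mask.mask[y0 // ds : -(-(y0 + size) // ds), x0 // ds : -(-(x0 + size) // ds)]
    return float(sub.mean()) if sub.size else 0.0


def _forward_tiles(model, image, tiles, batch_size=32, want_features=False):
    """Run the tile model over a list of positions; deterministic."""
    n = len(tiles)
    probs = np.zeros((n, len(model.class_order)), dtype=np.float32)
    feats = np.zeros((n, model.feature_dim), dtype=np.float32) if want_features else None
    for lo in range(0, n, batch_size):
        chunk = tiles[lo : lo + batch_size]
        batch = np.stack(
            [
                np.asarray(image[t.y0 : t.y0 + t.size, t.x0 : t.x0 + t.size])
                for t in chunk
            ]
        )
        f, p = model.forward(normalize_pixels(batch), train=False)
        probs[lo : lo + len(chunk)] = p
        if want_features:
            feats[lo : lo + len(chunk)] = f
    return feats, probs


def predict_slide(
    model,
    slide,
    grid: tuple | None = None,
    mask: TissueMask | None = None,
    stride: int = DEFAULT_STRIDE,
    batch_size: int = 32,
) -> TileProbGrid:
    """Tile-model probabilities at every tissue position of the grid."""
    tile_size = model.config.input_size
    if grid is None:
        tiles, flags, (rows, cols) = enumerate_grid(
            (slide.width_px, slide.height_px), tile_size, stride, mask
        )
    else:
        tiles, flags, (rows, cols) = grid
        if tiles and tiles[0].size != tile_size:
            raise ValueError(
                f"grid tile size {tiles[0].size} != model input {tile_size}"
            )
        stride = tiles[1].x0 - tiles[0].x0 if len(tiles) > 1 else stride
    image = slide.load_image()
    flat = flags.ravel()
    tissue_tiles = [t for t, f in zip(tiles, flat) if f]
    probs = np.zeros((rows * cols, len(model.class_order)), dtype=np.float32)
    if tissue_tiles:
        _, p = _forward_tiles(model, image, tissue_tiles, batch_size)
        probs[flat] = p
    return TileProbGrid(
        origin=(0, 0),
        stride=stride,
        tile_size=tile_size,
        probs=probs.reshape(rows, cols, -1),
        tissue=flags,
    )


def extract_features(
    model,
    slide,
    grid: tuple | None = None,
    mask: TissueMask | None = None,
    stride: int = DEFAULT_STRIDE,
    batch_size: int = 32,
) -> FeatureSequence:
    """Pre-classification feature vectors at every tissue position."""
    tile_size = model.config.input_size
    if grid is None:
        tiles, flags, _ = enumerate_grid(
            (slide.width_px, slide.height_px), tile_size, stride, mask
        )
    else:
        tiles, flags, _ = grid
    image = slide.load_image()
    tissue_tiles = [t for t, f in zip(tiles, flags.ravel()) if f]
    if tissue_tiles:
        feats, _ = _forward_tiles(model, image, tissue_tiles, batch_size, want_features=True)
    else:
        feats = np.zeros((0, model.feature_dim), dtype=np.float32)
    return FeatureSequence(slide_id=slide.slide_id, tiles=tissue_tiles, features=feats)


def render_heatmap(
    grid: TileProbGrid, label: str, cell_px: int = 8, cmap: str = "inferno"
) -> np.ndarray:
    """Per-label probability map as an RGBA uint8 image (pure view).

    Each grid cell becomes a ``cell_px`` square; non-tissue cells are
    fully transparent. Grid data is never modified.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    idx = LABELS.index(label)
    p = grid.probs[:, :, idx]
    rgba = (colormaps[cmap](p) * 255).astype(np.uint8)
    rgba[..., 3] = np.where(grid.tissue, 255, 0)
    return np.kron(rgba, np.ones((cell_px, cell_px, 1), dtype=np.uint8))


def render_argmax_overlay(
    grid: TileProbGrid, base_image: np.ndarray, alpha: float = 0.45, thumb_downsample: int = 32
) -> np.ndarray:
    """Alpha-blend argmax label colours over a slide thumbnail."""
    thumb = downscale_local_mean(
        np.asarray(base_image, dtype=np.float64), (thumb_downsample, thumb_downsample, 1)
    )
    out = thumb.copy()
    argmax = grid.probs.argmax(axis=2)
    rows, cols = grid.shape
    for i in range(rows):
        for j in range(cols):
            if not grid.tissue[i, j]:
                continue
            color = np.array(LABEL_COLORS[LABELS[argmax[i, j]]], dtype=np.float64)
            x0 = (grid.origin[0] + j * grid.stride) // thumb_downsample
            y0 = (grid.origin[1] + i * grid.stride) // thumb_downsample
            x1 = (grid.origin[0] + j * grid.stride + grid.tile_size) // thumb_downsample
            y1 = (grid.origin[1] + i * grid.stride + grid.tile_size) // thumb_downsample
            patch = out[y0:y1, x0:x1]
            patch[...] = (1 - alpha) * patch + alpha * color
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# -- persistence ------------------------------------------------------------


def save_grid(grid: TileProbGrid, path: Path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), probs=grid.probs, tissue=grid.tissue)
    sidecar = {
        "origin": list(grid.origin),
        "stride": grid.stride,
        "tile_size": grid.tile_size,
        "labels": list(LABELS),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_grid(path: Path) -> TileProbGrid:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return TileProbGrid(
        origin=tuple(meta["origin"]),
        stride=meta["stride"],
        tile_size=meta["tile_size"],
        probs=data["probs"],
        tissue=data["tissue"],
    )


def save_features(seq: FeatureSequence, path: Path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), features=seq.features)
    rows = [
        {"x0": t.x0, "y0": t.y0, "size": t.size, "orientation": t.orientation}
        for t in seq.tiles
    ]
    path.with_suffix(".json").write_text(
        json.dumps({"slide_id": seq.slide_id, "tiles": rows})
    )


def load_features(path: Path) -> FeatureSequence:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    tiles = [TileRef(x0=r["x0"], y0=r["y0"], size=r["size"], orientation=r["orientation"]) for r in meta["tiles"]]
    return FeatureSequence(slide_id=meta["slide_id"], tiles=tiles, features=data["features"])
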