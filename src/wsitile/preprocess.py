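"""Tissue detection, slide-label assignment and balanced tile sampling.

Coordinates are 0-based level-0 pixels throughout; a tile with origin
(x0, y0) and size T spans the half-open square [x0, x0+T) x [y0, y0+T).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union
from skimage.color import rgb2hsv
from skimage.transform import downscale_local_mean

from .labels import LABELS, check_label

log = logging.getLogger(__name__)

DEFAULT_TILE_SIZE = 512
DEFAULT_CENTRAL_WINDOW = 128
DEFAULT_N_PER_LABEL = 400
DEFAULT_SATURATION_THRESHOLD = 0.07
DEFAULT_DOWNSAMPLE = 32

#: Dihedral-group orientations: index = 4*flip + rot, i.e. rotate by
#: ``rot`` quarter turns, then (if flip) mirror left-right.
N_ORIENTATIONS = 8


def apply_orientation(tile: np.ndarray, orientation: int) -> np.ndarray:
    """Apply one of the 8 dihedral transforms to a square tile."""
    if not 0 <= orientation < N_ORIENTATIONS:
        raise ValueError(f"orientation must be in [0, 8), got {orientation}")
    out = np.rot90(tile, orientation % 4)
    if orientation >= 4:
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def invert_orientation(orientation: int) -> int:
    """Index of the inverse dihedral transform.

    Pure rotations invert to the opposite rotation; every flip-composed
    transform is an involution.
    """
    if orientation >= 4:
        return orientation
    return (4 - orientation) % 4


@dataclass(frozen=True)
class TissueMask:
    """Binary tissue mask at a stated downsample of level 0."""

    mask: np.ndarray  # bool, (ceil(H/ds), ceil(W/ds))
    downsample: int
    saturation_threshold: float

    def at_level0(self, x: int, y: int) -> bool:
        return bool(self.mask[y // self.downsample, x // self.downsample])


@dataclass(frozen=True)
class TileRef:
    """One sampled or inferred tile."""

    x0: int
    y0: int
    size: int = DEFAULT_TILE_SIZE
    orientation: int = 0
    label: str | None = None


def detect_tissue(
    image: np.ndarray,
    saturation_threshold: float = DEFAULT_SATURATION_THRESHOLD,
    downsample: int = DEFAULT_DOWNSAMPLE,
) -> TissueMask:
    """Saturation-threshold tissue detection on a downsampled grid.

    The image is block-averaged by ``downsample`` (edge blocks are partial)
    and a cell is tissue where HSV saturation exceeds the threshold.
    Saturation is invariant to uniform intensity scaling, so the zero
    padding of partial edge blocks does not disturb the threshold test.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    if not 0.0 < saturation_threshold < 1.0:
        raise ValueError("saturation threshold must lie strictly inside (0, 1)")
    small = downscale_local_mean(np.asarray(image, dtype=np.float64), (downsample, downsample, 1))
    sat = rgb2hsv(small / 255.0)[..., 1]
    return TissueMask(
        mask=sat > saturation_threshold,
        downsample=downsample,
        saturation_threshold=saturation_threshold,
    )


def assign_slide_label(region_labels: set) -> str:
    """Slide-level diagnosis: highest-priority label present.

    Priority order: adenocarcinoma, adenoma, non_neoplastic.
    """
    if not region_labels:
        raise ValueError("slide has no annotated regions")
    for label in region_labels:
        check_label(label)
    for label in LABELS:
        if label in region_labels:
            return label
    raise AssertionError("unreachable")


def window_coverage(
    label_geometry, tile: TileRef, central_window: int = DEFAULT_CENTRAL_WINDOW
) -> float:
    """Fraction of the tile's centred window covered by the label geometry."""
    off = (tile.size - central_window) // 2
    win = box(
        tile.x0 + off,
        tile.y0 + off,
        tile.x0 + off + central_window,
        tile.y0 + off + central_window,
    )
    return label_geometry.intersection(win).area / float(central_window**2)


def sample_training_tiles(
    slide,
    mask: TissueMask,
    n_per_label: int = DEFAULT_N_PER_LABEL,
    tile_size: int = DEFAULT_TILE_SIZE,
    central_window: int = DEFAULT_CENTRAL_WINDOW,
    min_coverage: float = 0.5,
    rng_seed: int = 0,
) -> list:
    """Balanced annotated tile sampling with the centred-window rule.

    For every label annotated on the slide, up to ``n_per_label`` tiles are
    drawn by rejection sampling of origins over the label's bounding boxes.
    A candidate is accepted iff its origin lies on detected tissue and at
    least ``min_coverage`` of the centred ``central_window`` square is
    covered by that label's annotated area. Each accepted tile gets a
    random dihedral orientation. Yields fewer than ``n_per_label`` (with a
    warning) when the annotated area cannot supply them within the attempt
    budget of ``50 * n_per_label`` per label.
    """
    if not slide.regions:
        raise ValueError(f"slide {slide.slide_id!r} has no annotations")
    if n_per_label < 1:
        raise ValueError("n_per_label must be >= 1")
    if central_window > tile_size:
        raise ValueError("central_window cannot exceed tile_size")
    if tile_size > min(slide.width_px, slide.height_px):
        raise ValueError(
            f"tile size {tile_size} exceeds slide dims "
            f"{slide.width_px}x{slide.height_px}"
        )
    rng = np.random.default_rng(rng_seed)
    off = (tile_size - central_window) // 2
    tiles: list[TileRef] = []
    for label in LABELS:
        polys = [p for p, lab in slide.regions if lab == label]
        if not polys:
            continue
        geom = unary_union(polys)
        minx, miny, maxx, maxy = geom.bounds
        # origins whose centred window can intersect the label's bbox
        x_lo = max(0, int(np.ceil(minx - off - central_window)))
        x_hi = min(slide.width_px - tile_size, int(np.floor(maxx - off)))
        y_lo = max(0, int(np.ceil(miny - off - central_window)))
        y_hi = min(slide.height_px - tile_size, int(np.floor(maxy - off)))
        if x_hi < x_lo or y_hi < y_lo:
            log.warning("label %s on %s leaves no valid tile origins", label, slide.slide_id)
            continue
        accepted = 0
        for _ in range(50 * n_per_label):
            if accepted >= n_per_label:
                break
            x0 = int(rng.integers(x_lo, x_hi + 1))
            y0 = int(rng.integers(y_lo, y_hi + 1))
            if not mask.at_level0(x0, y0):
                continue
            cand = TileRef(x0=x0, y0=y0, size=tile_size)
            if window_coverage(geom, cand, central_window) < min_coverage:
                continue
            tiles.append(
                TileRef(
                    x0=x0,
                    y0=y0,
                    size=tile_size,
                    orientation=int(rng.integers(N_ORIENTATIONS)),
                    label=label,
                )
            )
            accepted += 1
        if accepted < n_per_label:
            log.warning(
                "slide %s label %s: only %d/%d tiles within attempt budget",
                slide.slide_id,
                label,
                accepted,
                n_per_label,
            )
    return tiles


def extract_tile_pixels(image: np.ndarray, tile: TileRef) -> np.ndarray:
    """Pixels of the tile's half-open square with its orientation applied."""
    h, w = image.shape[:2]
    if tile.x0 < 0 or tile.y0 < 0 or tile.x0 + tile.size > w or tile.y0 + tile.size > h:
        raise ValueError(
            f"tile ({tile.x0},{tile.y0},{tile.size}) out of bounds for {w}x{h} image"
        )
    block = np.asarray(image[tile.y0 : tile.y0 + tile.size, tile.x0 : tile.x0 + tile.size])
    return apply_orientation(block, tile.orientation)


def write_tile_manifest(tiles, path: Path, slide_ids=None) -> None:
    """CSV manifest: slide_id,x0,y0,size,orientation,label."""
    if slide_ids is None:
        slide_ids = [""] * len(tiles)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "x0", "y0", "size", "orientation", "label"])
        for sid, t in zip(slide_ids, tiles):
            writer.writerow([sid, t.x0, t.y0, t.size, t.orientation, t.label or ""])


def read_tile_manifest(path: Path) -> list:
    """-> list of (slide_id, TileRef)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                (
                    row["slide_id"],
                    TileRef(
                        x0=int(row["x0"]),
                        y0=int(row["y0"]),
                        size=int(row["size"]),
                        orientation=int(row["orientation"]),
                        label=row["label"] or None,
                    ),
                )
            )
    return out
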